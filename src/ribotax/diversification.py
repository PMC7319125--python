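"""Lineages-through-time curves, the Pybus-Harvey gamma statistic, and
pure-birth (Yule) null comparisons.

Gamma summarizes where the internal nodes of an ultrametric tree sit in
time: negative values mean nodes concentrate near the root (early, slowing
diversification), positive values near the tips (late nodes, consistent
with high turnover). Under a pure-birth process gamma is asymptotically
standard normal, which the Yule simulator here exploits to build null
distributions. Gamma is invariant to rescaling time, so all computations
run on relative time (root age 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import TreeNode

from .trees import is_ultrametric, is_rooted, node_depths


@dataclass
class LttCurve:
    """Step curve of lineage count against relative time in [0, 1]."""

    breakpoints: list[tuple[float, int]]

    def count_at(self, time: float) -> int:
        count = self.breakpoints[0][1]
        for t, c in self.breakpoints:
            if t <= time:
                count = c
            else:
                break
        return count


@dataclass
class GammaResult:
    n_tips: int
    gamma: float
    internode_intervals: list[float]  # g_2 .. g_n


@dataclass
class NullComparison:
    n_sim: int
    seed: int
    gamma_a: list[float]
    gamma_b: list[float]
    statistic: float
    p_value: float


def _speciation_times(tree: TreeNode, rtol: float = 1e-9) -> tuple[list[float], int]:
    """Sorted speciation-event times (distance from root) on relative time.

    A node with out-degree d contributes d - 1 events at its time, so a
    binary tree with n tips yields n - 1 events starting at the root (0).
    """
    if not is_ultrametric(tree, rtol=rtol):
        raise ValueError("tree is not ultrametric")
    depths = node_depths(tree)
    total = max(depths[t] for t in tree.tips())
    if total <= 0:
        raise ValueError("tree has zero depth")
    times: list[float] = []
    for node in tree.non_tips(include_self=True):
        times.extend([depths[node] / total] * (len(node.children) - 1))
    n_tips = len(list(tree.tips()))
    return sorted(times), n_tips


def ltt_curve(tree: TreeNode) -> LttCurve:
    """Lineage count through relative time on an ultrametric tree.

    The curve starts at 2 at the root; each later internal node adds its
    out-degree minus one (simultaneous nodes — polytomies or ties — are
    merged into a single step).
    """
    times, n_tips = _speciation_times(tree)
    if n_tips < 2:
        raise ValueError("LTT requires >= 2 tips")
    depths = node_depths(tree)
    total = max(depths[t] for t in tree.tips())
    increments: dict[float, int] = {}
    for node in tree.non_tips(include_self=True):
        t = depths[node] / total
        increments[t] = increments.get(t, 0) + (len(node.children) - 1)
    count = 1
    points: list[tuple[float, int]] = []
    for t in sorted(increments):
        count += increments[t]
        points.append((t, count))
    if points[-1][0] < 1.0:
        points.append((1.0, count))
    return LttCurve(points)


def pybus_gamma(tree: TreeNode) -> GammaResult:
    """The gamma statistic computed from internode intervals.

    With g_k the duration during which exactly k lineages are extant
    (k = 2..n), T_k = sum_{j=2..k} j g_j and T = T_n:

        gamma = [ mean_{i=2..n-1}(T_i) - T/2 ] / [ T sqrt(1 / (12 (n-2))) ]
    """
    times, n = _speciation_times(tree)
    if n < 3:
        raise ValueError(f"gamma requires >= 3 tips, got {n}")
    return gamma_from_times(times, n)


def gamma_from_times(times: list[float], n_tips: int, present: float = 1.0) -> GammaResult:
    """Gamma from sorted speciation times (first time = root)."""
    # interval with k lineages runs from the (k-1)-th event to the k-th
    events = list(times) + [present]
    g = [events[k + 1] - events[k] for k in range(len(times))]  # g_2..g_n
    n = n_tips
    T_k = 0.0
    partial = []
    for k, gk in enumerate(g, start=2):
        T_k += k * gk
        partial.append(T_k)
    T = partial[-1]
    if T <= 0:
        raise ValueError("zero total branching time")
    mean_T = sum(partial[:-1]) / (n - 2)
    gamma = (mean_T - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))
    return GammaResult(n_tips=n, gamma=gamma, internode_intervals=g)


def simulate_yule(n_tips: int, seed: int, rng: np.random.Generator | None = None) -> TreeNode:
    """Ultrametric pure-birth tree conditioned on the number of tips.

    Starting from the root split (two lineages at time 0), the waiting time
    with k lineages extant is Exponential(k * lambda) with lambda = 1
    (gamma is scale-free), and a uniformly random extant lineage splits.
    A final Exponential(n * lambda) interval separates the last split from
    the present. Depths are normalized to a root age of 1.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    root = TreeNode(name=None)
    extant: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(name=None, length=0.0)
        root.append(child)
        extant.append(child)
    t = 0.0
    birth_times = {id(c): 0.0 for c in extant}
    while len(extant) < n_tips:
        k = len(extant)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(0, k))
        parent = extant.pop(idx)
        parent.length = t - birth_times[id(parent)]
        for _ in range(2):
            child = TreeNode(name=None, length=0.0)
            parent.append(child)
            extant.append(child)
            birth_times[id(child)] = t
    t += rng.exponential(1.0 / n_tips)
    for node in extant:
        node.length = t - birth_times[id(node)]
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"t{i}"
    for node in root.traverse(include_self=False):
        node.length /= t
    return root


def gamma_null_distribution(
    n_tips: int, n_sim: int = 100, seed: int = 0, envelope_points: int = 101
) -> tuple[list[GammaResult], dict[str, np.ndarray]]:
    """Yule null sample of gamma plus a pointwise LTT min/max envelope."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    grid = np.linspace(0.0, 1.0, envelope_points)
    lo = np.full(envelope_points, np.inf)
    hi = np.full(envelope_points, -np.inf)
    results: list[GammaResult] = []
    for r in range(n_sim):
        tree = simulate_yule(n_tips, seed=seed + r)
        results.append(pybus_gamma(tree))
        curve = ltt_curve(tree)
        counts = np.array([curve.count_at(t) for t in grid], dtype=float)
        lo = np.minimum(lo, counts)
        hi = np.maximum(hi, counts)
    return results, {"time": grid, "min": lo, "max": hi}


def compare_clades_wilcoxon(
    clade_a_tips: int, clade_b_tips: int, n_sim: int = 1000, seed: int = 0
) -> NullComparison:
    """Wilcoxon rank-sum comparison of Yule gamma samples for two clades.

    ``n_sim`` pure-birth trees are simulated per clade at its tip count,
    gamma computed per tree, and the two gamma samples compared with a
    two-sample Wilcoxon rank-sum test.
    """
    if clade_a_tips < 3 or clade_b_tips < 3:
        raise ValueError("both clades need >= 3 tips")
    ga = [
        pybus_gamma(simulate_yule(clade_a_tips, seed=seed + r)).gamma
        for r in range(n_sim)
    ]
    gb = [
        pybus_gamma(simulate_yule(clade_b_tips, seed=seed + n_sim + r)).gamma
        for r in range(n_sim)
    ]
    res = stats.ranksums(ga, gb)
    return NullComparison(
        n_sim=n_sim, seed=seed, gamma_a=ga, gamma_b=gb,
        statistic=float(res.statistic), p_value=float(res.pvalue),
    )
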