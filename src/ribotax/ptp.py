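"""Poisson tree process (PTP-style) species delimitation.

Branch lengths on a phylogeny, in expected substitutions per site, are
modeled as draws from two exponential classes: between-species branches
(the speciation backbone, a connected edge set containing the root) and
within-species branches (everything below the species stems). A
delimitation is parameterized by an antichain of "species root" nodes
covering all tips; edges strictly inside a species subtree are
within-class, all others (including species stems) are between-class.

With per-class rate MLE lambda = n / sum(lengths), the profile
log-likelihood of a class is n (ln(n / S) - 1); the overall likelihood is
the sum over non-empty classes. The search is greedy over split/merge
moves with seeded random restarts; an exhaustive search over all
antichains is provided for small trees as an oracle.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Iterator

from skbio import TreeNode

from .abgd import Partition, make_partition

EPSILON = 1e-9


def _class_loglik(n: int, total: float) -> float:
    if n == 0:
        return 0.0
    return n * (math.log(n / total) - 1.0)


@dataclass
class PtpFit:
    partition: Partition
    rate_between: float | None
    rate_within: float | None
    log_likelihood: float
    null_log_likelihood: float


class _Indexed:
    """Tree pre-indexed for O(1) move evaluation.

    For each node: the sum/count of stem lengths of its strict descendants
    (the within-class contribution if that node is a species root).
    """

    def __init__(self, tree: TreeNode):
        self.root = tree
        self.nodes = list(tree.postorder())
        self.order = {node: i for i, node in enumerate(self.nodes)}
        self.stem: dict[TreeNode, float] = {}
        self.below_sum: dict[TreeNode, float] = {}
        self.below_cnt: dict[TreeNode, int] = {}
        for node in self.nodes:
            if node is not tree:
                self.stem[node] = max(node.length or 0.0, EPSILON)
        for node in self.nodes:
            if node.is_tip():
                self.below_sum[node] = 0.0
                self.below_cnt[node] = 0
            else:
                self.below_sum[node] = sum(
                    self.below_sum[c] + self.stem[c] for c in node.children
                )
                self.below_cnt[node] = sum(
                    self.below_cnt[c] + 1 for c in node.children
                )
        self.total_sum = self.below_sum[tree]
        self.total_cnt = self.below_cnt[tree]
        #: sum of the immediate children's stem lengths (the edges that
        #: change class when a node is split off or merged back)
        self.child_stem_sum = {
            n: sum(self.stem[c] for c in n.children)
            for n in self.nodes if not n.is_tip()
        }

    def within_totals(self, species_roots: set[TreeNode]) -> tuple[int, float]:
        return (
            sum(self.below_cnt[s] for s in species_roots),
            sum(self.below_sum[s] for s in species_roots),
        )

    def ll_from_within(self, w_cnt: int, w_sum: float) -> float:
        return _class_loglik(w_cnt, w_sum) + _class_loglik(
            self.total_cnt - w_cnt, self.total_sum - w_sum
        )

    def loglik(self, species_roots: set[TreeNode]) -> float:
        return self.ll_from_within(*self.within_totals(species_roots))


def _moves(index: _Indexed, current: set[TreeNode]):
    """All single split/merge moves with their within-class deltas."""
    for s in sorted(current, key=index.order.get):
        if not s.is_tip():
            # split: the children's stem edges leave the within class
            yield ("split", s, -len(s.children), -index.child_stem_sum[s])
    parents = {s.parent for s in current if s.parent is not None}
    for p in sorted(parents, key=index.order.get):
        if all(c in current for c in p.children):
            yield ("merge", p, len(p.children), index.child_stem_sum[p])


def _apply(current: set[TreeNode], move) -> set[TreeNode]:
    kind, node, _, _ = move
    if kind == "split":
        return (current - {node}) | set(node.children)
    return (current - set(node.children)) | {node}


def _greedy(index: _Indexed, start: set[TreeNode]) -> tuple[set[TreeNode], float]:
    current = set(start)
    w_cnt, w_sum = index.within_totals(current)
    ll = index.ll_from_within(w_cnt, w_sum)
    while True:
        best_delta, best_move = 0.0, None
        for move in _moves(index, current):
            _, _, d_cnt, d_sum = move
            delta = index.ll_from_within(w_cnt + d_cnt, w_sum + d_sum) - ll
            if delta > best_delta + 1e-12:
                best_delta, best_move = delta, move
        if best_move is None:
            return current, ll
        current = _apply(current, best_move)
        w_cnt += best_move[2]
        w_sum += best_move[3]
        ll += best_delta


def _exact_ml_antichain(index: _Indexed) -> tuple[set[TreeNode], float]:
    """Globally optimal delimitation by dynamic programming.

    For a fixed number k of within-class edges the profile log-likelihood
    is convex in the within-class length sum, so its maximum over the
    achievable sums lies at the minimum or maximum achievable sum. A
    bottom-up knapsack over the tree computes, for every node and every k,
    the extreme achievable within-sums of an antichain covering the
    node's subtree; the best (k, sum) pair at the root is exact.
    """
    # table[node]: k -> [min_sum, max_sum, min_choice, max_choice]
    # choice: None = species root here; else list of (child, k_child, which)
    table: dict[TreeNode, dict[int, list]] = {}
    for node in index.nodes:  # postorder
        if node.is_tip():
            table[node] = {0: [0.0, 0.0, None, None]}
            continue
        options: dict[int, list] = {}
        k_here = index.below_cnt[node]
        s_here = index.below_sum[node]
        options[k_here] = [s_here, s_here, None, None]
        comb: dict[int, list] = {0: [0.0, 0.0, [], []]}
        for child in node.children:
            new: dict[int, list] = {}
            for k1, e1 in comb.items():
                for k2, e2 in table[child].items():
                    k = k1 + k2
                    mn = e1[0] + e2[0]
                    mx = e1[1] + e2[1]
                    entry = new.get(k)
                    if entry is None:
                        new[k] = [
                            mn, mx,
                            e1[2] + [(child, k2, "min")],
                            e1[3] + [(child, k2, "max")],
                        ]
                    else:
                        if mn < entry[0]:
                            entry[0] = mn
                            entry[2] = e1[2] + [(child, k2, "min")]
                        if mx > entry[1]:
                            entry[1] = mx
                            entry[3] = e1[3] + [(child, k2, "max")]
            comb = new
        for k, e in comb.items():
            entry = options.get(k)
            if entry is None:
                options[k] = e
            else:
                if e[0] < entry[0]:
                    entry[0], entry[2] = e[0], e[2]
                if e[1] > entry[1]:
                    entry[1], entry[3] = e[1], e[3]
        table[node] = options

    root = index.root
    best_ll, best_key = -math.inf, None
    for k in sorted(table[root]):
        entry = table[root][k]
        for which, s in (("min", entry[0]), ("max", entry[1])):
            ll = index.ll_from_within(k, s)
            if ll > best_ll + 1e-12:
                best_ll, best_key = ll, (k, which)

    species: set[TreeNode] = set()

    def _collect(node: TreeNode, k: int, which: str) -> None:
        entry = table[node][k]
        choice = entry[2] if which == "min" else entry[3]
        if choice is None:
            species.add(node)
            return
        for child, k_child, w_child in choice:
            _collect(child, k_child, w_child)

    _collect(root, *best_key)
    return species, best_ll


def _random_antichain(root: TreeNode, rng: random.Random) -> set[TreeNode]:
    stop_p = rng.random()
    out: set[TreeNode] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_tip() or rng.random() < stop_p:
            out.add(node)
        else:
            stack.extend(node.children)
    return out


def enumerate_antichains(root: TreeNode) -> Iterator[set[TreeNode]]:
    """All antichains of nodes covering every tip (for exhaustive search)."""
    if root.is_tip():
        yield {root}
        return
    yield {root}
    children_choices = [list(enumerate_antichains(c)) for c in root.children]

    def product(i: int) -> Iterator[set[TreeNode]]:
        if i == len(children_choices):
            yield set()
            return
        for head in children_choices[i]:
            for rest in product(i + 1):
                yield head | rest

    yield from product(0)


def _to_fit(index: _Indexed, species_roots: set[TreeNode], source: str, params: dict) -> PtpFit:
    w_sum = sum(index.below_sum[s] for s in species_roots)
    w_cnt = sum(index.below_cnt[s] for s in species_roots)
    b_sum, b_cnt = index.total_sum - w_sum, index.total_cnt - w_cnt
    blocks = [set(t.name for t in s.tips(include_self=True)) for s in species_roots]
    partition = make_partition(blocks, source, params)
    return PtpFit(
        partition=partition,
        rate_between=(b_cnt / b_sum) if b_cnt else None,
        rate_within=(w_cnt / w_sum) if w_cnt else None,
        log_likelihood=index.loglik(species_roots),
        null_log_likelihood=_class_loglik(index.total_cnt, index.total_sum),
    )


def ptp_partition(
    tree: TreeNode,
    rooted: bool = True,
    n_restarts: int = 10,
    seed: int = 0,
) -> PtpFit:
    """Maximum-likelihood two-rate Poisson delimitation of a tree.

    The search is the exact per-count dynamic program
    (:func:`_exact_ml_antichain`); a greedy split/merge hill-climb with
    ``n_restarts`` seeded random restarts runs alongside as a cheap
    cross-check and the better solution is kept. ``rooted`` only labels
    the provenance of the result (``ptp_rooted`` / ``ptp_unrooted``); the
    tree's own root is the origin of the speciation backbone in both
    cases.
    """
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("PTP requires at least 2 tips")
    index = _Indexed(tree)
    best, best_ll = _exact_ml_antichain(index)
    state, ll = _greedy(index, {tree})
    if ll > best_ll + 1e-12:
        best, best_ll = state, ll
    rng = random.Random(seed)
    for _ in range(max(0, n_restarts)):
        state, ll = _greedy(index, _random_antichain(tree, rng))
        if ll > best_ll + 1e-12:
            best, best_ll = state, ll
    source = "ptp_rooted" if rooted else "ptp_unrooted"
    return _to_fit(index, best, source, {"n_restarts": n_restarts, "seed": seed})


def ptp_exhaustive(tree: TreeNode, rooted: bool = True) -> PtpFit:
    """Exact ML delimitation by enumerating all antichains (small trees)."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("PTP requires at least 2 tips")
    index = _Indexed(tree)
    best: set[TreeNode] | None = None
    best_ll = -math.inf
    for antichain in enumerate_antichains(tree):
        ll = index.loglik(antichain)
        if ll > best_ll + 1e-12:
            best, best_ll = antichain, ll
    source = "ptp_rooted" if rooted else "ptp_unrooted"
    return _to_fit(index, best, source, {"search": "exhaustive"})
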