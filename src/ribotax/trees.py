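"""Distance-based tree building, bootstrap, rooting, patristic distances,
and mean-path-length ultrametricization.

Trees are scikit-bio ``TreeNode`` objects throughout. An "unrooted" tree is
represented with a trifurcating root (as produced by neighbor joining); a
rooted tree has a bifurcating root.
"""

from __future__ import annotations

import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .seqdist import pairwise_distance

logger = logging.getLogger(__name__)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (unrooted).

    Negative branch-length estimates are clamped to zero. Requires at least
    three labels.
    """
    if len(dist.ids) < 3:
        raise ValueError(f"neighbor joining needs >= 3 labels, got {len(dist.ids)}")
    return _skbio_nj(dist, neg_as_zero=True)


def is_rooted(tree: TreeNode) -> bool:
    return len(tree.children) == 2


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each canonicalized
    to the smaller side (ties broken lexicographically)."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return parts


def bootstrap_support(
    sequences: dict[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "K80",
) -> TreeNode:
    """NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement; each replicate is
    rebuilt with NJ and support is the percentage of replicates containing
    each original bipartition. Replicate r uses ``seed + r``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels = list(sequences)
    length = len(next(iter(sequences.values())))
    tree = nj_tree(pairwise_distance(sequences, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in _bipartitions(tree)}
    arrays = {lab: np.array(list(sequences[lab])) for lab in labels}
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, length, size=length)
        resampled = {lab: "".join(arrays[lab][cols]) for lab in labels}
        rep_parts = _bipartitions(nj_tree(pairwise_distance(resampled, model)))
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    all_tips = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, all_tips - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_replicates
    return tree


def root_with_outgroup(tree: TreeNode, outgroup_tips: set[str]) -> TreeNode:
    """Root on the edge separating the outgroup, at its midpoint."""
    tips = {t.name for t in tree.tips()}
    if not outgroup_tips:
        raise ValueError("outgroup is empty")
    if not outgroup_tips <= tips:
        raise ValueError(f"outgroup tips not in tree: {sorted(outgroup_tips - tips)}")
    if outgroup_tips == tips:
        raise ValueError("outgroup cannot contain all tips")
    try:
        return tree.root_by_outgroup(sorted(outgroup_tips))
    except Exception as exc:
        raise ValueError(f"outgroup not separable by a single edge: {exc}") from exc


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length matrix. Requires every branch length set."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at node {node.name!r}")
    return tree.tip_tip_distances()


def node_depths(tree: TreeNode) -> dict[TreeNode, float]:
    """Distance from the root to every node (missing lengths are errors)."""
    depths: dict[TreeNode, float] = {tree: 0.0}
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise ValueError(f"missing branch length at node {node.name!r}")
        depths[node] = depths[node.parent] + node.length
    return depths


def is_ultrametric(tree: TreeNode, rtol: float = 1e-9) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[t] for t in tree.tips()]
    top = max(tip_depths)
    if top == 0:
        return True
    return max(tip_depths) - min(tip_depths) <= rtol * top


def ultrametricize(tree: TreeNode, method: str = "mean_path_length") -> TreeNode:
    """Transform a rooted tree into a relative-time ultrametric tree.

    Each internal node's age is the mean path length to its descendant tips;
    child ages exceeding the parent's are clamped (logged). Ages are
    normalized so the root is at age 1 and tips at age 0; branch lengths
    become age differences. Node ages are exposed as ``node.age``.
    """
    if method != "mean_path_length":
        raise ValueError(f"unknown method {method!r}")
    if not is_rooted(tree):
        raise ValueError("ultrametricization requires a rooted (bifurcating-root) tree")
    tree = tree.copy()
    for node in tree.postorder():
        if node.is_tip():
            node.age = 0.0
            node._tip_count = 1
            node._path_sum = 0.0
        else:
            node._tip_count = sum(c._tip_count for c in node.children)
            node._path_sum = sum(
                c._path_sum + c._tip_count * (c.length or 0.0) for c in node.children
            )
            node.age = node._path_sum / node._tip_count
    if tree.age <= 0:
        raise ValueError("tree has zero total depth; cannot normalize")
    n_clamped = 0
    for node in tree.preorder(include_self=False):
        if not node.is_tip() and node.age > node.parent.age:
            node.age = node.parent.age
            n_clamped += 1
    if n_clamped:
        logger.warning("ultrametricize: clamped %d node age(s) to parent age", n_clamped)
    root_age = tree.age
    for node in tree.traverse():
        node.age = node.age / root_age
        del node._tip_count, node._path_sum
    for node in tree.traverse(include_self=False):
        node.length = node.parent.age - node.age
    tree.length = None
    return tree
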