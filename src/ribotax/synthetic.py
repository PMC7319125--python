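"""Synthetic clone-library datasets with known taxonomic truth.

The generator emulates the sampling design of a global clone-library
survey of a benthic foraminifer: ~16 sites along a longitudinal gradient,
3-8 sequenced specimens per site, 8-16 PCR clones per specimen of a ~700 bp
rDNA fragment, and a hierarchy of six genotypes nested in four lineages
with mutually exclusive site occupancy.

Divergence is layered on four well-separated scales (expected
substitutions/site): lineage depth > genotype depth > within-genotype
haplotype divergence > per-clone noise (polymerase/intragenomic variation).
Each genotype carries a shared pool of intragenomic rDNA haplotypes;
specimens sample 1-3 pool haplotypes and their clones scatter around them,
so recurrent haplotypes co-occur within specimens across the genotype —
the structure the basetype/basegroup system relies on.

Sequences evolve under K80 (transition/transversion ratio kappa, default
2), i.i.d. sites, no indels: data are generated pre-aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
from skbio import TreeNode
from sklearn.metrics import adjusted_rand_score

from .records import SequenceRecord, Site
from .taxonomy import TaxonomyAssignment
from .diversification import simulate_yule

#: Internal splits of a level tree are confined to the older part of the
#: level's time band (ages in [MIN_SPLIT_FRACTION, 1] x depth). This keeps
#: the divergence bands of successive hierarchy levels from overlapping —
#: without it, a recent split at one level can produce divergences
#: indistinguishable from the level below, and the dataset would not carry
#: the scale separation it is meant to exhibit.
MIN_SPLIT_FRACTION = 0.5

_BASES = "ACGT"
#: K80 transition partner (A<->G, C<->T) per base index
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = [(1, 3), (0, 2), (1, 3), (0, 2)]


@dataclass(frozen=True)
class SyntheticConfig:
    n_lineages: int = 4
    genotypes_per_lineage: tuple[int, ...] = (1, 3, 1, 1)
    n_sites: int = 16
    specimens_per_site: tuple[int, int] = (3, 8)
    clones_per_specimen: tuple[int, int] = (8, 16)
    seq_length: int = 700
    lineage_depth: float = 0.10
    genotype_depth: float = 0.04
    within_genotype: float = 0.005
    clone_noise: float = 0.001
    kappa: float = 2.0
    haplotypes_per_genotype: int = 4
    haplotypes_per_specimen: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes_per_lineage) != self.n_lineages:
            raise ValueError("genotypes_per_lineage length must equal n_lineages")
        if any(g < 1 for g in self.genotypes_per_lineage):
            raise ValueError("every lineage needs >= 1 genotype")
        depths = (self.lineage_depth, self.genotype_depth, self.within_genotype)
        if not (depths[0] > depths[1] > depths[2] > self.clone_noise >= 0):
            raise ValueError(
                "divergence scales must satisfy "
                "lineage_depth > genotype_depth > within_genotype > clone_noise >= 0"
            )
        if self.n_lineages < 2:
            raise ValueError("need >= 2 lineages")


@dataclass
class SyntheticTruth:
    tree: TreeNode  # haplotype genealogy
    taxonomy: dict[str, tuple[str, str, str]]  # sequence -> (lineage, genotype, basegroup)
    site_genotype: dict[str, str]
    sites: dict[str, Site]
    haplotype_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_lineages(self) -> int:
        return len({v[0] for v in self.taxonomy.values()})

    @property
    def n_genotypes(self) -> int:
        return len({v[1] for v in self.taxonomy.values()})


def _level_tree(n_tips: int, depth: float, rng: np.random.Generator) -> "TreeNode":
    """Yule tree for one hierarchy level, splits confined to the old band.

    The pure-birth tree is drawn on relative time (root age 1, tips 0) and
    its internal node ages are mapped affinely into
    [MIN_SPLIT_FRACTION, 1] * depth; tips stay at age 0 and branch lengths
    become age differences.
    """
    tree = simulate_yule(n_tips, seed=0, rng=rng)
    age: dict[TreeNode, float] = {tree: 1.0}
    for node in tree.preorder(include_self=False):
        age[node] = age[node.parent] - node.length
    new_age: dict[TreeNode, float] = {}
    for node in tree.traverse():
        if node.is_tip():
            new_age[node] = 0.0
        else:
            new_age[node] = depth * (
                MIN_SPLIT_FRACTION + (1.0 - MIN_SPLIT_FRACTION) * age[node]
            )
    for node in tree.traverse(include_self=False):
        node.length = new_age[node.parent] - new_age[node]
    return tree


def _mutate(seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a base-index array for expected ``t`` substitutions/site (K80)."""
    out = seq.copy()
    n_events = rng.poisson(t, size=seq.size)
    p_transition = kappa / (kappa + 2.0)
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            base = out[site]
            if rng.random() < p_transition:
                out[site] = _TRANSITION[base]
            else:
                pair = _TRANSVERSIONS[base]
                out[site] = pair[int(rng.random() < 0.5)]
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def _site_allocation(config: SyntheticConfig) -> list[int]:
    """Number of sites per genotype (genotypes in lineage order).

    The last two lineages play the isolated-island role and get one site
    each; the remaining sites spread as evenly as possible over the other
    genotypes, earlier genotypes taking the remainder.
    """
    genotype_lineage = [
        li for li, g in enumerate(config.genotypes_per_lineage) for _ in range(g)
    ]
    n_geno = len(genotype_lineage)
    if config.n_sites < n_geno:
        raise ValueError("need at least one site per genotype")
    counts = [0] * n_geno
    island_lineages = list(range(config.n_lineages))[-2:]
    islands = [i for i, li in enumerate(genotype_lineage) if li in island_lineages]
    others = [i for i in range(n_geno) if i not in islands]
    if not others:  # degenerate: everything is an island
        others, islands = list(range(n_geno)), []
    for i in islands:
        counts[i] = 1
    remaining = config.n_sites - len(islands)
    base, extra = divmod(remaining, len(others))
    for rank, i in enumerate(others):
        counts[i] = base + (1 if rank < extra else 0)
    return counts


def simulate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[SequenceRecord], dict[str, tuple[str, str]], dict[str, Site], SyntheticTruth]:
    """Generate (records, metadata, sites, truth), reproducible under seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length

    # --- genealogy: lineage Yule tree, genotype Yule subtrees, haplotype stars
    lineage_tree = _level_tree(config.n_lineages, config.lineage_depth, rng)
    lineage_tips = list(lineage_tree.tips())
    genotype_ids: list[str] = []
    genotype_lineage: dict[str, str] = {}
    for li, tip in enumerate(lineage_tips, start=1):
        lineage_id = f"L{li}"
        tip.name = None
        n_geno = config.genotypes_per_lineage[li - 1]
        if n_geno == 1:
            sub = TreeNode(name=f"{lineage_id}G1", length=config.genotype_depth)
            tip.append(sub)
        else:
            sub = _level_tree(n_geno, config.genotype_depth, rng)
            sub.length = 0.0
            for gi, gtip in enumerate(sub.tips(), start=1):
                gtip.name = f"{lineage_id}G{gi}"
            tip.append(sub)
        for gi in range(1, n_geno + 1):
            gid = f"{lineage_id}G{gi}"
            genotype_ids.append(gid)
            genotype_lineage[gid] = lineage_id
    # haplotype stars below genotype tips
    for gtip in [t for t in lineage_tree.tips()]:
        gid = gtip.name
        gtip.name = None
        for h in range(1, config.haplotypes_per_genotype + 1):
            gtip.append(TreeNode(name=f"{gid}H{h}", length=config.within_genotype))

    # --- evolve haplotype sequences along the genealogy
    root_seq = rng.integers(0, 4, size=L)
    seqs: dict[TreeNode, np.ndarray] = {lineage_tree: root_seq}
    for node in lineage_tree.preorder(include_self=False):
        seqs[node] = _mutate(seqs[node.parent], node.length or 0.0, config.kappa, rng)
    pool: dict[str, list[tuple[str, np.ndarray]]] = {g: [] for g in genotype_ids}
    for tip in lineage_tree.tips():
        gid = tip.name.rsplit("H", 1)[0]
        pool[gid].append((tip.name, seqs[tip]))

    # --- sites on a longitudinal gradient, one genotype each
    counts = _site_allocation(config)
    sites: dict[str, Site] = {}
    site_genotype: dict[str, str] = {}
    longitudes = np.linspace(40.0, 175.0, config.n_sites)
    site_idx = 0
    for gi, gid in enumerate(genotype_ids):
        for _ in range(counts[gi]):
            site_idx += 1
            sid = f"site{site_idx:02d}"
            lat = float(np.round(rng.uniform(-25.0, 25.0), 4))
            sites[sid] = Site(sid, f"Locality {site_idx}", lat, float(np.round(longitudes[site_idx - 1], 4)))
            site_genotype[sid] = gid

    # --- specimens and clones
    records: list[SequenceRecord] = []
    metadata: dict[str, tuple[str, str]] = {}
    taxonomy: dict[str, tuple[str, str, str]] = {}
    haplotype_of: dict[str, str] = {}
    specimen_haplotypes: dict[str, list[str]] = {}
    lo_sp, hi_sp = config.specimens_per_site
    lo_cl, hi_cl = config.clones_per_specimen
    lo_h, hi_h = config.haplotypes_per_specimen
    for sid in sites:
        gid = site_genotype[sid]
        hap_pool = pool[gid]
        n_specimens = int(rng.integers(lo_sp, hi_sp + 1))
        for sp in range(1, n_specimens + 1):
            specimen_id = f"{sid}_sp{sp}"
            n_hap = int(rng.integers(lo_h, min(hi_h, len(hap_pool)) + 1))
            chosen = rng.choice(len(hap_pool), size=n_hap, replace=False)
            specimen_haplotypes[specimen_id] = [hap_pool[i][0] for i in chosen]
            n_clones = int(rng.integers(lo_cl, hi_cl + 1))
            for c in range(1, n_clones + 1):
                hap_name, hap_seq = hap_pool[int(rng.choice(chosen))]
                clone = (
                    _mutate(hap_seq, config.clone_noise, config.kappa, rng)
                    if config.clone_noise > 0 else hap_seq
                )
                seq_id = f"{specimen_id}_c{c:02d}"
                records.append(
                    SequenceRecord(seq_id, specimen_id, sid, _decode(clone))
                )
                metadata[seq_id] = (specimen_id, sid)
                haplotype_of[seq_id] = hap_name

    # --- true basegroups: co-occurrence components of pool haplotypes
    graph = nx.Graph()
    graph.add_nodes_from(haplotype_of.values())
    for haps in specimen_haplotypes.values():
        for other in haps[1:]:
            graph.add_edge(haps[0], other)
    component_of: dict[str, str] = {}
    for comp in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        label = min(comp)
        for hap in comp:
            component_of[hap] = label
    for seq_id, hap in haplotype_of.items():
        gid = hap.rsplit("H", 1)[0]
        taxonomy[seq_id] = (genotype_lineage[gid], gid, component_of[hap])

    truth = SyntheticTruth(
        tree=lineage_tree, taxonomy=taxonomy, site_genotype=site_genotype,
        sites=sites, haplotype_of=haplotype_of,
    )
    return records, metadata, sites, truth


def truth_recovery_score(
    truth: SyntheticTruth,
    inferred: TaxonomyAssignment | dict[str, tuple[str, ...] | list[str]],
) -> dict[str, float | int | bool]:
    """Compare an inferred taxonomy with the generating truth.

    ``inferred`` is a :class:`TaxonomyAssignment` or a plain mapping
    sequence_id -> (lineage, genotype, ...) as found in the pipeline
    report. Reports inferred lineage/genotype unit counts, equality flags
    against the truth, and the adjusted Rand index of the genotype
    partition over the full sequence universe (unassigned sequences form
    one extra cluster).
    """
    if isinstance(inferred, TaxonomyAssignment):
        labels = {s: (r.lineage, r.genotype) for s, r in inferred.rows.items()}
    else:
        labels = {s: (v[0], v[1]) for s, v in inferred.items()}
    if set(truth.taxonomy) != set(labels):
        raise ValueError("sequence universes differ between truth and inference")
    seq_ids = sorted(truth.taxonomy)
    true_geno = [truth.taxonomy[s][1] for s in seq_ids]
    inf_geno = [labels[s][1] for s in seq_ids]
    inf_lineages = {v[0] for v in labels.values() if v[0] != "unassigned"}
    inf_genotypes = {g for g in inf_geno if g != "unassigned"}
    return {
        "n_lineages_true": truth.n_lineages,
        "n_genotypes_true": truth.n_genotypes,
        "n_lineages_inferred": len(inf_lineages),
        "n_genotypes_inferred": len(inf_genotypes),
        "lineage_count_match": len(inf_lineages) == truth.n_lineages,
        "genotype_count_match": len(inf_genotypes) == truth.n_genotypes,
        "ari": float(adjusted_rand_score(true_geno, inf_geno)),
        "n_unassigned": sum(1 for g in inf_geno if g == "unassigned"),
    }


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    from .io import write_newick

    payload = {
        "tree_newick": write_newick(truth.tree),
        "taxonomy": {k: list(v) for k, v in truth.taxonomy.items()},
        "site_genotype": truth.site_genotype,
        "sites": {k: asdict(s) for k, s in truth.sites.items()},
        "haplotype_of": truth.haplotype_of,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
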