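"""Reconciling, validating, and naming delimitation units.

Raw partitions from the barcode-gap and Poisson-tree-process analyses are
(1) aggregated so that no basegroup is split across units, (2) validated by
comparing intra- vs inter-unit patristic distances (one-sided
Kolmogorov-Smirnov and Mann-Whitney tests), with invalidated units merged
into their closest neighbor, and (3) assembled into the hierarchical
lineage > genotype > basegroup nomenclature (labels I, IIa, IIc6, ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .abgd import Partition, make_partition
from .taxonomy import Basegroup, Basetype

logger = logging.getLogger(__name__)


def reconcile_with_basegroups(partition: Partition, basegroups: list[Basegroup]) -> Partition:
    """Merge units until no basegroup's basetypes span two units (fixpoint).

    The merged unit keeps the label of its largest constituent (ties: the
    lexicographically smallest unit label).
    """
    assignment = dict(partition.assignment)
    merged_any = False
    while True:
        changed = False
        for bg in basegroups:
            members = [b for b in bg.basetype_ids if b in assignment]
            units = {assignment[b] for b in members}
            if len(units) < 2:
                continue
            sizes: dict[str, int] = {}
            for unit in assignment.values():
                sizes[unit] = sizes.get(unit, 0) + 1
            keep = sorted(units, key=lambda u: (-sizes[u], u))[0]
            for label, unit in assignment.items():
                if unit in units:
                    assignment[label] = keep
            changed = merged_any = True
        if not changed:
            break
    if not merged_any:
        return partition
    blocks = {}
    for label, unit in assignment.items():
        blocks.setdefault(unit, set()).add(label)
    return make_partition(
        list(blocks.values()), "merged",
        {"from": partition.source, **partition.parameters},
    )


@dataclass
class UnitVerdict:
    unit: str
    n_members: int
    ks_statistic: float | None
    ks_p: float | None
    mw_statistic: float | None
    mw_p: float | None
    median_intra: float | None
    median_inter: float | None
    validated: bool
    reason: str = ""
    merge_target: str | None = None


@dataclass
class ValidationReport:
    alpha: float
    verdicts: dict[str, UnitVerdict] = field(default_factory=dict)

    @property
    def all_validated(self) -> bool:
        return all(v.validated for v in self.verdicts.values())

    def invalidated_units(self) -> list[str]:
        return sorted(u for u, v in self.verdicts.items() if not v.validated)


def _intra_values(dist: DistanceMatrix, members: list[str]) -> np.ndarray:
    idx = [dist.index(m) for m in members]
    sub = dist.data[np.ix_(idx, idx)]
    return sub[np.triu_indices(len(idx), k=1)]


def _cross_values(dist: DistanceMatrix, a: list[str], b: list[str]) -> np.ndarray:
    ia = [dist.index(m) for m in a]
    ib = [dist.index(m) for m in b]
    return dist.data[np.ix_(ia, ib)].ravel()


def validate_partition_patristic(
    partition: Partition,
    patristic: DistanceMatrix,
    alpha: float = 0.05,
    parent_partition: Partition | None = None,
) -> ValidationReport:
    """Test each unit's intra- vs inter-unit patristic distance separation.

    Inter-unit distances are restricted to the unit's parent clade when a
    parent partition is given (e.g. genotypes compared within their
    lineage). A unit is validated iff both one-sided tests (inter > intra)
    reject at ``alpha`` AND median(inter) > median(intra). Units with fewer
    than two members cannot be validated; a unit alone in its parent clade
    has nothing to be tested against and passes trivially.
    """
    units = partition.units()
    if len(units) < 2:
        raise ValueError("validation requires at least 2 units")
    if all(len(m) < 2 for m in units.values()):
        raise ValueError("all units are singletons; nothing can be validated")
    report = ValidationReport(alpha=alpha)
    for unit, members in sorted(units.items()):
        members = sorted(members)
        if parent_partition is not None:
            parent_unit = parent_partition.assignment[members[0]]
            scope = [
                lab for lab, pu in parent_partition.assignment.items()
                if pu == parent_unit and lab in partition.assignment
            ]
        else:
            scope = list(partition.assignment)
        others = sorted(set(scope) - set(members))
        if not others:
            report.verdicts[unit] = UnitVerdict(
                unit, len(members), None, None, None, None, None, None,
                validated=True, reason="sole_unit_in_parent",
            )
            continue
        if len(members) < 2:
            report.verdicts[unit] = UnitVerdict(
                unit, len(members), None, None, None, None, None,
                float(np.median(_cross_values(patristic, members, others))),
                validated=False, reason="too_few_members",
            )
            continue
        intra = _intra_values(patristic, members)
        inter = _cross_values(patristic, members, others)
        # one-sided: intra stochastically smaller than inter
        ks = stats.ks_2samp(intra, inter, alternative="greater")
        mw = stats.mannwhitneyu(intra, inter, alternative="less")
        med_intra, med_inter = float(np.median(intra)), float(np.median(inter))
        ok = ks.pvalue < alpha and mw.pvalue < alpha and med_inter > med_intra
        report.verdicts[unit] = UnitVerdict(
            unit, len(members),
            float(ks.statistic), float(ks.pvalue),
            float(mw.statistic), float(mw.pvalue),
            med_intra, med_inter,
            validated=bool(ok), reason="" if ok else "no_patristic_gap",
        )
    return report


def merge_invalidated(
    partition: Partition, report: ValidationReport, patristic: DistanceMatrix
) -> Partition:
    """Merge each invalidated unit into its patristically closest neighbor.

    Targets are chosen by minimum median inter-unit patristic distance;
    invalidated units are processed in unit-label order. Returns the
    partition unchanged if nothing was invalidated.
    """
    bad = report.invalidated_units()
    if not bad:
        return partition
    assignment = dict(partition.assignment)
    for unit in bad:
        members = sorted(l for l, u in assignment.items() if u == unit)
        if not members:
            continue  # already absorbed by an earlier merge
        other_units = sorted(set(assignment.values()) - {unit})
        if not other_units:
            break
        medians = {}
        for other in other_units:
            other_members = sorted(l for l, u in assignment.items() if u == other)
            medians[other] = float(
                np.median(_cross_values(patristic, members, other_members))
            )
        target = min(other_units, key=lambda u: (medians[u], u))
        for label in members:
            assignment[label] = target
        report.verdicts[unit].merge_target = target
        logger.info("merged invalidated unit %s into %s", unit, target)
    blocks: dict[str, set[str]] = {}
    for label, unit in assignment.items():
        blocks.setdefault(unit, set()).add(label)
    return make_partition(
        list(blocks.values()), "validated",
        {"from": partition.source, "merged_units": bad},
    )


def _roman(n: int) -> str:
    numerals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
        (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in numerals:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _letters(i: int) -> str:
    # a, b, ..., z, aa, ab, ... (i is 0-based)
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def assemble_nomenclature(
    lineage_partition: Partition,
    genotype_partition: Partition,
    basegroups: list[Basegroup],
) -> dict[str, tuple[str, str, str]]:
    """Hierarchical labels for every basetype.

    Lineages are labeled I, II, ... by decreasing basetype count (ties:
    lexicographically smallest member); genotypes are suffixed a, b, c
    within their lineage by the same order; basegroups are numbered within
    their genotype (e.g. IIc6). A genotype unit straddling two lineages is
    split, with a warning. Returns basetype_id -> (lineage, genotype,
    basegroup) and writes labels onto the given basegroups.
    """
    if not lineage_partition.assignment or not genotype_partition.assignment:
        raise ValueError("empty partition")
    # enforce nesting: split any genotype unit spanning several lineages
    geno_blocks: list[set[str]] = []
    for unit, members in sorted(genotype_partition.units().items()):
        by_lineage: dict[str, set[str]] = {}
        for m in members:
            by_lineage.setdefault(lineage_partition.assignment[m], set()).add(m)
        if len(by_lineage) > 1:
            logger.warning(
                "genotype unit %s straddles %d lineages; splitting", unit, len(by_lineage)
            )
        geno_blocks.extend(by_lineage.values())

    lineage_units = sorted(
        lineage_partition.units().items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    lineage_label = {}
    for i, (_, members) in enumerate(lineage_units, start=1):
        for m in members:
            lineage_label[m] = _roman(i)

    genotype_label: dict[str, str] = {}
    for i, (_, lin_members) in enumerate(lineage_units, start=1):
        blocks = [b for b in geno_blocks if b <= lin_members]
        blocks.sort(key=lambda b: (-len(b), min(b)))
        for j, block in enumerate(blocks):
            for m in block:
                genotype_label[m] = _roman(i) + _letters(j)

    basegroup_label: dict[str, str] = {}
    by_genotype: dict[str, list[Basegroup]] = {}
    for bg in basegroups:
        members = sorted(b for b in bg.basetype_ids if b in genotype_label)
        if not members:
            continue
        by_genotype.setdefault(genotype_label[members[0]], []).append(bg)
    for geno, bgs in sorted(by_genotype.items()):
        bgs.sort(key=lambda bg: (-len(bg.basetype_ids), min(bg.basetype_ids)))
        for k, bg in enumerate(bgs, start=1):
            bg.label = f"{geno}{k}"
            for b in bg.basetype_ids:
                basegroup_label[b] = bg.label

    return {
        b: (lineage_label[b], genotype_label[b], basegroup_label.get(b, "unassigned"))
        for b in lineage_partition.assignment
    }


def pairwise_unit_tests(
    patristic: DistanceMatrix, unit_map: dict[str, str]
) -> pd.DataFrame:
    """Pairwise t tests of within- vs between-unit patristic distances.

    For every pair of units with >= 2 members each, a two-sample t test
    compares the pooled within-unit distances against the between-pair
    distances; p values carry a Bonferroni adjustment over the number of
    pairs tested. Units with fewer than two distances are excluded with a
    note in the ``note`` column.
    """
    units: dict[str, list[str]] = {}
    for label, unit in sorted(unit_map.items()):
        units.setdefault(unit, []).append(label)
    testable = {u: m for u, m in units.items() if len(m) >= 2}
    excluded = sorted(set(units) - set(testable))
    if len(testable) < 2:
        raise ValueError("need >= 2 units with >= 2 members each")
    rows = []
    pairs = [
        (a, b)
        for i, a in enumerate(sorted(testable))
        for b in sorted(testable)[i + 1 :]
    ]
    m = len(pairs)
    for a, b in pairs:
        within = np.concatenate(
            [_intra_values(patristic, testable[a]), _intra_values(patristic, testable[b])]
        )
        between = _cross_values(patristic, testable[a], testable[b])
        t = stats.ttest_ind(within, between, equal_var=False)
        p_adj = min(1.0, m * float(t.pvalue))
        rows.append(
            {
                "unit_a": a, "unit_b": b,
                "t_statistic": float(t.statistic), "p_value": float(t.pvalue),
                "p_adjusted": p_adj, "significant": p_adj < 0.05, "note": "",
            }
        )
    for u in excluded:
        rows.append(
            {
                "unit_a": u, "unit_b": "", "t_statistic": np.nan, "p_value": np.nan,
                "p_adjusted": np.nan, "significant": False,
                "note": "excluded: fewer than 2 members",
            }
        )
    return pd.DataFrame(rows)


def refines(fine: Partition, coarse: Partition) -> bool:
    """True when every unit of ``fine`` lies inside one unit of ``coarse``."""
    for members in fine.units().values():
        parents = {coarse.assignment[m] for m in members if m in coarse.assignment}
        if len(parents) > 1:
            return False
    return True


def choose_lineage_partition(
    abgd_initial: list[Partition], ptp_rooted: Partition
) -> Partition:
    """Coarsest barcode-gap initial partition that the PTP partition refines.

    Falls back to the coarsest multi-unit initial partition, then to the
    PTP partition itself.
    """
    candidates = sorted(
        (p for p in abgd_initial if p.n_units >= 2), key=lambda p: p.n_units
    )
    for cand in candidates:
        if refines(ptp_rooted, cand):
            return cand
    if candidates:
        return candidates[0]
    return ptp_rooted


def choose_genotype_partition(
    all_partitions: list[Partition],
    lineage_partition: Partition,
    patristic: DistanceMatrix,
    alpha: float = 0.05,
) -> tuple[Partition, ValidationReport]:
    """Finest reconciled partition nested in the lineages, then validated.

    The finest (most units) candidate refining the lineage partition is
    validated per lineage; invalidated units are merged into their closest
    neighbor and the result is re-validated once.
    """
    nested = [p for p in all_partitions if refines(p, lineage_partition)]
    pool = nested or [lineage_partition]
    finest = max(pool, key=lambda p: p.n_units)
    if finest.n_units < 2:
        return finest, ValidationReport(alpha=alpha)
    report = validate_partition_patristic(
        finest, patristic, alpha=alpha, parent_partition=lineage_partition
    )
    merged = merge_invalidated(finest, report, patristic)
    if merged is not finest and merged.n_units >= 2:
        report = validate_partition_patristic(
            merged, patristic, alpha=alpha, parent_partition=lineage_partition
        )
        return merged, report
    return merged, report
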