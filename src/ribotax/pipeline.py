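"""End-to-end orchestration of the cryptic-diversity analysis.

Stage order: validate -> basetypes/basegroups -> distances -> tree (built
or imported) -> delimitation (barcode gap; Poisson tree process on rooted
and unrooted trees) -> basegroup reconciliation -> patristic validation
and merging -> nomenclature -> assignment of leftover clones ->
ultrametricization -> LTT / gamma / pure-birth nulls -> geography.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as rio
from .abgd import AbgdParams, Partition, abgd_partition
from .delimit import (
    choose_genotype_partition,
    choose_lineage_partition,
    merge_invalidated,
    pairwise_unit_tests,
    reconcile_with_basegroups,
    validate_partition_patristic,
)
from .diversification import (
    compare_clades_wilcoxon,
    gamma_null_distribution,
    ltt_curve,
    pybus_gamma,
)
from .geography import build_pair_table, classify_dispersion, fit_regression
from .ptp import ptp_partition
from .records import Dataset, SequenceRecord, Site, validate_dataset
from .seqdist import pairwise_distance
from .taxonomy import (
    assign_remaining_sequences,
    build_basegroups,
    extract_basetypes,
)
from .trees import (
    bootstrap_support,
    nj_tree,
    patristic_distances,
    root_with_outgroup,
    ultrametricize,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    min_occurrences: int = 2
    count_mode: str = "clones"
    tree_model: str = "K80"
    delimitation_model: str = "p"
    abgd: AbgdParams = field(default_factory=AbgdParams)
    ptp_restarts: int = 10
    alpha: float = 0.05
    min_identity: float = 0.97
    bootstrap_replicates: int = 0
    n_sim_null: int = 100
    n_sim_wilcoxon: int = 1000
    min_clade_tips: int = 3
    seed: int = 0
    outgroup: tuple[str, ...] = ()
    tree_newick: str | None = None  # pre-computed tree (path or literal)
    routing_overrides: dict = field(default_factory=dict)
    include_sites: list[str] | None = None
    band: str = "half_range"


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _partition_summary(p: Partition) -> dict:
    params = {
        k: (v if not isinstance(v, (list, tuple)) else list(v))
        for k, v in p.parameters.items()
    }
    return {"source": p.source, "n_units": p.n_units, "parameters": params}


def run_full_pipeline(
    records: list[SequenceRecord],
    metadata: dict[str, tuple[str, str]],
    sites: dict[str, Site],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the whole analysis and return a machine-readable report.

    The report is a pure function of (inputs, config): every random stage
    derives its stream from ``config.seed``.
    """
    config = config or PipelineConfig()
    report: dict = {"config": _jsonable_config(config), "counts": {}}

    ds: Dataset = _stage("validate")(validate_dataset)(records, metadata, sites)
    report["counts"].update(
        n_sequences=ds.n_sequences, n_specimens=ds.n_specimens, n_sites=ds.n_sites
    )

    extraction = _stage("basetypes")(extract_basetypes)(
        ds.records, config.min_occurrences, config.count_mode
    )
    basetypes = extraction.basetypes
    basegroups = _stage("basegroups")(build_basegroups)(basetypes)
    report["counts"].update(
        n_basetypes=len(basetypes),
        n_basetype_member_sequences=sum(b.occurrence_count for b in basetypes),
        n_discarded_singletons=len(extraction.discarded),
        n_basegroups=len(basegroups),
    )

    alignment = {b.basetype_id: b.nucleotides for b in basetypes}
    dm_delim = _stage("distances")(pairwise_distance)(alignment, config.delimitation_model)

    @_stage("tree")
    def _build_tree() -> TreeNode:
        if config.tree_newick is not None:
            return rio.read_newick(config.tree_newick)
        if config.bootstrap_replicates > 0:
            return bootstrap_support(
                alignment, config.bootstrap_replicates, seed=config.seed,
                model=config.tree_model,
            )
        return nj_tree(pairwise_distance(alignment, config.tree_model))

    unrooted = _build_tree()

    @_stage("rooting")
    def _root() -> TreeNode:
        if config.outgroup:
            rooted = root_with_outgroup(unrooted, set(config.outgroup))
            keep = [t.name for t in rooted.tips() if t.name not in config.outgroup]
            return rooted.shear(keep)
        return unrooted.root_at_midpoint()

    rooted = _root()
    patristic = _stage("patristic")(patristic_distances)(unrooted)

    raw_partitions = _stage("abgd")(abgd_partition)(dm_delim, config.abgd)
    ptp_rooted = _stage("ptp_rooted")(ptp_partition)(
        rooted, rooted=True, n_restarts=config.ptp_restarts, seed=config.seed
    )
    ptp_unrooted = _stage("ptp_unrooted")(ptp_partition)(
        unrooted, rooted=False, n_restarts=config.ptp_restarts, seed=config.seed + 1
    )
    raw_partitions = raw_partitions + [ptp_rooted.partition, ptp_unrooted.partition]
    report["ptp"] = {
        "rooted": {
            "log_likelihood": ptp_rooted.log_likelihood,
            "null_log_likelihood": ptp_rooted.null_log_likelihood,
            "n_units": ptp_rooted.partition.n_units,
        },
        "unrooted": {
            "log_likelihood": ptp_unrooted.log_likelihood,
            "null_log_likelihood": ptp_unrooted.null_log_likelihood,
            "n_units": ptp_unrooted.partition.n_units,
        },
    }

    @_stage("reconcile")
    def _reconcile() -> list[Partition]:
        return [reconcile_with_basegroups(p, basegroups) for p in raw_partitions]

    reconciled = _reconcile()
    n_aggregations = sum(
        1 for raw, rec in zip(raw_partitions, reconciled) if rec.n_units < raw.n_units
    )
    report["partitions"] = {
        "raw": [_partition_summary(p) for p in raw_partitions],
        "reconciled": [_partition_summary(p) for p in reconciled],
        "n_with_basegroup_aggregation": n_aggregations,
    }

    @_stage("lineages")
    def _lineages() -> tuple[Partition, dict]:
        abgd_initial = [
            rec for raw, rec in zip(raw_partitions, reconciled)
            if raw.source == "abgd_initial"
        ]
        ptp_rec = reconciled[len(reconciled) - 2]  # rooted PTP, reconciled
        lineage = choose_lineage_partition(abgd_initial, ptp_rec)
        summary: dict = {"n_before_validation": lineage.n_units}
        if lineage.n_units >= 2 and any(len(m) >= 2 for m in lineage.units().values()):
            rep = validate_partition_patristic(lineage, patristic, config.alpha)
            lineage = merge_invalidated(lineage, rep, patristic)
            summary["n_invalidated"] = len(rep.invalidated_units())
        return lineage, summary

    lineage_partition, lineage_summary = _lineages()

    @_stage("genotypes")
    def _genotypes():
        return choose_genotype_partition(
            reconciled, lineage_partition, patristic, config.alpha
        )

    genotype_partition, genotype_report = _genotypes()

    from .delimit import assemble_nomenclature

    nomenclature = _stage("nomenclature")(assemble_nomenclature)(
        lineage_partition, genotype_partition, basegroups
    )
    report["counts"].update(
        n_lineages=len({v[0] for v in nomenclature.values()}),
        n_genotypes=len({v[1] for v in nomenclature.values()}),
    )
    report["lineage_selection"] = lineage_summary

    assignment = _stage("assign_remaining")(assign_remaining_sequences)(
        ds.records, basetypes, nomenclature, config.min_identity
    )
    report["assignment"] = {
        s: [r.lineage, r.genotype, r.basegroup, r.status]
        for s, r in sorted(assignment.rows.items())
    }
    n_assigned = sum(1 for r in assignment.rows.values() if r.status == "assigned")
    n_unassigned = sum(
        1 for r in assignment.rows.values() if r.status.startswith("unassigned")
    )
    report["counts"].update(n_assigned_remaining=n_assigned, n_unassigned=n_unassigned)

    @_stage("pairwise_tests")
    def _pairwise() -> pd.DataFrame | None:
        unit_map = {b: nomenclature[b][1] for b in nomenclature}
        testable = {}
        for b, u in unit_map.items():
            testable.setdefault(u, []).append(b)
        if sum(1 for m in testable.values() if len(m) >= 2) < 2:
            return None
        return pairwise_unit_tests(patristic, unit_map)

    pairwise_df = _pairwise()

    @_stage("diversification")
    def _diversification() -> dict:
        ultra = ultrametricize(rooted)
        out: dict = {"clades": {}, "ltt": {}}
        clades: dict[str, TreeNode] = {"all": ultra}
        lineage_of = {b: nomenclature[b][0] for b in nomenclature}
        for lab in sorted(set(lineage_of.values())):
            members = [b for b, l in lineage_of.items() if l == lab]
            if len(members) >= config.min_clade_tips:
                clades[lab] = ultra.shear(members)
        for i, (lab, subtree) in enumerate(sorted(clades.items())):
            g = pybus_gamma(subtree)
            nulls, envelope = gamma_null_distribution(
                g.n_tips, config.n_sim_null, seed=config.seed + 1000 * (i + 1)
            )
            null_gammas = np.array([r.gamma for r in nulls])
            out["clades"][lab] = {
                "n_tips": g.n_tips,
                "gamma": g.gamma,
                "null_gamma_mean": float(null_gammas.mean()),
                "null_gamma_quantile_975": float(np.quantile(null_gammas, 0.975)),
                "exceeds_null_975": bool(g.gamma > np.quantile(null_gammas, 0.975)),
            }
            out["ltt"][lab] = ltt_curve(subtree).breakpoints
        named = [lab for lab in clades if lab != "all"]
        named.sort(key=lambda lab: -clades[lab].count(tips=True))
        if len(named) >= 2:
            a, b = named[0], named[1]
            comp = compare_clades_wilcoxon(
                clades[a].count(tips=True), clades[b].count(tips=True),
                n_sim=config.n_sim_wilcoxon, seed=config.seed + 777,
            )
            out["wilcoxon"] = {
                "clade_a": a, "clade_b": b,
                "statistic": comp.statistic, "p_value": comp.p_value,
                "n_sim": comp.n_sim,
            }
        return out

    report["diversification"] = _diversification()

    @_stage("geography")
    def _geography() -> dict:
        specimen_site = {r.specimen_id: r.site_id for r in ds.records}
        site_tips: dict[str, set[str]] = {s: set() for s in sites}
        for bt in basetypes:
            for sp in bt.specimen_ids:
                site_tips[specimen_site[sp]].add(bt.basetype_id)
        overrides = {
            frozenset(k) if not isinstance(k, frozenset) else k: v
            for k, v in config.routing_overrides.items()
        }
        pairs = build_pair_table(
            sites, site_tips, patristic, overrides, config.include_sites
        )
        fit = fit_regression(pairs, band=config.band)
        classified = classify_dispersion(pairs, fit)
        counts = {"underdispersed": 0, "consistent": 0, "overdispersed": 0}
        for p in classified:
            counts[p.dispersion] += 1
        # per-site genotype table (from the full assignment, for the
        # mutual-exclusion check)
        site_genotypes: dict[str, set[str]] = {}
        for r in ds.records:
            row = assignment.rows[r.sequence_id]
            if row.genotype != "unassigned":
                site_genotypes.setdefault(r.site_id, set()).add(row.genotype)
        return {
            "n_pairs": len(classified),
            "regression": dataclasses.asdict(fit),
            "dispersion_counts": counts,
            "pairs": [dataclasses.asdict(p) for p in classified],
            "site_genotypes": {s: sorted(g) for s, g in sorted(site_genotypes.items())},
        }

    report["geography"] = _geography()

    if outdir is not None:
        _write_outputs(
            Path(outdir), report, basetypes, basegroups, nomenclature, assignment,
            reconciled, genotype_report, pairwise_df, unrooted, rooted,
        )
    return report


def _jsonable_config(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    out["routing_overrides"] = {
        "|".join(sorted(k)): list(map(list, v)) for k, v in config.routing_overrides.items()
    }
    return out


def _write_outputs(
    outdir, report, basetypes, basegroups, nomenclature, assignment,
    reconciled, genotype_report, pairwise_df, unrooted, rooted,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "basetype_id": b.basetype_id, "count": b.occurrence_count,
                "n_specimens": len(b.specimen_ids), "sequence": b.nucleotides,
            }
            for b in basetypes
        ]
    ).to_csv(outdir / "basetypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "basegroup_id": g.basegroup_id, "label": g.label,
                "basetypes": ",".join(sorted(g.basetype_ids)),
            }
            for g in basegroups
        ]
    ).to_csv(outdir / "basegroups.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"basetype_id": b, "lineage": v[0], "genotype": v[1], "basegroup": v[2]}
            for b, v in sorted(nomenclature.items())
        ]
    ).to_csv(outdir / "nomenclature.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(r) for _, r in sorted(assignment.rows.items())]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    rows = []
    for p in reconciled:
        for label, unit in sorted(p.assignment.items()):
            rows.append(
                {
                    "basetype_id": label, "unit": unit, "source": p.source,
                    "parameters": json.dumps(p.parameters, sort_keys=True, default=str),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "partitions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(v) for v in genotype_report.verdicts.values()]
    ).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    if pairwise_df is not None:
        pairwise_df.to_csv(outdir / "pairwise_unit_tests.tsv", sep="\t", index=False)
    pd.DataFrame(report["geography"]["pairs"]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )
    (outdir / "regression.json").write_text(
        json.dumps(report["geography"]["regression"], indent=1, sort_keys=True)
    )
    rio.write_newick(unrooted, outdir / "tree_unrooted.nwk")
    rio.write_newick(rooted, outdir / "tree_rooted.nwk")
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=str), encoding="utf-8"
    )
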