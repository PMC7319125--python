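"""Partition reconciliation, patristic validation, merging, nomenclature."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from ribotax.abgd import Partition, make_partition
from ribotax.delimit import (
    assemble_nomenclature,
    choose_lineage_partition,
    merge_invalidated,
    pairwise_unit_tests,
    reconcile_with_basegroups,
    refines,
    validate_partition_patristic,
)
from ribotax.taxonomy import Basegroup


def _bg(bid, members):
    return Basegroup(bid, frozenset(members))


def _partition(blocks, source="abgd_initial"):
    return make_partition([set(b) for b in blocks], source)


class TestReconcile:
    def test_basegroup_split_merged(self):
        p = _partition([{"b1"}, {"b2"}, {"b3"}])
        merged = reconcile_with_basegroups(p, [_bg("g1", {"b1", "b2"})])
        units = merged.units()
        assert len(units) == 2
        assert any(m == {"b1", "b2"} for m in units.values())
        assert merged.source == "merged"

    def test_no_split_identity(self):
        p = _partition([{"b1", "b2"}, {"b3"}])
        out = reconcile_with_basegroups(p, [_bg("g1", {"b1", "b2"})])
        assert out is p

    def test_transitive_chain_merges_all(self):
        p = _partition([{"b1"}, {"b2"}, {"b3"}])
        out = reconcile_with_basegroups(
            p, [_bg("g1", {"b1", "b2"}), _bg("g2", {"b2", "b3"})]
        )
        assert out.n_units == 1

    def test_never_increases_unit_count(self):
        rng = np.random.default_rng(0)
        labels = [f"b{i}" for i in range(12)]
        for trial in range(10):
            blocks: dict[int, set] = {}
            for lab in labels:
                blocks.setdefault(int(rng.integers(0, 5)), set()).add(lab)
            p = _partition(list(blocks.values()))
            groups = [
                _bg(f"g{j}", rng.choice(labels, size=3, replace=False))
                for j in range(3)
            ]
            out = reconcile_with_basegroups(p, groups)
            assert out.n_units <= p.n_units


def _two_scale_matrix(sizes, within=(0.001, 0.005), between=(0.05, 0.09), seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = [f"b{i:02d}" for i in range(n)]
    block = np.repeat(np.arange(len(sizes)), sizes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = within if block[i] == block[j] else between
            m[i, j] = m[j, i] = rng.uniform(lo, hi)
    blocks = [
        {labels[i] for i in range(n) if block[i] == k} for k in range(len(sizes))
    ]
    return DistanceMatrix(m, labels), blocks


class TestValidation:
    def test_separated_units_validated(self):
        dm, blocks = _two_scale_matrix([7, 7])
        p = _partition(blocks)
        report = validate_partition_patristic(p, dm)
        assert report.all_validated
        for v in report.verdicts.values():
            assert v.median_inter > v.median_intra
            assert v.ks_p < 0.05 and v.mw_p < 0.05

    def test_identical_distributions_not_validated(self):
        dm, blocks = _two_scale_matrix([7, 7], within=(0.01, 0.05), between=(0.01, 0.05))
        p = _partition(blocks)
        report = validate_partition_patristic(p, dm)
        assert not report.all_validated

    def test_singleton_unit_flagged(self):
        dm, blocks = _two_scale_matrix([7, 7])
        one = sorted(blocks[1])[0]
        p = _partition([blocks[0], blocks[1] - {one}, {one}])
        report = validate_partition_patristic(p, dm)
        singleton_unit = p.assignment[one]
        assert not report.verdicts[singleton_unit].validated
        assert report.verdicts[singleton_unit].reason == "too_few_members"

    def test_all_singletons_error(self):
        dm, _ = _two_scale_matrix([2, 2])
        p = _partition([{l} for l in dm.ids])
        with pytest.raises(ValueError):
            validate_partition_patristic(p, dm)


class TestMergeInvalidated:
    def test_singleton_merged_into_nearest(self):
        dm, blocks = _two_scale_matrix([7, 7])
        one = sorted(blocks[1])[0]
        p = _partition([blocks[0], blocks[1] - {one}, {one}])
        report = validate_partition_patristic(p, dm)
        merged = merge_invalidated(p, report, dm)
        assert merged.n_units == 2
        # the singleton joined its own block, not the distant one
        units = merged.units()
        assert any(m == frozenset(blocks[1]) for m in units.values())

    def test_no_invalidated_identity(self):
        dm, blocks = _two_scale_matrix([7, 7])
        p = _partition(blocks)
        report = validate_partition_patristic(p, dm)
        assert merge_invalidated(p, report, dm) is p

    def test_two_invalidated_merge_together(self):
        dm, blocks = _two_scale_matrix([8, 2])
        a, b = sorted(blocks[1])
        p = _partition([blocks[0], {a}, {b}])
        report = validate_partition_patristic(p, dm)
        merged = merge_invalidated(p, report, dm)
        units = merged.units()
        assert any({a, b} <= m for m in units.values())

    def test_never_increases_unit_count(self):
        dm, blocks = _two_scale_matrix([5, 5, 2])
        p = _partition(blocks)
        report = validate_partition_patristic(p, dm)
        merged = merge_invalidated(p, report, dm)
        assert merged.n_units <= p.n_units


class TestNomenclature:
    def test_four_lineages_with_nested_genotypes(self):
        # lineage sizes 6, 12 (3 genotypes), 2, 1 -> I..IV by size
        lineages = [
            {f"x{i}" for i in range(12)},        # -> I (largest)
            {f"y{i}" for i in range(6)},         # -> II
            {"z0", "z1"},                        # -> III
            {"w0"},                              # -> IV
        ]
        genotypes = [
            {f"x{i}" for i in range(5)},
            {f"x{i}" for i in range(5, 9)},
            {f"x{i}" for i in range(9, 12)},
            lineages[1], lineages[2], lineages[3],
        ]
        lp = _partition(lineages)
        gp = _partition(genotypes)
        groups = [_bg("g1", {"x0", "x1"}), _bg("g2", {"y0"})]
        nom = assemble_nomenclature(lp, gp, groups)
        assert nom["x0"][0] == "I"
        assert {nom[f"x{i}"][1] for i in range(12)} == {"Ia", "Ib", "Ic"}
        assert nom["y0"][:2] == ("II", "IIa")
        assert nom["z0"][0] == "III"
        assert nom["w0"][:2] == ("IV", "IVa")
        assert nom["x0"][2] == "Ia1"

    def test_single_lineage_single_genotype(self):
        lp = _partition([{"a", "b"}])
        gp = _partition([{"a", "b"}])
        nom = assemble_nomenclature(lp, gp, [_bg("g1", {"a", "b"})])
        assert nom["a"] == ("I", "Ia", "Ia1")

    def test_straddling_genotype_split(self):
        lp = _partition([{"a", "b"}, {"c", "d"}])
        gp = _partition([{"a", "b", "c"}, {"d"}])
        nom = assemble_nomenclature(lp, gp, [_bg("g1", {"a"})])
        assert nom["a"][1] != nom["c"][1]  # split along the lineage boundary

    def test_empty_partition_error(self):
        with pytest.raises(ValueError):
            assemble_nomenclature(
                Partition({}, "x"), Partition({}, "x"), []
            )


class TestPairwiseUnitTests:
    def test_separated_units_significant(self):
        dm, blocks = _two_scale_matrix([8, 8])
        unit_map = {m: f"u{k}" for k, b in enumerate(blocks) for m in b}
        table = pairwise_unit_tests(dm, unit_map)
        row = table[table["note"] == ""].iloc[0]
        assert row["p_adjusted"] < 0.05 and row["significant"]

    def test_same_distribution_not_significant(self):
        dm, blocks = _two_scale_matrix(
            [8, 8], within=(0.01, 0.05), between=(0.01, 0.05), seed=3
        )
        unit_map = {m: f"u{k}" for k, b in enumerate(blocks) for m in b}
        table = pairwise_unit_tests(dm, unit_map)
        assert table[table["note"] == ""].iloc[0]["p_adjusted"] > 0.05

    def test_bonferroni_factor(self):
        # adjustment multiplies by the number of pairs and caps at 1
        dm, blocks = _two_scale_matrix([5, 5, 5, 5, 5])
        unit_map = {m: f"u{k}" for k, b in enumerate(blocks) for m in b}
        table = pairwise_unit_tests(dm, unit_map)
        tested = table[table["note"] == ""]
        assert len(tested) == 10
        for _, row in tested.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                min(1.0, 10 * row["p_value"])
            )

    def test_small_unit_excluded_with_note(self):
        dm, blocks = _two_scale_matrix([7, 7])
        one = sorted(blocks[1])[0]
        unit_map = {m: "u0" for m in blocks[0]}
        unit_map.update({m: "u1" for m in blocks[1] - {one}})
        unit_map[one] = "u2"
        table = pairwise_unit_tests(dm, unit_map)
        assert (table["note"] != "").sum() == 1


class TestLevelSelection:
    def test_refines(self):
        fine = _partition([{"a"}, {"b"}, {"c", "d"}])
        coarse = _partition([{"a", "b"}, {"c", "d"}])
        assert refines(fine, coarse)
        assert not refines(coarse, fine)

    def test_coarsest_supported_by_ptp_chosen(self):
        ptp = _partition([{"a"}, {"b"}, {"c"}, {"d"}], source="ptp_rooted")
        cand_bad = _partition([{"a", "c"}, {"b", "d"}])  # not refined by... (it is)
        cand_good = _partition([{"a", "b"}, {"c", "d"}])
        fine = _partition([{"a"}, {"b"}, {"c", "d"}])
        # ptp (all singletons) refines everything; coarsest candidate wins
        chosen = choose_lineage_partition([fine, cand_good], ptp)
        assert chosen is cand_good

    def test_non_refining_candidates_skipped(self):
        ptp = _partition([{"a", "b"}, {"c", "d"}], source="ptp_rooted")
        straddling = _partition([{"a", "c"}, {"b", "d"}])
        compatible = _partition([{"a", "b"}, {"c", "d"}])
        chosen = choose_lineage_partition([straddling, compatible], ptp)
        assert chosen is compatible
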