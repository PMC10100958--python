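from __future__ import annotations

import numpy as np
import pytest

from pairomics.indirect import DeltaTable
from pairomics.io_formats import (
    FeatureTable,
    Group,
    IndicatorCategory,
    Layer,
    SampleKey,
    SnvCallSet,
    SnvKey,
    Timepoint,
)
from pairomics.snv import (
    GAINED,
    LOST,
    TemporalSnvChange,
    correlate_snv_immunity,
    group_candidate_snvs,
    host_temporal_changes,
    species_categorize,
    venn_subtract,
)

from conftest import make_table


def key(pos: int, sgb: str = "SGB0001") -> SnvKey:
    return SnvKey(sgb, f"{sgb}_c1", pos, "A", "G")


def callset(subject: str, tp: Timepoint, positions, group=Group.PLACEBO) -> SnvCallSet:
    return SnvCallSet(
        SampleKey(subject, group, tp), frozenset(key(p) for p in positions)
    )


class TestHostTemporalChanges:
    def test_identical_callsets_empty(self):
        a = callset("A", Timepoint.BASELINE, [1, 2, 3])
        b = callset("A", Timepoint.ENDLINE, [1, 2, 3])
        assert host_temporal_changes(a, b) == frozenset()

    def test_gain(self):
        a = callset("A", Timepoint.BASELINE, [1])
        b = callset("A", Timepoint.ENDLINE, [1, 2])
        changes = host_temporal_changes(a, b)
        assert changes == frozenset({TemporalSnvChange("A", key(2), GAINED)})

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(61)
        base_pos = set(rng.choice(1000, 100, replace=False).tolist())
        end_pos = set(rng.choice(1000, 100, replace=False).tolist())
        a = callset("A", Timepoint.BASELINE, base_pos)
        b = callset("A", Timepoint.ENDLINE, end_pos)
        changes = host_temporal_changes(a, b)
        expected = set()
        for p in base_pos | end_pos:  # brute-force membership scan
            if p in end_pos and p not in base_pos:
                expected.add(TemporalSnvChange("A", key(p), GAINED))
            elif p in base_pos and p not in end_pos:
                expected.add(TemporalSnvChange("A", key(p), LOST))
        assert changes == frozenset(expected)

    def test_subject_mismatch_rejected(self):
        a = callset("A", Timepoint.BASELINE, [1])
        b = callset("B", Timepoint.ENDLINE, [1])
        with pytest.raises(ValueError, match="different subjects"):
            host_temporal_changes(a, b)

    def test_same_timepoint_rejected(self):
        a = callset("A", Timepoint.BASELINE, [1])
        b = callset("A", Timepoint.BASELINE, [1])
        with pytest.raises(ValueError, match="same timepoint"):
            host_temporal_changes(a, b)


def changes_map(spec: dict[str, list[int]], direction=GAINED):
    return {
        subject: {TemporalSnvChange(subject, key(p), direction) for p in positions}
        for subject, positions in spec.items()
    }


class TestGroupCandidates:
    def test_inclusive_boundary_30_percent(self):
        spec = {f"S{i}": ([7] if i < 3 else []) for i in range(10)}
        out = group_candidate_snvs(changes_map(spec), Group.PLACEBO, 0.30)
        assert out.snvs == frozenset({key(7)})
        assert out.support_fraction[key(7)] == pytest.approx(0.3)

    def test_below_threshold_dropped(self):
        spec = {f"S{i}": ([7] if i < 2 else []) for i in range(10)}
        out = group_candidate_snvs(changes_map(spec), Group.PLACEBO, 0.30)
        assert out.snvs == frozenset()

    def test_gained_only_scope(self):
        spec = {f"S{i}": [7] for i in range(10)}
        lost = changes_map(spec, direction=LOST)
        out = group_candidate_snvs(lost, Group.PLACEBO, 0.30, direction_scope="gained")
        assert out.snvs == frozenset()
        out = group_candidate_snvs(lost, Group.PLACEBO, 0.30, direction_scope="either")
        assert out.snvs == frozenset({key(7)})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no paired subjects"):
            group_candidate_snvs({}, Group.PLACEBO)


class TestVennSubtract:
    def _sets(self, pro_pos, pla_pos):
        pro = group_candidate_snvs(
            changes_map({"P1": pro_pos}), Group.PROBIOTIC, 0.0001
        )
        pla = group_candidate_snvs(
            changes_map({"Q1": pla_pos}), Group.PLACEBO, 0.0001
        )
        return pro, pla

    def test_disjoint(self):
        res = venn_subtract(*self._sets([1, 2], [3, 4]))
        assert res.shared == frozenset()
        assert res.unique_probiotic == frozenset({key(1), key(2)})

    def test_equal_inputs(self):
        res = venn_subtract(*self._sets([1, 2], [1, 2]))
        assert res.unique_probiotic == frozenset()
        assert res.unique_placebo == frozenset()
        assert res.shared == frozenset({key(1), key(2)})

    def test_random_matches_brute_force(self):
        rng = np.random.default_rng(62)
        pro_pos = set((rng.choice(500, 200, replace=False) + 1).tolist())
        pla_pos = set((rng.choice(500, 200, replace=False) + 1).tolist())
        res = venn_subtract(*self._sets(pro_pos, pla_pos))
        # brute-force oracle over the union
        u_pro, u_pla, shared = set(), set(), set()
        for p in pro_pos | pla_pos:
            if p in pro_pos and p in pla_pos:
                shared.add(key(p))
            elif p in pro_pos:
                u_pro.add(key(p))
            else:
                u_pla.add(key(p))
        assert res.unique_probiotic == frozenset(u_pro)
        assert res.unique_placebo == frozenset(u_pla)
        assert res.shared == frozenset(shared)

    def test_partition_invariant(self):
        rng = np.random.default_rng(63)
        pro_pos = set((rng.choice(100, 40, replace=False) + 1).tolist())
        pla_pos = set((rng.choice(100, 40, replace=False) + 1).tolist())
        res = venn_subtract(*self._sets(pro_pos, pla_pos))
        union = res.unique_probiotic | res.unique_placebo | res.shared
        assert union == frozenset(key(p) for p in pro_pos | pla_pos)
        assert len(union) == (
            len(res.unique_probiotic) + len(res.unique_placebo) + len(res.shared)
        )


def abundance_table(sgbs):
    n_feat = len(sgbs)
    X = np.full((4, n_feat), 1.0 / n_feat)
    return make_table(X, layer=Layer.BACTERIA, feature_ids=sgbs, n_per_group=1)


class TestSpeciesCategorize:
    def _result(self, pro_keys, pla_keys):
        pro = group_candidate_snvs(
            {"P1": {TemporalSnvChange("P1", k, GAINED) for k in pro_keys}},
            Group.PROBIOTIC, 0.0001,
        )
        pla = group_candidate_snvs(
            {"Q1": {TemporalSnvChange("Q1", k, GAINED) for k in pla_keys}},
            Group.PLACEBO, 0.0001,
        )
        return venn_subtract(pro, pla)

    def test_single_species_rank_one(self):
        res = self._result([key(1), key(2)], [])
        table = species_categorize(
            res, {"SGB0001": "sp1"}, abundance_table(["SGB0001"])
        )
        assert list(table.index) == ["sp1"]
        assert table["rank_probiotic"].iloc[0] == 1.0
        assert np.isnan(table["rank_placebo"].iloc[0])

    def test_tied_counts_share_dense_rank(self):
        res = self._result(
            [key(1, "SGB0001"), key(2, "SGB0002")], []
        )
        table = species_categorize(
            res, {"SGB0001": "sp1", "SGB0002": "sp2"},
            abundance_table(["SGB0001", "SGB0002"]),
        )
        assert set(table["rank_probiotic"]) == {1.0}

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(64)
        sgbs = [f"SGB{i:04d}" for i in range(1, 6)]
        species = {s: f"sp{(i % 3) + 1}" for i, s in enumerate(sgbs)}
        pro_keys = [key(int(p), rng.choice(sgbs)) for p in rng.choice(10_000, 30, replace=False)]
        pla_keys = [key(int(p), rng.choice(sgbs)) for p in rng.choice(20_000, 40, replace=False) + 10_000]
        res = self._result(pro_keys, pla_keys)
        table = species_categorize(res, species, abundance_table(sgbs), top_k=None)
        for sp in table.index:
            expected_pro = sum(1 for k in res.unique_probiotic if species[k.sgb_id] == sp)
            expected_pla = sum(1 for k in res.unique_placebo if species[k.sgb_id] == sp)
            assert table.loc[sp, "n_probiotic"] == expected_pro
            assert table.loc[sp, "n_placebo"] == expected_pla

    def test_unmapped_sgb_rejected(self):
        res = self._result([key(1)], [])
        with pytest.raises(ValueError, match="SGB0001"):
            species_categorize(res, {}, abundance_table(["SGB0001"]))


class TestSnvImmunity:
    def _setup(self, rng, n=20, couple=True):
        pro_key = key(1, "SGB0001")
        subjects = [f"P{i}" for i in range(n)]
        carriers = set(subjects[: n // 2])
        changes = {
            s: ({TemporalSnvChange(s, pro_key, GAINED)} if s in carriers else set())
            for s in subjects
        }
        x = np.array([1.0 if s in carriers else 0.0 for s in subjects])
        values = rng.normal(0, 1, (n, 3))
        if couple:
            values[:, 0] += 2.5 * x
        deltas = DeltaTable(
            group=Group.PROBIOTIC, subjects=subjects,
            ids=["CYT001", "CBC001", "LYM001"], values=values,
        )
        cats = {
            "CYT001": IndicatorCategory.CYTOKINE,
            "CBC001": IndicatorCategory.CBC,
            "LYM001": IndicatorCategory.LYMPHOCYTE,
        }
        pro = group_candidate_snvs(changes, Group.PROBIOTIC, 0.0001)
        pla = group_candidate_snvs(
            changes_map({"Q1": [99]}), Group.PLACEBO, 0.0001
        )
        res = venn_subtract(pro, pla)
        pla_subjects = ["Q1"] + [f"Q{i}" for i in range(2, n + 1)]
        pla_changes = {s: set() for s in pla_subjects}
        pla_changes["Q1"] = {TemporalSnvChange("Q1", key(99), GAINED)}
        pla_deltas = DeltaTable(
            group=Group.PLACEBO, subjects=pla_subjects, ids=list(deltas.ids),
            values=rng.normal(0, 1, (n, 3)),
        )
        return res, {Group.PROBIOTIC: changes, Group.PLACEBO: pla_changes}, {
            Group.PROBIOTIC: deltas, Group.PLACEBO: pla_deltas,
        }, cats

    def test_planted_coupling_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(700 + rep)
            res, changes, deltas, cats = self._setup(rng, n=45)
            assoc = correlate_snv_immunity(res, changes, deltas, cats)
            pro_edges = assoc.edges[assoc.edges["group"] == "probiotic"]
            hits += (pro_edges["indicator"] == "CYT001").any()
        assert hits >= 8

    def test_alpha_zero_no_edges(self):
        rng = np.random.default_rng(65)
        res, changes, deltas, cats = self._setup(rng)
        assoc = correlate_snv_immunity(res, changes, deltas, cats, alpha=0.0)
        assert assoc.edges.empty
        assert (assoc.category_summary["n_snvs"] == 0).all()

    def test_constant_encoding_skipped(self):
        rng = np.random.default_rng(66)
        res, changes, deltas, cats = self._setup(rng)
        # no probiotic subject carries the change -> constant zero encoding
        for s in changes[Group.PROBIOTIC]:
            changes[Group.PROBIOTIC][s] = set()
        assoc = correlate_snv_immunity(res, changes, deltas, cats)
        assert assoc.n_skipped_constant[Group.PROBIOTIC] == 1
        assert assoc.edges[assoc.edges["group"] == "probiotic"].empty
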