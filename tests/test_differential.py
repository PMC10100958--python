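from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

from pairomics.differential import (
    CLASS_TIME,
    CLASS_TREATMENT,
    CLASS_UNCHANGED,
    bh_fdr,
    clr_transform,
    direct_influence_summary,
    metabolite_qc,
    paired_change_test,
    time_effect_subtraction,
)
from pairomics.io_formats import Group, Layer, Timepoint

from conftest import make_table


class TestMetaboliteQc:
    def test_per_group_prevalence_rule(self):
        # feature 0: >=1000 in 25% of placebo samples but only 0% of probiotic
        n = 4  # 8 samples per group
        X = np.full((4 * n, 2), 500.0)
        X[:, 1] = 2000.0  # feature 1 passes everywhere
        X[0, 0] = 2000.0
        X[2, 0] = 2000.0  # 2/8 placebo samples = 25%
        table = make_table(X, layer=Layer.METABOLITE, n_per_group=n)
        filtered, report = metabolite_qc(table, min_prevalence=0.20, max_rsd=10.0)
        assert filtered.feature_ids == ["F002"]
        assert report.n_removed_prevalence == 1

    def test_constant_feature_retained(self):
        X = np.full((4, 1), 5000.0)
        table = make_table(X, layer=Layer.METABOLITE)
        filtered, report = metabolite_qc(table)
        assert filtered.n_features == 1 and report.n_removed_rsd == 0

    def test_rsd_matches_hand_arithmetic(self):
        rng = np.random.default_rng(31)
        X = np.abs(rng.normal(5000.0, 1500.0, (8, 20))) + 1000.0
        table = make_table(X, layer=Layer.METABOLITE, n_per_group=2)
        _, report = metabolite_qc(table, max_rsd=0.25)
        expected_removed = 0
        for j in range(20):
            col = X[:, j]
            if col.std(ddof=1) / col.mean() > 0.25:
                expected_removed += 1
        assert report.n_removed_rsd == expected_removed
        assert report.n_features_out == 20 - expected_removed

    def test_wrong_layer_rejected(self):
        table = make_table(np.full((4, 2), 0.5), layer=Layer.BACTERIA)
        with pytest.raises(ValueError, match="metabolite layer"):
            metabolite_qc(table)

    def test_accounting_order(self):
        # one feature fails intensity outright, one fails prevalence, one RSD
        X = np.array(
            [[500.0, 2000.0, 4000.0],
             [400.0, 900.0, 100.0],
             [300.0, 900.0, 4100.0],
             [200.0, 900.0, 90.0]]
        )
        table = make_table(X, layer=Layer.METABOLITE)
        _, report = metabolite_qc(table, min_prevalence=0.6, max_rsd=0.2)
        assert report.n_removed_intensity == 1
        assert report.n_removed_prevalence >= 1
        assert report.n_features_in == 3
        assert report.n_features_out == (
            3 - report.n_removed_intensity - report.n_removed_prevalence
            - report.n_removed_rsd
        )


class TestClr:
    def test_constant_composition_zero(self):
        table = make_table(np.ones((4, 3)), layer=Layer.METABOLITE)
        out = clr_transform(table)
        assert np.allclose(out.values, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(32)
        X = rng.random((4, 6)) + 0.1
        a = clr_transform(make_table(X, layer=Layer.METABOLITE))
        b = clr_transform(make_table(3.7 * X, layer=Layer.METABOLITE))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_rows_sum_to_zero_and_match_formula(self):
        rng = np.random.default_rng(33)
        X = rng.random((4, 8)) + 0.05
        out = clr_transform(make_table(X, layer=Layer.METABOLITE))
        assert np.allclose(out.values.sum(axis=1), 0.0, atol=1e-9)
        expected = np.log(X[0]) - np.log(X[0]).mean()
        assert np.allclose(out.values[0], expected, atol=1e-12)

    def test_zero_replacement_preserves_total(self):
        X = np.array([[0.0, 2.0, 3.0, 5.0]])
        from pairomics.differential import multiplicative_pseudocount

        row = multiplicative_pseudocount(X[0])
        assert row[0] == pytest.approx(0.65 * 2.0)
        assert row.sum() == pytest.approx(X[0].sum())

    def test_all_zero_sample_rejected(self):
        X = np.vstack([np.zeros(3), np.ones((3, 3))])
        table = make_table(X, layer=Layer.METABOLITE)
        with pytest.raises(ValueError, match="all zeros"):
            clr_transform(table)

    def test_output_scale_flag(self):
        table = make_table(np.ones((4, 3)) * 2, layer=Layer.METABOLITE)
        assert clr_transform(table).scale == "clr"


def exhaustive_signed_rank_p(diffs: np.ndarray) -> float:
    """Independent oracle: full 2^n sign-flip enumeration of the W statistic."""
    d = diffs[diffs != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        count += w <= w_obs + 1e-12
    return count / 2 ** n


class TestPairedChangeTest:
    def _table(self, base: np.ndarray, end: np.ndarray) -> object:
        n, f = base.shape
        values = np.empty((2 * n, f))
        values[0::2] = base
        values[1::2] = end
        full = np.vstack([values, values])  # mirror into the probiotic arm
        return make_table(full, layer=Layer.METABOLITE, n_per_group=n)

    def test_no_change_p_one(self):
        rng = np.random.default_rng(41)
        base = rng.random((8, 3)) + 1
        table = self._table(base, base.copy())
        res = paired_change_test(table, Group.PLACEBO)
        assert (res["p"] == 1.0).all()
        assert (res["direction"] == "none").all()

    def test_uniform_shift_minimal_p(self):
        rng = np.random.default_rng(42)
        base = rng.random((20, 1)) + 1
        # strictly positive, tie-free differences -> exact minimal p
        shift = np.linspace(0.5, 1.5, 20)[:, None]
        table = self._table(base, base + shift)
        res = paired_change_test(table, Group.PLACEBO)
        # minimal attainable two-sided exact p for n=20 is 2/2^20
        assert res["p"].iloc[0] == pytest.approx(2 / 2 ** 20)
        assert res["direction"].iloc[0] == "up"

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(43)
        diffs = rng.normal(0.4, 1.0, 10)
        base = np.abs(rng.normal(5, 1, (10, 1))) + 1
        table = self._table(base, base + diffs[:, None])
        res = paired_change_test(table, Group.PLACEBO)
        assert res["p"].iloc[0] == pytest.approx(exhaustive_signed_rank_p(diffs), abs=1e-12)

    def test_median_change_fraction(self):
        base = np.full((6, 1), 2.0)
        end = np.full((6, 1), 2.5)
        res = paired_change_test(self._table(base, end), Group.PLACEBO)
        assert res["median_change_fraction"].iloc[0] == pytest.approx(0.25)

    def test_too_few_subjects(self):
        base = np.ones((3, 2))
        with pytest.raises(ValueError, match="at least 6"):
            paired_change_test(self._table(base, base), Group.PLACEBO)


def _res(features, ps, meds):
    return pd.DataFrame(
        {"p": ps, "median_diff": meds, "direction": "x",
         "median_change_fraction": np.nan},
        index=pd.Index(features, name="feature"),
    )


class TestTimeEffectSubtraction:
    def test_same_way_both_groups_is_time_effect(self):
        out = time_effect_subtraction(
            _res(["f"], [0.01], [1.0]), _res(["f"], [0.02], [2.0])
        )
        assert out["classification"].iloc[0] == CLASS_TIME

    def test_probiotic_only_is_treatment(self):
        out = time_effect_subtraction(
            _res(["f"], [0.8], [0.1]), _res(["f"], [0.01], [1.0])
        )
        assert out["classification"].iloc[0] == CLASS_TREATMENT

    def test_opposite_directions_is_treatment(self):
        out = time_effect_subtraction(
            _res(["f"], [0.01], [1.0]), _res(["f"], [0.01], [-1.0])
        )
        assert out["classification"].iloc[0] == CLASS_TREATMENT

    def test_placebo_only_default_vs_strict(self):
        pla, pro = _res(["f"], [0.01], [1.0]), _res(["f"], [0.9], [0.0])
        assert time_effect_subtraction(pla, pro)["classification"].iloc[0] == CLASS_TREATMENT
        assert (
            time_effect_subtraction(pla, pro, strict=True)["classification"].iloc[0]
            == CLASS_UNCHANGED
        )

    def test_unchanged(self):
        out = time_effect_subtraction(
            _res(["f"], [0.5], [1.0]), _res(["f"], [0.6], [1.0])
        )
        assert out["classification"].iloc[0] == CLASS_UNCHANGED

    def test_time_effect_symmetric_in_groups(self):
        rng = np.random.default_rng(44)
        feats = [f"f{i}" for i in range(30)]
        a = _res(feats, rng.random(30), rng.normal(size=30))
        b = _res(feats, rng.random(30), rng.normal(size=30))
        ab = time_effect_subtraction(a, b)["classification"] == CLASS_TIME
        ba = time_effect_subtraction(b, a)["classification"] == CLASS_TIME
        assert (ab == ba).all()

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes differ"):
            time_effect_subtraction(
                _res(["f1"], [0.5], [1.0]), _res(["f2"], [0.5], [1.0])
            )


class TestDirectInfluence:
    def _classified(self, features, classes):
        return pd.DataFrame(
            {"classification": classes}, index=pd.Index(features, name="feature")
        )

    def test_zero_differential(self):
        table = make_table(np.full((4, 3), 1 / 3), layer=Layer.FUNGI)
        diff = self._classified(table.feature_ids, [CLASS_UNCHANGED] * 3)
        s = direct_influence_summary(diff, table)
        assert (s.n_differential, s.proportion) == (0, 0.0)

    def test_all_differential(self):
        table = make_table(np.full((4, 4), 0.25), layer=Layer.FUNGI)
        diff = self._classified(table.feature_ids, [CLASS_TREATMENT] * 4)
        s = direct_influence_summary(diff, table)
        assert s.count_ratio == 1.0
        assert s.proportion == pytest.approx(1.0)

    def test_hand_summed_proportion(self):
        rng = np.random.default_rng(45)
        X = rng.random((4, 10))
        X = X / X.sum(axis=1, keepdims=True)
        table = make_table(X, layer=Layer.FUNGI)
        classes = [CLASS_TREATMENT] * 3 + [CLASS_UNCHANGED] * 7
        diff = self._classified(table.feature_ids, classes)
        s = direct_influence_summary(diff, table)
        sub_rows = [
            i for i, k in enumerate(table.sample_keys)
            if k.group is Group.PROBIOTIC and k.timepoint is Timepoint.ENDLINE
        ]
        expected = X[sub_rows][:, :3].mean(axis=0).sum()
        assert s.proportion == pytest.approx(expected, abs=1e-12)
        assert s.count_ratio == pytest.approx(0.3)


def test_bh_fdr_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(46)
    p = rng.random(50)
    expected = sm.multipletests(p, method="fdr_bh")[1]
    assert np.allclose(bh_fdr(p), expected, atol=1e-12)
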