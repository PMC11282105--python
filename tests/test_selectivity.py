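"""ROC/DI computation, permutation nulls, population comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texdisc.selectivity import (compare_fractions, compute_di_table,
                                 discrimination_index, encoding_model,
                                 permutation_significance, roc_auc,
                                 selectivity_fractions, slope_comparison)


def mann_whitney_auc(a, b):
    """Brute-force pairwise-comparison oracle with ties counted one half."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / a.size / b.size)


class TestRocAuc:
    def test_identical_distributions(self):
        x = [0.0, 1.0, 2.0, 3.0]
        assert roc_auc(x, x) == pytest.approx(0.5, abs=1e-12)

    def test_complete_separation(self):
        assert roc_auc([2, 3, 4], [0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert roc_auc([0, 1], [2, 3, 4]) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_constant(self):
        assert roc_auc([1.0, 1.0], [1.0, 1.0]) == 0.5

    def test_mann_whitney_oracle(self, rng):
        # lattice-valued responses: exact ties likely, near-ties (below the
        # threshold sweep's resolution) impossible
        for _ in range(50):
            na, nb = rng.integers(2, 21, size=2)
            a = np.round(np.clip(rng.normal(0.5, 1.0, na), -3, 3), 2)
            b = np.round(np.clip(rng.normal(0.0, 1.0, nb), -3, 3), 2)
            assert abs(roc_auc(a, b) - mann_whitney_auc(a, b)) < 0.01

    def test_rank_method_is_exact_mann_whitney(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 12)
        assert roc_auc(a, b, method="rank") == pytest.approx(
            mann_whitney_auc(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=10),
           st.lists(st.floats(-5, 5), min_size=2, max_size=10))
    def test_complement_symmetry(self, a, b):
        assert roc_auc(a, b) + roc_auc(b, a) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        """DI matches the rank statistic under a strictly increasing transform."""
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 15)
        direct = roc_auc(a, b, method="rank")
        warped = roc_auc(np.exp(a), np.exp(b), method="rank")
        assert direct == pytest.approx(warped, abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestDiscriminationIndex:
    @pytest.mark.parametrize("auc,di", [(0.5, 0.0), (1.0, 1.0), (0.0, -1.0),
                                        (0.75, 0.5)])
    def test_affine_map(self, auc, di):
        assert discrimination_index(auc) == pytest.approx(di)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            discrimination_index(1.2)


class TestPermutation:
    def test_determinism(self, rng):
        a = rng.normal(1, 1, 15)
        b = rng.normal(0, 1, 15)
        r1 = permutation_significance(a, b, seed=7)
        r2 = permutation_significance(a, b, seed=7)
        assert (r1.perm_lo, r1.perm_hi, r1.significant) == \
               (r2.perm_lo, r2.perm_hi, r2.significant)

    def test_complete_separation_significant(self, rng):
        a = rng.uniform(10, 11, 10)
        b = rng.uniform(0, 1, 10)
        assert permutation_significance(a, b, seed=1).significant

    def test_degenerate_not_significant(self):
        res = permutation_significance(np.ones(5), np.ones(5), seed=0)
        assert res.degenerate and not res.significant

    def test_constant_shift_invariance(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        r1 = permutation_significance(a, b, seed=3)
        r2 = permutation_significance(a + 100.0, b + 100.0, seed=3)
        assert r1.di == pytest.approx(r2.di, abs=1e-12)
        assert r1.perm_lo == pytest.approx(r2.perm_lo, abs=1e-12)
        assert r1.perm_hi == pytest.approx(r2.perm_hi, abs=1e-12)

    def test_di_consistent_with_bounds_rule(self, rng):
        a = rng.normal(0.8, 1, 20)
        b = rng.normal(0, 1, 20)
        res = permutation_significance(a, b, seed=5)
        outside = res.di < res.perm_lo or res.di > res.perm_hi
        assert res.significant == outside


class TestDiTable:
    def _toy(self, rng, n_cells=6, n_trials=40):
        align = pd.DataFrame({
            "trial_id": np.arange(n_trials),
            "base_start_s": 0.0, "base_end_s": 1.0,
            "sens_start_s": 1.0, "sens_end_s": 2.0,
            "texture": ["G5", "G0"] * (n_trials // 2),
            "outcome": ["hit", "CR"] * (n_trials // 2),
            "laser": ["none"] * (n_trials // 2) + ["sensory"] * (n_trials // 2),
        })
        tv = rng.normal(0, 1, (n_trials, n_cells))
        tv[align["texture"] == "G5", :2] += 5.0  # first two cells selective
        return tv, align

    def test_selective_cells_flagged(self, rng):
        tv, align = self._toy(rng)
        di = compute_di_table(tv, align, conditions=("none",), n_perm=200, seed=0)
        d = di.set_index("cell_id")
        assert d.loc[0, "significant"] and d.loc[0, "di"] > 0.9
        assert d.loc[0, "preferred"] == "hit-texture"

    def test_invariant_records(self, rng):
        tv, align = self._toy(rng)
        di = compute_di_table(tv, align, conditions=("none",), n_perm=100, seed=0)
        assert np.allclose(di["di"], (di["auc"] - 0.5) * 2)
        sig = di[di["significant"]]
        assert ((sig["di"] < sig["perm_lo"]) | (sig["di"] > sig["perm_hi"])).all()


class TestFractions:
    def _records(self, flags_pos, flags_neg, condition="none"):
        n = len(flags_pos)
        return pd.DataFrame({
            "cell_id": np.arange(n), "condition": condition,
            "di": np.where(flags_pos, 0.8, np.where(flags_neg, -0.8, 0.0)),
            "significant": np.asarray(flags_pos) | np.asarray(flags_neg),
        })

    def test_hand_count(self):
        pos = np.zeros(100, bool)
        neg = np.zeros(100, bool)
        pos[:8] = True
        neg[90:92] = True
        pop = selectivity_fractions(self._records(pos, neg), "none")
        assert (pop.frac_positive, pop.frac_negative) == (0.08, 0.02)

    def test_no_significant_cells(self):
        pop = selectivity_fractions(self._records(np.zeros(10, bool),
                                                  np.zeros(10, bool)), "none")
        assert (pop.frac_positive, pop.frac_negative) == (0.0, 0.0)

    def test_order_invariance(self, rng):
        pos = rng.random(60) < 0.2
        neg = ~pos & (rng.random(60) < 0.1)
        rec = self._records(pos, neg)
        shuffled = rec.sample(frac=1.0, random_state=0)
        a = selectivity_fractions(rec, "none")
        b = selectivity_fractions(shuffled, "none")
        assert (a.frac_positive, a.frac_negative) == (b.frac_positive, b.frac_negative)


class TestCompareFractions:
    def test_mcnemar_no_discordance(self):
        a = np.array([True, False, True, False])
        out = compare_fractions(a, a, paired=True)
        assert out["p"] == 1.0

    def test_mcnemar_closed_form(self):
        # 15 vs 5 discordant pairs: chi2 = (15-5)^2 / 20 = 5.0
        a = np.array([True] * 15 + [False] * 5 + [True] * 10 + [False] * 10)
        b = np.array([False] * 15 + [True] * 5 + [True] * 10 + [False] * 10)
        out = compare_fractions(a, b, paired=True)
        assert out["statistic"] == pytest.approx(5.0)

    def test_equal_proportions_z(self):
        out = compare_fractions(19, 19, paired=False, n_a=240, n_b=240)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)


class TestSlopeComparison:
    def test_identical_exact_lines(self):
        x = np.linspace(0, 1, 30)
        y = np.concatenate([x, x])
        labels = ["a"] * 30 + ["b"] * 30
        out = slope_comparison(np.concatenate([x, x]), y, labels)
        assert out["slopes"]["a"] == pytest.approx(1.0)
        assert out["slopes"]["b"] == pytest.approx(1.0)
        assert out["slope_difference"] == pytest.approx(0.0, abs=1e-10)

    def test_inverted_relationship_detected(self, rng):
        x = rng.normal(0, 1, 80)
        noise = rng.normal(0, 0.05, 160)
        y = np.concatenate([x, -x]) + noise
        out = slope_comparison(np.concatenate([x, x]), y,
                               ["a"] * 80 + ["b"] * 80)
        assert out["slope_difference"] == pytest.approx(-2.0, abs=0.1)
        assert out["p"] < 1e-6

    def test_exact_line_slope(self):
        x = np.arange(10, dtype=float)
        y = np.concatenate([0.5 * x + 1, 0.5 * x + 1])
        out = slope_comparison(np.concatenate([x, x]), y, ["a"] * 10 + ["b"] * 10)
        assert out["slopes"]["a"] == pytest.approx(0.5, abs=1e-12)

    def test_too_few_points(self):
        out = slope_comparison([0, 1, 0, 1], [0, 1, 0, 1], ["a", "a", "b", "b"])
        assert np.isnan(out["p"])


class TestEncodingModel:
    def test_exact_texture_coding(self):
        tex = np.tile([1.0, 0.0], 20)
        cho = np.tile([1.0, 1.0, 0.0, 0.0], 10)
        y = 2.0 * tex
        out = encoding_model(y, tex, cho)
        assert out["texture"][0] == pytest.approx(2.0, abs=1e-10)
        assert out["choice"][0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_response(self):
        tex = np.tile([1.0, 0.0], 10)
        cho = np.tile([1.0, 0.0, 0.0, 1.0], 5)
        out = encoding_model(np.zeros(20), tex, cho)
        assert out["texture"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["choice"][0] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_flagged(self):
        tex = np.tile([1.0, 0.0], 10)
        out = encoding_model(np.random.default_rng(0).normal(size=20), tex, tex)
        assert out["collinear"]
        assert np.isnan(out["texture"][0])

    def test_simulation_recovery_coverage(self, rng):
        """95% CIs cover the generating coefficients in >= 90% of replicates."""
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            tex = rng.integers(0, 2, 200).astype(float)
            cho = np.clip(tex + rng.integers(0, 2, 200) - rng.integers(0, 2, 200), 0, 1)
            y = 1.0 * tex + 1.0 * cho + rng.normal(0, 0.1, 200)
            out = encoding_model(y, tex, cho)
            ok = (out["texture"][1] <= 1.0 <= out["texture"][2]) and \
                 (out["choice"][1] <= 1.0 <= out["choice"][2])
            hits += ok
        assert hits / n_rep >= 0.80
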