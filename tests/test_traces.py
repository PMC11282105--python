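"""Baseline estimation, dF/F, window statistics, responsiveness, sign flip."""

import numpy as np
import pandas as pd
import pytest

from texdisc.exceptions import AlignmentError
from texdisc.traces import (TraceMatrix, apply_sign_flip, compute_dff,
                            estimate_baseline, is_responsive,
                            texture_responsiveness, trial_auc_responsiveness,
                            trial_window_means)

FS = 7.5
DT = 1.0 / FS


def _alignment(trial_starts, base=(0.2, 4.0), sens=(4.0, 7.8), **labels):
    rows = []
    for i, t0 in enumerate(trial_starts):
        rows.append({"trial_id": i,
                     "base_start_s": t0 + base[0], "base_end_s": t0 + base[1],
                     "sens_start_s": t0 + sens[0], "sens_end_s": t0 + sens[1],
                     "texture": labels.get("texture", "G5"),
                     "outcome": labels.get("outcome", "hit"),
                     "laser": labels.get("laser", "none")})
    return pd.DataFrame(rows)


class TestBaseline:
    def test_constant_preserved(self):
        base = estimate_baseline(np.full(500, 7.25))
        assert np.allclose(base, 7.25)

    def test_slow_sinusoid_tracked(self):
        t = np.arange(3000) / FS
        raw = 100 * (1 + 0.05 * np.sin(2 * np.pi * t / 120))
        base = estimate_baseline(raw)
        rms = np.sqrt(np.mean((base - raw) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(raw ** 2))

    def test_sparse_transients_rejected(self, rng):
        t = np.arange(3000) / FS
        clean = 100 * (1 + 0.05 * np.sin(2 * np.pi * t / 120))
        raw = clean.copy()
        amp = 20.0
        idx = rng.choice(3000, size=150, replace=False)  # 5% of frames
        raw[idx] += amp
        base = estimate_baseline(raw)
        rms = np.sqrt(np.mean((base - clean) ** 2))
        assert rms < 0.1 * amp

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="window"):
            estimate_baseline(np.zeros(50))


class TestDff:
    def test_zero_when_raw_equals_baseline(self):
        raw = np.random.default_rng(0).uniform(90, 110, 200)
        assert np.allclose(compute_dff(raw, raw), 0.0)

    def test_twenty_percent(self):
        base = np.full(100, 50.0)
        assert np.allclose(compute_dff(1.2 * base, base), 20.0)

    def test_single_frame_value(self):
        assert compute_dff(np.array([110.0]), np.array([100.0]))[0] == pytest.approx(10.0)

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones(5), np.zeros(5))


class TestWindows:
    def _matrix(self, values):
        return TraceMatrix(values=values, sampling_rate=FS)

    def test_zero_trace_zero_means(self):
        dff = self._matrix(np.zeros((2, 80)))
        align = _alignment([0.0])
        base, sens = trial_window_means(dff, align)
        assert np.allclose(base, 0) and np.allclose(sens, 0)

    def test_unit_step_spanning_sensory_window(self):
        vals = np.zeros((1, 80))
        i0 = int(round(4.0 * FS))
        vals[0, i0:i0 + 28] = 1.0
        dff = self._matrix(vals)
        base, sens = trial_window_means(dff, _alignment([0.0]))
        assert base[0, 0] == pytest.approx(0.0)
        assert sens[0, 0] == pytest.approx(1.0)

    def test_ramp_mean_half(self):
        vals = np.zeros((1, 80))
        i0 = int(round(4.0 * FS))
        ramp = np.linspace(0, 1, 28)
        vals[0, i0:i0 + 28] = ramp
        dff = self._matrix(vals)
        _, sens = trial_window_means(dff, _alignment([0.0]))
        assert sens[0, 0] == pytest.approx(ramp.mean())

    def test_window_outside_recording_raises(self):
        dff = self._matrix(np.zeros((1, 30)))
        with pytest.raises(AlignmentError):
            trial_window_means(dff, _alignment([0.0]))

    def test_time_shift_invariance(self):
        """Shifting the recording clock and windows together changes nothing."""
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (2, 160))
        shift = 4.0
        a = TraceMatrix(vals, FS)
        b = TraceMatrix(vals, FS, frame_times=np.arange(160) / FS + shift)
        al_a = _alignment([0.0, 10.0])
        al_b = al_a.copy()
        for c in ("base_start_s", "base_end_s", "sens_start_s", "sens_end_s"):
            al_b[c] += shift
        np.testing.assert_allclose(trial_auc_responsiveness(a, al_a),
                                   trial_auc_responsiveness(b, al_b), atol=1e-9)


class TestAucResponsiveness:
    def test_flat_zero(self):
        dff = TraceMatrix(np.zeros((1, 80)), FS)
        tv = trial_auc_responsiveness(dff, _alignment([0.0]))
        assert tv[0, 0] == 0.0

    def test_constant_cancels(self):
        dff = TraceMatrix(np.full((1, 80), 3.7), FS)
        tv = trial_auc_responsiveness(dff, _alignment([0.0]))
        assert tv[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_step_discrete_trapezoid(self):
        # 28 frames at 7.5 Hz: trapezoid of a unit step = 27 * dt = 3.6
        vals = np.zeros((1, 80))
        i0 = int(round(4.0 * FS))
        vals[0, i0:i0 + 28] = 1.0
        dff = TraceMatrix(vals, FS)
        tv = trial_auc_responsiveness(dff, _alignment([0.0]))
        assert tv[0, 0] == pytest.approx(27 * DT)

    def test_linear_in_amplitude(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (1, 160))
        align = _alignment([0.0, 10.0])
        a = trial_auc_responsiveness(TraceMatrix(vals, FS), align)
        b = trial_auc_responsiveness(TraceMatrix(3.0 * vals, FS), align)
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-9)

    def test_group_mean_and_empty_group(self):
        tv = np.array([[1.0], [3.0], [5.0]])
        assert texture_responsiveness(tv, np.array([0, 2]), 0) == pytest.approx(3.0)
        assert np.isnan(texture_responsiveness(tv, np.array([], dtype=int), 0))


class TestIsResponsive:
    def test_all_zero_not_responsive(self):
        assert not is_responsive({"G5|none": np.zeros(20)})

    def test_clear_shift_responsive(self, rng):
        d = 10.0 + rng.normal(0, 0.1, 20)
        assert is_responsive({"G5|none": d})

    def test_too_few_trials_ignored(self, rng):
        d = 10.0 + rng.normal(0, 0.1, 4)  # below the 5-trial minimum
        assert not is_responsive({"G5|none": d})

    def test_skew_gate_routes_to_sign_test(self, rng):
        # heavily skewed differences: sign test must still detect a median shift
        d = rng.exponential(1.0, 40) + 0.5
        assert is_responsive({"G5|none": d})

    def test_null_false_positive_rate(self, rng):
        """Family-wise null rate over 4 groups matches 1 - (1-alpha)^4."""
        n_cells, n_trials = 1000, 20
        hits = 0
        for _ in range(n_cells):
            groups = {f"g{i}": rng.normal(0, 1, n_trials) for i in range(4)}
            hits += is_responsive(groups)
        expected = 1 - 0.95 ** 4
        se = np.sqrt(expected * (1 - expected) / n_cells)
        assert abs(hits / n_cells - expected) < 4 * se


class TestSignFlip:
    def _records(self, values):
        rows = []
        for cell, by_group in values.items():
            for grp, val in by_group.items():
                rows.append({"cell_id": cell, "trial_group": grp, "value": val,
                             "sign_flipped": False})
        return pd.DataFrame(rows)

    def test_positive_reference_unchanged(self):
        rec = self._records({0: {"G5-hit-none": 5.0, "G5-hit-sensory": -3.0}})
        out = apply_sign_flip(rec)
        assert out["value"].tolist() == [5.0, -3.0]
        assert not out["sign_flipped"].any()

    def test_negative_reference_flips_others_not_itself(self):
        rec = self._records({0: {"G5-hit-none": -5.0, "G5-hit-sensory": -3.0,
                                 "G0-CR-none": 2.0}})
        out = apply_sign_flip(rec).set_index("trial_group")["value"]
        assert out["G5-hit-none"] == -5.0  # reference not negated
        assert out["G5-hit-sensory"] == 3.0
        assert out["G0-CR-none"] == -2.0

    def test_flip_count_matches_brute_force(self, rng):
        values = {c: {"G5-hit-none": rng.normal(), "G0-CR-none": rng.normal()}
                  for c in range(50)}
        rec = self._records(values)
        out = apply_sign_flip(rec)
        expected = sum(v["G5-hit-none"] < 0 for v in values.values())
        flipped = out.groupby("cell_id")["sign_flipped"].any().sum()
        assert flipped == expected

    def test_missing_reference_skipped(self, caplog):
        rec = self._records({0: {"G0-CR-none": 1.0}})
        out = apply_sign_flip(rec)
        assert out["value"].tolist() == [1.0]
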