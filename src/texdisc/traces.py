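"""Raw fluorescence to dF/F, responsive-cell selection, AUC responsiveness.

dF/F is the percent change of raw fluorescence from a slowly varying baseline.
The baseline estimator suppresses spike-driven transients by clipping each
frame to a running low percentile (10th, over a centred 81-frame window),
smooths with a 4th-order, 81-point Savitzky-Golay filter (mirror-padded
edges), and recentres by the per-cell median residual.  At the 7.5 Hz frame
rate the 81-point window spans ~10.8 s, long relative to a transient but
short relative to drift.

Trial statistics use two equal-length windows per trial: a baseline window
(the last ``3.8`` s of the pre-stimulus epoch) and the sensory window (texture
presentation).  *Texture responsiveness* of a trial group is the mean over
trials of (trapezoidal AUC of dF/F over the sensory window) minus (AUC over
the baseline window).  A cell is *responsive* when, for any of the G5/G0 x
no-laser/sensory-laser trial groups, the paired per-trial differences of
window means depart from zero (Wilcoxon signed-rank when the differences'
absolute skew is < 0.6, sign test otherwise; p < 0.05, no multiplicity
correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import savgol_filter
from scipy.stats import binomtest, skew, wilcoxon

from .exceptions import AlignmentError, ParameterError

logger = logging.getLogger(__name__)

#: trial groups tested by the responsiveness screen
RESPONSIVE_GROUPS = (("G5", "none"), ("G0", "none"), ("G5", "sensory"), ("G0", "sensory"))


@dataclass
class TraceMatrix:
    """Cells x frames fluorescence with a uniform frame clock."""

    values: np.ndarray
    sampling_rate: float
    frame_times: np.ndarray = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.frame_times is None:
            self.frame_times = np.arange(self.values.shape[1]) / self.sampling_rate
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size != self.values.shape[1]:
            raise ParameterError("frame_times length must match the frame axis")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def estimate_baseline(raw: np.ndarray, window: int = 81, polyorder: int = 4,
                      percentile: float = 10.0, recenter: bool = True) -> np.ndarray:
    """Time-varying baseline: transient clipping then Savitzky-Golay smoothing.

    Each frame is clipped to a running low percentile (centred ``window``),
    which rejects calcium transients even when their decay tails occupy most
    frames of a trial, and the clipped trace is Savitzky-Golay smoothed.
    Because a low percentile sits systematically below the trace's central
    level, the smoothed curve is then recentred by adding back the per-cell
    median residual (``recenter``); this restores an unbiased dF/F around
    zero on transient-free data while leaving sensory-minus-baseline window
    differences untouched (a per-cell constant cancels there exactly).

    Works on a single trace or a cells x frames matrix (filtered per row).
    """
    arr = np.asarray(raw, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] < window:
        raise ValueError(
            f"trace length {arr.shape[1]} is shorter than the {window}-frame "
            "filter window; reduce the window via the analysis config")
    running = percentile_filter(arr, percentile, size=(1, window), mode="reflect")
    clipped = np.minimum(arr, running)
    base = savgol_filter(clipped, window_length=window, polyorder=polyorder,
                         axis=1, mode="mirror")
    if recenter:
        base = base + np.median(arr - base, axis=1, keepdims=True)
    return base[0] if squeeze else base


def compute_dff(raw: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Percent change from baseline: 100 * (raw - baseline) / baseline."""
    raw = np.asarray(raw, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline: baseline estimate is invalid")
    return 100.0 * (raw - baseline) / baseline


def dff_from_raw(traces: TraceMatrix, window: int = 81, polyorder: int = 4,
                 percentile: float = 10.0) -> TraceMatrix:
    """Convenience: baseline-estimate and normalize a raw TraceMatrix."""
    base = estimate_baseline(traces.values, window=window, polyorder=polyorder,
                             percentile=percentile)
    return TraceMatrix(values=compute_dff(traces.values, base),
                       sampling_rate=traces.sampling_rate,
                       frame_times=traces.frame_times.copy())


def _window_slice(frame_times: np.ndarray, start_s: float, end_s: float,
                  sampling_rate: float) -> slice:
    """Frames of the half-open window [start, end).

    The first frame is the first with time >= start; the frame count is fixed
    at floor(duration * fs) so equal-duration windows always select equally
    many frames (their constant components cancel exactly in AUC differences).
    """
    duration = end_s - start_s
    n = int(np.floor(duration * sampling_rate + 1e-9))
    i0 = int(np.searchsorted(frame_times, start_s - 1e-9, side="left"))
    if n <= 0 or i0 + n > frame_times.size:
        raise AlignmentError(
            f"window [{start_s}, {end_s}) does not fit inside the recording")
    return slice(i0, i0 + n)


def trial_window_means(dff: TraceMatrix, alignment: pd.DataFrame):
    """Per trial x cell mean dF/F over the baseline and sensory windows.

    Returns ``(base_means, sens_means)``, each shaped (n_trials, n_cells) in
    the row order of ``alignment``.
    """
    n_trials = len(alignment)
    base = np.empty((n_trials, dff.n_cells))
    sens = np.empty((n_trials, dff.n_cells))
    for i, row in enumerate(alignment.itertuples(index=False)):
        bs = _window_slice(dff.frame_times, row.base_start_s, row.base_end_s,
                           dff.sampling_rate)
        ss = _window_slice(dff.frame_times, row.sens_start_s, row.sens_end_s,
                           dff.sampling_rate)
        base[i] = dff.values[:, bs].mean(axis=1)
        sens[i] = dff.values[:, ss].mean(axis=1)
    return base, sens


def trial_auc_responsiveness(dff: TraceMatrix, alignment: pd.DataFrame) -> np.ndarray:
    """Per-trial AUC difference (sensory - baseline), shape (n_trials, n_cells).

    AUC is the trapezoid of dF/F over the window's frame times, in
    dF/F % * seconds.
    """
    n_trials = len(alignment)
    out = np.empty((n_trials, dff.n_cells))
    t = dff.frame_times
    for i, row in enumerate(alignment.itertuples(index=False)):
        bs = _window_slice(t, row.base_start_s, row.base_end_s, dff.sampling_rate)
        ss = _window_slice(t, row.sens_start_s, row.sens_end_s, dff.sampling_rate)
        auc_b = np.trapezoid(dff.values[:, bs], t[bs], axis=1)
        auc_s = np.trapezoid(dff.values[:, ss], t[ss], axis=1)
        out[i] = auc_s - auc_b
    return out


def select_trials(alignment: pd.DataFrame, texture: str | None = None,
                  laser: str | None = None, outcome=None) -> np.ndarray:
    """Row indices of alignment trials matching the given labels."""
    mask = np.ones(len(alignment), dtype=bool)
    if texture is not None:
        mask &= (alignment["texture"] == texture).to_numpy()
    if laser is not None:
        mask &= (alignment["laser"] == laser).to_numpy()
    if outcome is not None:
        outcomes = [outcome] if isinstance(outcome, str) else list(outcome)
        mask &= alignment["outcome"].isin(outcomes).to_numpy()
    return np.nonzero(mask)[0]


def is_responsive(diffs_by_group: dict, alpha: float = 0.05,
                  skew_cutoff: float = 0.6, min_trials: int = 5) -> bool:
    """Skew-gated responsiveness test on per-trial window-mean differences.

    ``diffs_by_group`` maps a group label to the 1-D array of per-trial
    (sensory mean - baseline mean) differences for one cell.  Groups with
    fewer than ``min_trials`` trials are ignored.  For each remaining group
    the test is a Wilcoxon signed-rank when |adjusted Fisher-Pearson skew| <
    ``skew_cutoff``, otherwise a two-sided sign test (ties dropped).  The cell
    is responsive when any group's p-value is below ``alpha``.
    """
    any_tested = False
    for label, d in diffs_by_group.items():
        d = np.asarray(d, dtype=float)
        if d.size < min_trials:
            continue
        if np.all(d == 0):
            logger.debug("group %s: all-zero differences, skipped", label)
            continue
        any_tested = True
        sk = skew(d, bias=False)
        if np.isfinite(sk) and abs(sk) < skew_cutoff:
            p = wilcoxon(d).pvalue
        else:
            nz = d[d != 0]
            p = binomtest(int((nz > 0).sum()), nz.size, 0.5).pvalue
        if p < alpha:
            return True
    if not any_tested:
        logger.debug("is_responsive: no testable group (degenerate cell)")
    return False


def responsive_cells(dff: TraceMatrix, alignment: pd.DataFrame,
                     alpha: float = 0.05, skew_cutoff: float = 0.6,
                     min_trials: int = 5,
                     groups=RESPONSIVE_GROUPS) -> np.ndarray:
    """Boolean responsiveness flag per cell over the standard trial groups."""
    base, sens = trial_window_means(dff, alignment)
    diffs = sens - base  # (n_trials, n_cells)
    idx_by_group = {f"{tex}|{las}": select_trials(alignment, texture=tex, laser=las)
                    for tex, las in groups}
    flags = np.zeros(dff.n_cells, dtype=bool)
    for c in range(dff.n_cells):
        per_cell = {k: diffs[idx, c] for k, idx in idx_by_group.items() if idx.size}
        flags[c] = is_responsive(per_cell, alpha=alpha, skew_cutoff=skew_cutoff,
                                 min_trials=min_trials)
    return flags


def texture_responsiveness(trial_values: np.ndarray, trial_indices: np.ndarray,
                           cell: int) -> float:
    """Group responsiveness: mean per-trial AUC difference over a trial group.

    ``trial_values`` is the (n_trials, n_cells) output of
    :func:`trial_auc_responsiveness`.  Returns NaN for an empty group.
    """
    idx = np.asarray(trial_indices, dtype=int)
    if idx.size == 0:
        logger.warning("texture_responsiveness: empty trial group")
        return float("nan")
    return float(trial_values[idx, cell].mean())


def responsiveness_records(trial_values: np.ndarray, alignment: pd.DataFrame,
                           groups: dict) -> pd.DataFrame:
    """Tidy per cell x group responsiveness table.

    ``groups`` maps a group name to selector kwargs for :func:`select_trials`,
    e.g. ``{"G5-hit-none": dict(texture="G5", outcome="hit", laser="none")}``.
    """
    n_cells = trial_values.shape[1]
    rows = []
    for name, sel in groups.items():
        idx = select_trials(alignment, **sel)
        for c in range(n_cells):
            rows.append({"cell_id": c, "trial_group": name,
                         "value": texture_responsiveness(trial_values, idx, c),
                         "sign_flipped": False})
    return pd.DataFrame(rows)


def apply_sign_flip(records: pd.DataFrame,
                    reference_group: str = "G5-hit-none") -> pd.DataFrame:
    """Sign-flip rule for suppressed cells.

    A cell whose reference-group (no-laser G5) responsiveness is negative has
    every *other* group's value negated, so that response suppression and
    enhancement are compared on a common sign convention.  Applied exactly
    once by the pipeline; cells lacking the reference group are skipped with a
    warning.
    """
    out = records.copy()
    for cell_id, sub in out.groupby("cell_id"):
        ref = sub[sub["trial_group"] == reference_group]
        if ref.empty or ref["value"].isna().all():
            logger.warning("apply_sign_flip: cell %s lacks reference group %s",
                           cell_id, reference_group)
            continue
        if float(ref["value"].iloc[0]) < 0:
            mask = (out["cell_id"] == cell_id) & (out["trial_group"] != reference_group)
            out.loc[mask, "value"] = -out.loc[mask, "value"]
            out.loc[out["cell_id"] == cell_id, "sign_flipped"] = True
    return out
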