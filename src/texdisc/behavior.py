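"""Trial classification and session-level performance metrics for go/no-go tasks.

A session is a :class:`pandas.DataFrame` with one row per trial (see
``texdisc.io.TRIAL_COLUMNS``).  Outcomes follow signal-detection convention:
lick to a go stimulus is a *hit*, no lick a *miss*; lick to the no-go stimulus
is a *false alarm* (FA), no lick a *correct rejection* (CR).  Percent correct,
d-prime and error rate are computed on the trained stimulus pair only (the
coarsest grating G5 versus the smooth G0 texture; the largest deflection M1
versus the no-movement catch NoM in the detection task).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import norm

from .exceptions import AlignmentError

logger = logging.getLogger(__name__)

OUTCOMES = ("hit", "miss", "FA", "CR", "aborted")

#: default trained pairs per task, used when a session contains the level
_GO_REFERENCE_LEVELS = ("G5", "M1")


def classify_trial(is_go: bool, licked: bool) -> str:
    """Outcome of a single non-aborted trial.

    go & lick -> hit, go & no-lick -> miss, no-go & lick -> FA,
    no-go & no-lick -> CR.
    """
    if is_go:
        return "hit" if licked else "miss"
    return "FA" if licked else "CR"


def filter_analysis_trials(session: pd.DataFrame) -> pd.DataFrame:
    """Drop aborted and bias-correction trials; order preserved; idempotent."""
    mask = ~(session["aborted"].astype(bool) | session["bias_correction"].astype(bool))
    out = session.loc[mask].copy()
    if out.empty:
        logger.warning("no analyzable trials remain after exclusion filters")
    return out


def _reference_levels(session: pd.DataFrame,
                      go_level: str | None,
                      nogo_level: str | None) -> tuple[str, str]:
    levels = set(session["stimulus_level"].unique())
    if nogo_level is None:
        nogo = set(session.loc[~session["is_go"].astype(bool), "stimulus_level"].unique())
        if len(nogo) != 1:
            raise ValueError("cannot infer no-go level; pass nogo_level explicitly")
        nogo_level = nogo.pop()
    if go_level is None:
        for cand in _GO_REFERENCE_LEVELS:
            if cand in levels:
                go_level = cand
                break
        else:
            raise ValueError("cannot infer go reference level; pass go_level explicitly")
    return go_level, nogo_level


def _pair_trials(session: pd.DataFrame, go_level: str | None,
                 nogo_level: str | None) -> pd.DataFrame:
    go_level, nogo_level = _reference_levels(session, go_level, nogo_level)
    sub = filter_analysis_trials(session)
    return sub[sub["stimulus_level"].isin([go_level, nogo_level])]


def percent_correct(session: pd.DataFrame, go_level: str | None = None,
                    nogo_level: str | None = None) -> float:
    """(hits + CRs) / (hits + CRs + misses + FAs) x 100 on the trained pair.

    Returns NaN when no trained-pair trial is present.
    """
    sub = _pair_trials(session, go_level, nogo_level)
    counts = sub["outcome"].value_counts()
    denom = sum(counts.get(o, 0) for o in ("hit", "CR", "miss", "FA"))
    if denom == 0:
        logger.warning("percent_correct undefined: no analyzed trained-pair trials")
        return float("nan")
    return 100.0 * (counts.get("hit", 0) + counts.get("CR", 0)) / denom


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Signal-detection sensitivity d' = z(hit) - z(FA).

    Rates are clipped to [1/(2N), 1 - 1/(2N)] per response category before the
    inverse-normal transform so extreme sessions stay finite (the standard
    log-linear correction).  Returns NaN when a trial count is non-positive.
    """
    if n_go <= 0 or n_nogo <= 0:
        return float("nan")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    return float(norm.ppf(h) - norm.ppf(f))


def error_rate(session: pd.DataFrame, go_level: str | None = None,
               nogo_level: str | None = None) -> float:
    """Mean of the miss rate (go reference trials) and FA rate (no-go trials)."""
    go_level, nogo_level = _reference_levels(session, go_level, nogo_level)
    sub = filter_analysis_trials(session)
    go = sub[sub["stimulus_level"] == go_level]
    ng = sub[sub["stimulus_level"] == nogo_level]
    if go.empty or ng.empty:
        logger.warning("error_rate undefined: missing %s or %s trials", go_level, nogo_level)
        return float("nan")
    miss_rate = float((go["outcome"] == "miss").mean())
    fa_rate = float((ng["outcome"] == "FA").mean())
    return 0.5 * (miss_rate + fa_rate)


@dataclass
class SessionMetrics:
    """Performance summary of one session x laser condition."""

    hit_rate: float
    fa_rate: float
    percent_correct: float
    dprime: float
    error_rate: float
    n_by_outcome: dict = field(default_factory=dict)
    included: bool = False


def session_metrics(session: pd.DataFrame, laser: str | None = None,
                    go_level: str | None = None,
                    nogo_level: str | None = None) -> SessionMetrics:
    """All trained-pair metrics, optionally restricted to one laser condition."""
    sub = session if laser is None else session[session["laser"] == laser]
    go_level, nogo_level = _reference_levels(session, go_level, nogo_level)
    pair = _pair_trials(sub, go_level, nogo_level)
    counts = pair["outcome"].value_counts().to_dict()
    n_go = counts.get("hit", 0) + counts.get("miss", 0)
    n_nogo = counts.get("FA", 0) + counts.get("CR", 0)
    hit_rate = counts.get("hit", 0) / n_go if n_go else float("nan")
    fa_rate = counts.get("FA", 0) / n_nogo if n_nogo else float("nan")
    pc = percent_correct(sub, go_level, nogo_level)
    dp = dprime(hit_rate, fa_rate, n_go, n_nogo) if n_go and n_nogo else float("nan")
    er = error_rate(sub, go_level, nogo_level)
    included = bool((not np.isnan(dp) and dp > 1.0) or (not np.isnan(pc) and pc > 70.0))
    return SessionMetrics(hit_rate=hit_rate, fa_rate=fa_rate, percent_correct=pc,
                          dprime=dp, error_rate=er, n_by_outcome=counts,
                          included=included)


def session_included(session: pd.DataFrame, go_level: str | None = None,
                     nogo_level: str | None = None) -> bool:
    """Session-inclusion rule: no-laser d' > 1 or no-laser percent correct > 70."""
    m = session_metrics(session, laser="none", go_level=go_level, nogo_level=nogo_level)
    if np.isnan(m.dprime) and np.isnan(m.percent_correct):
        logger.warning("session_included: metrics undefined, session excluded")
        return False
    return m.included


def whisk_rate(angle_trace: np.ndarray, sampling_rate: float,
               sensory_duration_s: float = 3.84,
               amplitude_threshold_deg: float = 5.0) -> float:
    """Whisks per second over the sensory period.

    A whisk is one continuous antero-posterior (protraction) sweep: an upward
    excursion between alternating local extrema whose peak-to-trough amplitude
    exceeds ``amplitude_threshold_deg``.  Window endpoints count as candidate
    extrema so a single monotonic sweep is one whisk.
    """
    angle = np.asarray(angle_trace, dtype=float)
    n_win = int(np.floor(sensory_duration_s * sampling_rate + 1e-9))
    if angle.size < n_win:
        raise AlignmentError(
            f"angle trace ({angle.size} samples) shorter than the "
            f"{sensory_duration_s} s sensory window ({n_win} samples)")
    seg = angle[:n_win]
    peaks, _ = find_peaks(seg)
    troughs, _ = find_peaks(-seg)
    idx = np.unique(np.concatenate([[0], peaks, troughs, [n_win - 1]]))
    # collapse consecutive extrema into a strictly alternating sequence,
    # keeping the more extreme of a same-direction run
    ext: list[int] = []
    for i in idx:
        if len(ext) < 2:
            ext.append(int(i))
            continue
        prev, cur = seg[ext[-2]], seg[ext[-1]]
        rising = cur >= prev
        if (seg[i] >= cur and rising) or (seg[i] <= cur and not rising):
            ext[-1] = int(i)  # same direction continues
        else:
            ext.append(int(i))
    n_whisks = 0
    for a, b in zip(ext[:-1], ext[1:]):
        if seg[b] - seg[a] >= amplitude_threshold_deg:
            n_whisks += 1
    return n_whisks / sensory_duration_s
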