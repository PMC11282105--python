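"""ROC discrimination index, permutation significance and population tests.

For each cell, the per-trial responses (AUC differences) on G5-hit trials are
compared to those on G0-CR trials with an ROC built from a linear sweep of
thresholds spanning the pooled minimum to maximum response: each threshold
yields the fraction of hit-texture trials and of CR-texture trials whose
response strictly exceeds it, the curve is closed at (0,0) and (1,1), and the
area is taken by the trapezoid rule.  The Discrimination Index is
DI = (AUC - 0.5) x 2, in [-1, 1]; positive DI means a larger response to the
rewarded (hit) texture.  Significance comes from a permutation test: trial
labels are shuffled (1000 times by default, preserving group sizes) and the
observed DI is significant when it falls outside the 2.5th-97.5th percentile
interval of the shuffled DIs.

Population-level comparisons (fractions of selective cells, hit-vs-CR slope
changes, texture + choice encoding regression) use standard statsmodels
machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from statsmodels.stats.contingency_tables import mcnemar as _mcnemar
from statsmodels.stats.proportion import proportions_ztest

from .traces import select_trials

logger = logging.getLogger(__name__)


def _auc_from_curves(hit: np.ndarray, fa: np.ndarray) -> np.ndarray:
    """Trapezoid area of ROC curves given per-threshold exceedance fractions.

    ``hit`` and ``fa`` are (..., n_thresholds), non-increasing along the
    threshold axis; the curve is closed with (1,1) below the minimum and
    (0,0) above the maximum threshold.
    """
    shape = hit.shape[:-1] + (1,)
    h = np.concatenate([np.ones(shape), hit, np.zeros(shape)], axis=-1)
    f = np.concatenate([np.ones(shape), fa, np.zeros(shape)], axis=-1)
    auc = np.sum(0.5 * (h[..., 1:] + h[..., :-1]) * (f[..., :-1] - f[..., 1:]),
                 axis=-1)
    # guard against sub-eps float overshoot from the summation
    return np.clip(auc, 0.0, 1.0)


def roc_auc(responses_a, responses_b, n_thresholds: int = 1000,
            method: str = "threshold") -> float:
    """ROC area for group a (hit texture) versus group b (CR texture).

    ``method="threshold"`` is the linear threshold sweep described above;
    ``method="rank"`` is the exact Mann-Whitney statistic U/(n_a n_b) with
    ties counted one half (the dense-threshold limit), kept as an independent
    cross-check.  Identical constant responses in both groups return 0.5.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both response groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.debug("roc_auc: degenerate constant responses, AUC = 0.5")
        return 0.5
    if method == "rank":
        ranks = rankdata(pooled)
        u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
        return float(u / (a.size * b.size))
    thr = np.linspace(pooled.min(), pooled.max(), n_thresholds)
    hit = (a[:, None] > thr).mean(axis=0)
    fa = (b[:, None] > thr).mean(axis=0)
    return float(_auc_from_curves(hit, fa))


def discrimination_index(auc: float) -> float:
    """DI = (AUC - 0.5) x 2; an exact affine bijection of AUC onto [-1, 1]."""
    if not (-1e-9 <= auc <= 1.0 + 1e-9):
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    return (float(np.clip(auc, 0.0, 1.0)) - 0.5) * 2.0


@dataclass
class PermutationResult:
    di: float
    auc: float
    significant: bool
    perm_lo: float
    perm_hi: float
    degenerate: bool = False


def permutation_significance(responses_a, responses_b, n_perm: int = 1000,
                             seed=None, rng: np.random.Generator | None = None,
                             n_thresholds: int = 1000,
                             percentiles=(2.5, 97.5)) -> PermutationResult:
    """Label-shuffle significance of the discrimination index.

    The null DI distribution is built by shuffling the group labels of the
    pooled responses ``n_perm`` times (group sizes preserved) and recomputing
    the threshold-sweep DI.  The observed DI is significant when outside the
    ``percentiles`` interval of the null distribution.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return PermutationResult(di=0.0, auc=0.5, significant=False,
                                 perm_lo=0.0, perm_hi=0.0, degenerate=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    thr = np.linspace(pooled.min(), pooled.max(), n_thresholds)
    exceed = (pooled[:, None] > thr).astype(float)       # (n, n_thr)
    obs_auc = float(_auc_from_curves(exceed[: a.size].mean(axis=0),
                                     exceed[a.size:].mean(axis=0)))
    obs_di = discrimination_index(obs_auc)

    labels = np.zeros(pooled.size, dtype=bool)
    labels[: a.size] = True
    perm = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)  # (n_perm, n)
    hit = (perm.astype(float) @ exceed) / a.size              # (n_perm, n_thr)
    fa = ((~perm).astype(float) @ exceed) / b.size
    null_di = (_auc_from_curves(hit, fa) - 0.5) * 2.0
    lo, hi = np.percentile(null_di, list(percentiles))
    significant = bool(obs_di < lo or obs_di > hi)
    return PermutationResult(di=obs_di, auc=obs_auc, significant=significant,
                             perm_lo=float(lo), perm_hi=float(hi))


#: default trial-group pairing for the DI: G5-hit vs G0-CR per laser condition
DI_GROUP_PAIR = (dict(texture="G5", outcome="hit"), dict(texture="G0", outcome="CR"))


def compute_di_table(trial_values: np.ndarray, alignment: pd.DataFrame,
                     conditions=("none", "sensory"), n_perm: int = 1000,
                     seed=None, n_thresholds: int = 1000,
                     group_pair=DI_GROUP_PAIR, min_trials: int = 2) -> pd.DataFrame:
    """DI records for every cell x laser condition.

    ``trial_values`` is the (n_trials, n_cells) per-trial response matrix
    (AUC differences).  Permutations use independent per-cell substreams
    spawned from ``seed`` so results are reproducible and cell-order
    invariant.  Cells with fewer than ``min_trials`` trials in either group of
    a condition are skipped for that condition.
    """
    n_cells = trial_values.shape[1]
    root = np.random.default_rng(seed)
    streams = root.spawn(n_cells * len(conditions))
    rows = []
    k = 0
    for cond in conditions:
        sel_a = select_trials(alignment, laser=cond, **group_pair[0])
        sel_b = select_trials(alignment, laser=cond, **group_pair[1])
        for c in range(n_cells):
            stream = streams[k]
            k += 1
            if sel_a.size < min_trials or sel_b.size < min_trials:
                continue
            res = permutation_significance(trial_values[sel_a, c],
                                           trial_values[sel_b, c],
                                           n_perm=n_perm, rng=stream,
                                           n_thresholds=n_thresholds)
            preferred = "none"
            if res.significant and res.di > 0:
                preferred = "hit-texture"
            elif res.significant and res.di < 0:
                preferred = "CR-texture"
            rows.append({"cell_id": c, "condition": cond, "auc": res.auc,
                         "di": res.di, "perm_lo": res.perm_lo,
                         "perm_hi": res.perm_hi, "significant": res.significant,
                         "preferred": preferred,
                         "n_a": int(sel_a.size), "n_b": int(sel_b.size)})
    return pd.DataFrame(rows)


@dataclass
class PopulationSelectivity:
    condition: str
    n_cells: int
    frac_positive: float  # significant with DI > 0 (hit-texture selective)
    frac_negative: float  # significant with DI < 0 (CR-texture selective)


def selectivity_fractions(di_records: pd.DataFrame,
                          condition: str) -> PopulationSelectivity:
    """Fractions of cells significantly selective for either texture."""
    sub = di_records[di_records["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no DI records for condition {condition!r}")
    n = len(sub)
    pos = float((sub["significant"] & (sub["di"] > 0)).sum() / n)
    neg = float((sub["significant"] & (sub["di"] < 0)).sum() / n)
    return PopulationSelectivity(condition=condition, n_cells=n,
                                 frac_positive=pos, frac_negative=neg)


def compare_fractions(a, b, paired: bool, n_a: int | None = None,
                      n_b: int | None = None, exact: bool = False) -> dict:
    """Compare two selectivity fractions.

    Paired (same cells, two categories/conditions): ``a`` and ``b`` are
    boolean indicator vectors and the test is McNemar's (chi-square without
    continuity correction by default, exact binomial with ``exact=True``).
    Unpaired: ``a`` and ``b`` are selective-cell counts with group sizes
    ``n_a``/``n_b`` and the test is a two-sided two-proportion z-test.
    """
    if paired:
        ai = np.asarray(a, dtype=bool)
        bi = np.asarray(b, dtype=bool)
        if ai.shape != bi.shape:
            raise ValueError("paired indicator vectors must have equal length")
        n01 = int((~ai & bi).sum())
        n10 = int((ai & ~bi).sum())
        if n01 + n10 == 0:
            return {"test": "mcnemar", "statistic": 0.0, "p": 1.0,
                    "note": "no discordant pairs"}
        table = [[int((ai & bi).sum()), n10], [n01, int((~ai & ~bi).sum())]]
        res = _mcnemar(table, exact=exact, correction=False)
        return {"test": "mcnemar", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    if n_a is None or n_b is None:
        raise ValueError("unpaired comparison needs group sizes n_a and n_b")
    stat, p = proportions_ztest([int(a), int(b)], [int(n_a), int(n_b)],
                                alternative="two-sided")
    return {"test": "two-proportion-z", "statistic": float(stat), "p": float(p)}


def slope_comparison(values_x, values_y, condition_labels) -> dict:
    """OLS slopes of y-on-x per condition and the slope-difference test.

    The difference is tested as the x-by-condition interaction in a pooled
    regression (two-sided Wald test).  Conditions with fewer than 3 points
    make the comparison undefined (NaN p).
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    labels = np.asarray(condition_labels)
    conds = list(pd.unique(labels))
    if len(conds) != 2:
        raise ValueError("slope_comparison expects exactly two conditions")
    slopes = {}
    for cond in conds:
        m = labels == cond
        if m.sum() < 3:
            slopes[cond] = float("nan")
            continue
        fit = sm.OLS(y[m], sm.add_constant(x[m])).fit()
        slopes[cond] = float(fit.params[1])
    if any(np.isnan(v) for v in slopes.values()):
        return {"slopes": slopes, "slope_difference": float("nan"), "p": float("nan")}
    d = (labels == conds[1]).astype(float)
    X = np.column_stack([np.ones_like(x), x, d, x * d])
    fit = sm.OLS(y, X).fit()
    return {"slopes": slopes, "slope_difference": float(fit.params[3]),
            "p": float(fit.pvalues[3])}


def encoding_model(per_trial_response, texture_code, choice_code,
                   alpha: float = 0.05) -> dict:
    """Per-cell linear regression of trial response on texture and choice.

    ``texture_code`` is 1 for the G5 texture and 0 for G0; ``choice_code`` is
    1 for a lick and 0 for no lick.  Returns OLS coefficients with two-sided
    confidence intervals.  Perfectly collinear predictors (texture identical
    to choice in the session) are flagged and yield NaN coefficients.
    """
    y = np.asarray(per_trial_response, dtype=float)
    tex = np.asarray(texture_code, dtype=float)
    cho = np.asarray(choice_code, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 trials for the encoding model")
    X = np.column_stack([np.ones_like(tex), tex, cho])
    if np.linalg.matrix_rank(X) < 3:
        logger.warning("encoding_model: collinear predictors, coefficients undefined")
        nan3 = (float("nan"),) * 3
        return {"collinear": True,
                "intercept": nan3, "texture": nan3, "choice": nan3}
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    out = {"collinear": False}
    for i, name in enumerate(("intercept", "texture", "choice")):
        out[name] = (float(fit.params[i]), float(ci[i, 0]), float(ci[i, 1]))
    return out
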