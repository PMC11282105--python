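"""The 4-parameter cumulative-Gaussian psychometric model and its fitting.

Lick probability as a function of the ordinal stimulus coordinate x is

    y(x) = g + (1 - g - l) * 0.5 * (1 + erf((x - u) / sqrt(2 v^2)))

with g the guess rate (lower asymptote, the asymptotic false-alarm rate),
l the lapse rate (1 - upper asymptote, the asymptotic miss rate), u the
bias/threshold (curve midpoint on the stimulus axis) and v > 0 the inverse
sensitivity (Gaussian SD; smaller v = steeper curve).

Fitting minimizes the trial-count-weighted squared error between observed and
predicted per-level lick probabilities under box constraints, from a
deterministic multi-start grid; a binomial maximum-likelihood objective is
available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf
from scipy.stats import shapiro, ttest_rel, wilcoxon

from .exceptions import FitError, ParameterError

logger = logging.getLogger(__name__)

#: box bounds for (g, l, u, v); u bounds are relative to the data range
G_BOUNDS = (0.0, 0.6)
L_BOUNDS = (0.0, 0.6)
V_BOUNDS = (1e-3, 10.0)
_PENALTY = 1e4  # soft penalty weight for g + l > 1


def psychometric_value(x, g: float, l: float, u: float, v: float):
    """Evaluate the psychometric curve at stimulus coordinate(s) ``x``."""
    if v <= 0:
        raise ParameterError(f"sensitivity parameter v must be > 0, got {v}")
    if not (0.0 <= g <= 1.0 and 0.0 <= l <= 1.0 and g + l <= 1.0):
        raise ParameterError(f"invalid asymptote parameters g={g}, l={l}")
    x = np.asarray(x, dtype=float)
    y = g + (1.0 - g - l) * 0.5 * (1.0 + erf((x - u) / np.sqrt(2.0 * v ** 2)))
    return float(y) if y.ndim == 0 else y


@dataclass
class PsychometricFit:
    """Fitted parameters plus the data and diagnostics of one fit."""

    g: float
    l: float
    u: float
    v: float
    levels: np.ndarray
    lick_probs: np.ndarray
    trial_counts: np.ndarray
    rss: float
    converged: bool
    n_restarts_used: int
    at_bounds: dict = field(default_factory=dict)
    objective: str = "wls"

    def predict(self, x):
        return psychometric_value(x, self.g, self.l, self.u, self.v)

    @property
    def params(self) -> dict:
        return {"g": self.g, "l": self.l, "u": self.u, "v": self.v}


def _objective_factory(x, p_obs, w, kind):
    if kind == "wls":
        def fun(theta):
            g, l, u, v = theta
            pred = g + (1 - g - l) * 0.5 * (1 + erf((x - u) / np.sqrt(2 * v ** 2)))
            pen = _PENALTY * max(0.0, g + l - 1.0) ** 2
            return float(np.sum(w * (p_obs - pred) ** 2) + pen)
    elif kind == "nll":
        def fun(theta):
            g, l, u, v = theta
            pred = g + (1 - g - l) * 0.5 * (1 + erf((x - u) / np.sqrt(2 * v ** 2)))
            pred = np.clip(pred, 1e-9, 1 - 1e-9)
            pen = _PENALTY * max(0.0, g + l - 1.0) ** 2
            ll = w * (p_obs * np.log(pred) + (1 - p_obs) * np.log(1 - pred))
            return float(-np.sum(ll) + pen)
    else:
        raise ValueError(f"unknown objective {kind!r}")
    return fun


def fit_psychometric(levels, lick_probs, trial_counts,
                     objective: str = "wls") -> PsychometricFit:
    """Fit (g, l, u, v) to per-level lick probabilities.

    Parameters
    ----------
    levels : array-like
        Stimulus coordinates (ordinal indices), at least 4 distinct values.
    lick_probs : array-like
        Observed lick probability per level, in [0, 1].
    trial_counts : array-like
        Trials per level (weights), > 0.
    objective : {"wls", "nll"}
        Count-weighted least squares (default) or binomial negative
        log-likelihood.
    """
    x = np.asarray(levels, dtype=float)
    p = np.asarray(lick_probs, dtype=float)
    n = np.asarray(trial_counts, dtype=float)
    if x.shape != p.shape or x.shape != n.shape:
        raise FitError("levels, lick_probs and trial_counts must have equal length")
    if np.unique(x).size < 4:
        raise FitError("need at least 4 distinct stimulus levels to fit 4 parameters")
    if np.any(n <= 0):
        raise FitError("trial counts must be positive")
    if np.any((p < 0) | (p > 1)):
        raise FitError("lick probabilities must lie in [0, 1]")

    # duplicate levels pool into one point with summed counts so fitting is
    # invariant to splitting a level's trials across rows
    order = np.argsort(x)
    x, p, n = x[order], p[order], n[order]
    ux = np.unique(x)
    if ux.size != x.size:
        pu = np.array([np.average(p[x == v], weights=n[x == v]) for v in ux])
        nu = np.array([n[x == v].sum() for v in ux])
        x, p, n = ux, pu, nu

    degenerate = bool(np.all(p == p[0]))
    if degenerate:
        logger.warning("fit_psychometric: degenerate data (all probabilities %.3g)", p[0])

    w = n / n.sum()
    fun = _objective_factory(x, p, w, objective)
    u_lo, u_hi = float(x.min() - 2.0), float(x.max() + 2.0)
    bounds = [G_BOUNDS, L_BOUNDS, (u_lo, u_hi), V_BOUNDS]

    g0 = float(np.clip(p[0], *G_BOUNDS))
    l0 = float(np.clip(1.0 - p[-1], *L_BOUNDS))
    u_grid = np.linspace(x.min(), x.max(), 4)
    v_grid = np.geomspace(0.3, 4.0, 4)

    best = None
    n_restarts = 0
    for u0 in u_grid:
        for v0 in v_grid:
            n_restarts += 1
            res = minimize(fun, x0=[g0, l0, u0, v0], method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    g, l, u, v = (float(t) for t in best.x)
    at_bounds = {
        "g": g in G_BOUNDS, "l": l in L_BOUNDS,
        "u": u in (u_lo, u_hi), "v": v in V_BOUNDS,
    }
    pred = psychometric_value(x, g, l, u, v)
    rss = float(np.sum(w * (p - pred) ** 2))
    return PsychometricFit(g=g, l=l, u=u, v=v, levels=x, lick_probs=p,
                           trial_counts=n, rss=rss,
                           converged=bool(best.success) and not degenerate,
                           n_restarts_used=n_restarts, at_bounds=at_bounds,
                           objective=objective)


_PARAM_NAMES = ("g", "l", "u", "v")


def compare_fits(fits_a: list[PsychometricFit],
                 fits_b: list[PsychometricFit],
                 normality_alpha: float = 0.05) -> dict:
    """Paired per-parameter comparison of two matched lists of fits.

    For each of g, l, u, v: reports the per-pair differences (b - a) and a
    paired two-sided test.  Test choice follows the normality policy: a
    Shapiro-Wilk test on the differences (for n < 30) selects a paired t-test
    when normality is not rejected and a Wilcoxon matched-pairs signed-rank
    test otherwise.  With a single pair (or zero variance) the p-value is NaN.
    """
    if len(fits_a) != len(fits_b):
        raise ValueError("fit lists must be paired (equal length)")
    if not fits_a:
        raise ValueError("empty fit lists")
    out = {}
    for name in _PARAM_NAMES:
        a = np.array([getattr(f, name) for f in fits_a], dtype=float)
        b = np.array([getattr(f, name) for f in fits_b], dtype=float)
        d = b - a
        entry = {"deltas": d, "mean_delta": float(d.mean()), "p": float("nan"),
                 "test": "none"}
        if d.size >= 2 and np.ptp(d) > 0:
            if d.size < 30:
                normal = shapiro(d).pvalue > normality_alpha
            else:
                normal = True
            if normal:
                entry["p"] = float(ttest_rel(b, a).pvalue)
                entry["test"] = "paired-t"
            else:
                entry["p"] = float(wilcoxon(b, a).pvalue)
                entry["test"] = "wilcoxon"
        elif d.size >= 2 and np.ptp(d) == 0 and d[0] == 0:
            entry["p"] = 1.0
            entry["test"] = "identical"
        out[name] = entry
    return out
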