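"""End-to-end pipeline: simulate -> behavior -> psychometrics -> calcium -> selectivity.

``run_pipeline(config, out_dir)`` executes every stage on synthetic data and
writes CSV/JSON artifacts plus a run log.  Rerunning with the same config and
seed reproduces all outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from . import optics
from .behavior import session_included, session_metrics
from .config import load_config
from .exceptions import ParameterError
from .psychometrics import fit_psychometric
from .selectivity import compare_fractions, compute_di_table, selectivity_fractions
from .synth import (CalciumSimParams, ObserverParams, SessionDesign,
                    simulate_calcium_experiment, simulate_session)
from .traces import (apply_sign_flip, dff_from_raw, responsive_cells,
                     responsiveness_records, trial_auc_responsiveness)

logger = logging.getLogger(__name__)

#: responsiveness groups written by the pipeline (texture x outcome x laser)
PIPELINE_GROUPS = {
    "G5-hit-none": dict(texture="G5", outcome="hit", laser="none"),
    "G0-CR-none": dict(texture="G0", outcome="CR", laser="none"),
    "G5-hit-sensory": dict(texture="G5", outcome="hit", laser="sensory"),
    "G0-CR-sensory": dict(texture="G0", outcome="CR", laser="sensory"),
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _observer_from(cfg: dict) -> ObserverParams:
    return ObserverParams(**cfg)


def run_pipeline(config=None, out_dir="texdisc_run") -> dict:
    """Run the full synthetic-data analysis pipeline.

    Returns the JSON-serializable summary (also written to
    ``<out_dir>/summary.json``).  Artifacts: ``session.csv``,
    ``alignment.csv``, ``ground_truth.csv``, ``responsiveness.csv``,
    ``di.csv``, ``fits.json``, ``summary.json``, ``run.log`` and, when
    ``pipeline.save_traces`` is set, ``traces_raw.csv``/``traces_dff.csv``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={_config_hash(cfg)}", f"seed={cfg['seed']}"]

    seed = int(cfg["seed"])
    # documented stream split: behavior, calcium, permutations
    seed_session, seed_calcium, seed_perm = (int(s) for s in
                                             np.random.SeedSequence(seed).generate_state(3) % (2 ** 31))

    # --- stage 1: simulate behavior ------------------------------------
    design = SessionDesign(seed=seed_session, **cfg["session"])
    observer = _observer_from(cfg["observer"])
    laser_observers = {k: _observer_from(v)
                       for k, v in cfg["observer_by_laser"].items()}
    session = simulate_session(observer, design, laser_observers=laser_observers)
    tio.write_trial_table(session, out / "session.csv")
    log_lines.append(f"simulated {len(session)} trials ({design.task})")

    # --- stage 2: behavior metrics -------------------------------------
    conditions = [c for c in ("none", "sensory", "delay")
                  if (session["laser"] == c).any()]
    metrics = {}
    for cond in conditions:
        m = session_metrics(session, laser=cond)
        metrics[cond] = {"hit_rate": m.hit_rate, "fa_rate": m.fa_rate,
                         "percent_correct": m.percent_correct,
                         "dprime": m.dprime, "error_rate": m.error_rate,
                         "n_by_outcome": m.n_by_outcome}
    included = session_included(session)
    if not included:
        logger.warning("session fails the inclusion rule (no-laser d'<=1 and <=70%% correct)")
        log_lines.append("warning: session excluded by performance rule")

    # --- stage 3: psychometric fits ------------------------------------
    fits = {}
    for cond in conditions:
        sub = session[(session["laser"] == cond) & ~session["aborted"]
                      & ~session["bias_correction"]]
        grouped = sub.groupby("stimulus_level", sort=False)
        levels = [design.coordinate(lv) for lv in grouped.groups]
        probs = grouped["licked"].mean().to_numpy()
        counts = grouped["licked"].size().to_numpy()
        fit = fit_psychometric(levels, probs, counts)
        fits[cond] = {"params": fit.params, "rss": fit.rss,
                      "converged": fit.converged, "at_bounds": fit.at_bounds,
                      "levels": list(fit.levels), "lick_probs": list(fit.lick_probs),
                      "trial_counts": [int(n) for n in fit.trial_counts]}
    tio.write_json(fits, out / "fits.json")

    # --- stage 4: calcium simulation and dF/F --------------------------
    calc = CalciumSimParams(seed=seed_calcium, **cfg["calcium"])
    traces, alignment, ground_truth = simulate_calcium_experiment(session, calc)
    tio.write_alignment(alignment, out / "alignment.csv")
    ground_truth.to_csv(out / "ground_truth.csv", index=False)
    ana = cfg["analysis"]
    dff = dff_from_raw(traces, window=int(ana["sg_window"]),
                       polyorder=int(ana["sg_order"]),
                       percentile=float(ana["clip_percentile"]))
    if cfg["pipeline"]["save_traces"]:
        tio.write_traces(traces, out / "traces_raw.csv")
        tio.write_traces(dff, out / "traces_dff.csv")

    responsive = responsive_cells(dff, alignment, alpha=float(ana["alpha"]),
                                  skew_cutoff=float(ana["skew_cutoff"]),
                                  min_trials=int(ana["min_trials"]))
    trial_values = trial_auc_responsiveness(dff, alignment)
    records = responsiveness_records(trial_values, alignment, PIPELINE_GROUPS)
    records = apply_sign_flip(records, reference_group="G5-hit-none")
    records.to_csv(out / "responsiveness.csv", index=False)
    log_lines.append(f"{int(responsive.sum())}/{calc.n_cells} cells responsive")

    # --- stage 5: selectivity ------------------------------------------
    laser_conditions = tuple(c for c in ("none", "sensory") if c in conditions)
    di = compute_di_table(trial_values, alignment, conditions=laser_conditions,
                          n_perm=int(ana["n_perm"]), seed=seed_perm,
                          n_thresholds=int(ana["n_thresholds"]))
    di["responsive"] = responsive[di["cell_id"].to_numpy()]
    di.to_csv(out / "di.csv", index=False)

    selectivity_summary = {}
    for cond in laser_conditions:
        pop = selectivity_fractions(di, cond)
        selectivity_summary[cond] = {"n_cells": pop.n_cells,
                                     "frac_positive": pop.frac_positive,
                                     "frac_negative": pop.frac_negative}
    if len(laser_conditions) == 2:
        a, b = laser_conditions
        da = di[di["condition"] == a].set_index("cell_id")
        db = di[di["condition"] == b].set_index("cell_id")
        common = da.index.intersection(db.index)
        paired = compare_fractions(
            (da.loc[common, "significant"] & (da.loc[common, "di"] > 0)).to_numpy(),
            (db.loc[common, "significant"] & (db.loc[common, "di"] > 0)).to_numpy(),
            paired=True)
        selectivity_summary["hit_selective_none_vs_sensory"] = paired

    # ground-truth recovery: significant-positive rate among simulated
    # hit-preferring cells vs the null (non-selective) cells, no-laser DI
    recovery = {}
    if "none" in laser_conditions:
        d0 = di[di["condition"] == "none"].set_index("cell_id")
        sel_mask = ground_truth.set_index("cell_id")["selective"]
        common = d0.index.intersection(sel_mask.index)
        sig_pos = (d0.loc[common, "significant"] & (d0.loc[common, "di"] > 0))
        truth = sel_mask.loc[common]
        recovery = {
            "true_positive_rate": float(sig_pos[truth].mean()) if truth.any() else float("nan"),
            "null_positive_rate": float(sig_pos[~truth].mean()) if (~truth).any() else float("nan"),
            "null_significant_rate": float(d0.loc[common[~truth.to_numpy()], "significant"].mean())
            if (~truth).any() else float("nan"),
            "n_selective": int(truth.sum()), "n_null": int((~truth).sum()),
        }

    # --- stage 6: optics + report --------------------------------------
    opt = cfg["optics"]
    fiber = optics.FiberSpec(power_mw=float(opt["power_mw"]),
                             core_diameter_um=float(opt["core_diameter_um"]),
                             numerical_aperture=float(opt["numerical_aperture"]))
    optics_summary = {
        "tip_irradiance_mw_mm2": optics.tip_irradiance(fiber),
        "activation_metric": optics.activation_estimate(
            float(opt["expression_area_mm2"]),
            float(opt["irradiance_loss_fraction"])),
    }

    summary = {
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "n_trials": int(len(session)),
        "session_included": bool(included),
        "behavior": metrics,
        "psychometric_fits": {c: f["params"] for c, f in fits.items()},
        "n_responsive_cells": int(responsive.sum()),
        "selectivity": selectivity_summary,
        "ground_truth_recovery": recovery,
        "optics": optics_summary,
    }
    tio.write_json(summary, out / "summary.json")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return summary
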