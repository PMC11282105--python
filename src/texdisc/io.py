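"""CSV/JSON interchange for trial tables, trace matrices and alignments.

CSV is the canonical format (UTF-8, dot decimal, header required).  The trial
table schema is one row per behavioral trial; trace matrices are one row per
cell with a header of frame times; alignment tables carry the per-trial
baseline/sensory windows and group labels.  All writers round-trip losslessly
through the matching readers.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .traces import TraceMatrix

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("trial_id", "stimulus_level", "is_go", "laser", "licked",
                 "outcome", "bias_correction", "aborted")
LASER_VALUES = {"none", "sensory", "delay"}
OUTCOME_VALUES = {"hit", "miss", "FA", "CR", "aborted"}
ALIGNMENT_COLUMNS = ("trial_id", "base_start_s", "base_end_s", "sens_start_s",
                     "sens_end_s", "texture", "outcome", "laser")
_BOOL_COLUMNS = ("is_go", "licked", "bias_correction", "aborted")


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Missing columns and unknown enum values raise :class:`FormatError` with
    the offending column / row numbers; outcomes inconsistent with
    (is_go, licked) produce a warning listing the trial ids.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["trial_id"] = df["trial_id"].astype(int)
    bad = ~df["laser"].isin(LASER_VALUES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # header is line 1
        raise FormatError(f"unknown laser value(s) at line(s) {rows}")
    bad = ~df["outcome"].isin(OUTCOME_VALUES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise FormatError(f"unknown outcome value(s) at line(s) {rows}")
    ok = df["aborted"]
    for is_go, licked, expect in ((True, True, "hit"), (True, False, "miss"),
                                  (False, True, "FA"), (False, False, "CR")):
        m = (df["is_go"] == is_go) & (df["licked"] == licked) & ~df["aborted"]
        ok = ok | (m & (df["outcome"] == expect))
    inconsistent = df.loc[~ok, "trial_id"].tolist()
    if inconsistent:
        logger.warning("outcome inconsistent with (is_go, licked) for trial_id(s) %s",
                       inconsistent)
    return df.loc[:, list(TRIAL_COLUMNS)]


def write_traces(matrix: TraceMatrix, path) -> None:
    """Write a trace matrix: one row per cell, header of frame times."""
    df = pd.DataFrame(matrix.values,
                      columns=[repr(float(t)) for t in matrix.frame_times])
    df.insert(0, "cell_id", np.arange(matrix.n_cells))
    df.to_csv(path, index=False)


def read_traces(path, spacing_rtol: float = 1e-6) -> TraceMatrix:
    """Read a trace-matrix CSV; the sampling rate is inferred from the header.

    Non-uniform frame spacing (beyond ``spacing_rtol`` relative tolerance)
    raises :class:`FormatError`.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "cell_id":
        raise FormatError("trace matrix must start with a cell_id column")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric frame time in header: {exc}") from exc
    if times.size < 2:
        raise FormatError("trace matrix needs at least two frames")
    dt = np.diff(times)
    if np.any(np.abs(dt - dt[0]) > spacing_rtol * abs(dt[0])):
        raise FormatError("frame times are not uniformly spaced")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if values.shape[0] == 0:
        values = values.reshape(0, times.size)
    return TraceMatrix(values=values, sampling_rate=1.0 / dt[0], frame_times=times)


def write_alignment(alignment: pd.DataFrame, path) -> None:
    alignment.loc[:, list(ALIGNMENT_COLUMNS)].to_csv(path, index=False)


def read_alignment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"alignment table missing column(s): {', '.join(missing)}")
    return df.loc[:, list(ALIGNMENT_COLUMNS)]


def write_json(obj, path) -> None:
    """JSON writer tolerant of numpy scalars/arrays."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_default)
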