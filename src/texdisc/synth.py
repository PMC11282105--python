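"""Synthetic behavioral sessions and trial-aligned calcium recordings.

The generator emulates the two go/no-go designs of the study so the whole
analysis pipeline runs without animal data:

* a **discrimination** session presents six textures G0-G5 (smooth foil to
  coarse grating), the no-go G0 on 30% of trials, stimuli ordered randomly
  with never more than two of the same level in a row, lick behavior drawn
  from the 4-parameter psychometric model, and optogenetic-laser trials
  interleaved at 50%;
* a **detection** session presents panel deflections M1-M6 (20.5 deg down to
  0.89 deg) plus no-movement catch trials as the no-go level.

Calcium recordings are simulated as raw fluorescence
``f0 * (1 + drift + transients + noise)`` sampled at 7.5 Hz: each trial places
one calcium transient (difference-of-exponentials kernel, unit peak) at the
sensory-period onset, with an amplitude drawn from the cell's trial-group
mean; cells are either *selective* (different mean on G5-hit versus G0-CR
trials) or *non-selective* (one shared mean).  A slow sinusoidal drift and
i.i.d. Gaussian frame noise exercise the time-varying baseline estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import classify_trial
from .exceptions import AlignmentError, DesignError, ParameterError
from .psychometrics import psychometric_value

DISCRIMINATION_LEVELS = ("G0", "G1", "G2", "G3", "G4", "G5")
DETECTION_LEVELS = ("NoM", "M6", "M5", "M4", "M3", "M2", "M1")
#: panel deflection angles (degrees) behind the ordinal detection coordinates
DETECTION_ANGLES_DEG = {"M1": 20.5, "M2": 13.7, "M3": 6.9, "M4": 3.4,
                        "M5": 1.7, "M6": 0.89, "NoM": 0.0}


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric observer: guess rate g, lapse rate l, bias u, slope v."""

    g: float
    l: float
    u: float
    v: float

    def __post_init__(self):
        if not (0.0 <= self.g <= 1.0 and 0.0 <= self.l <= 1.0):
            raise ParameterError("guess and lapse rates must lie in [0, 1]")
        if self.g + self.l > 1.0:
            raise ParameterError("g + l must not exceed 1")
        if self.v <= 0:
            raise ParameterError("sensitivity v must be > 0")

    def lick_probability(self, x):
        return psychometric_value(x, self.g, self.l, self.u, self.v)


@dataclass
class SessionDesign:
    """Trial structure of one behavioral session.

    ``stimulus_levels`` is ordered from the no-go level upward; the ordinal
    index of a level is its stimulus coordinate (G0 -> 0 ... G5 -> 5;
    NoM -> 0, M6 -> 1 ... M1 -> 6).
    """

    task: str = "discrimination"
    stimulus_levels: tuple = None
    nogo_fraction: float = 0.30
    laser_fractions: dict = field(default_factory=lambda: {"none": 0.5, "sensory": 0.5})
    n_trials: int = 300
    max_consecutive_same: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.stimulus_levels is None:
            if self.task == "discrimination":
                self.stimulus_levels = DISCRIMINATION_LEVELS
            elif self.task == "detection":
                self.stimulus_levels = DETECTION_LEVELS
            else:
                raise DesignError(f"unknown task {self.task!r}")
        self.stimulus_levels = tuple(self.stimulus_levels)
        if len(self.stimulus_levels) != len(set(self.stimulus_levels)) or not self.stimulus_levels:
            raise DesignError("stimulus levels must be non-empty and unique")
        if not (0.0 < self.nogo_fraction < 1.0):
            raise DesignError("nogo_fraction must lie in (0, 1)")
        if self.n_trials <= 0:
            raise DesignError("n_trials must be positive")
        if self.max_consecutive_same < 1:
            raise DesignError("max_consecutive_same must be >= 1")
        tot = sum(self.laser_fractions.values())
        if not np.isclose(tot, 1.0):
            raise DesignError("laser fractions must sum to 1")
        bad = set(self.laser_fractions) - {"none", "sensory", "delay"}
        if bad:
            raise DesignError(f"unknown laser conditions {sorted(bad)}")

    @property
    def nogo_level(self) -> str:
        return self.stimulus_levels[0]

    def coordinate(self, level: str) -> float:
        return float(self.stimulus_levels.index(level))


def _has_long_run(seq, i, k):
    """True if position i sits inside a run longer than k."""
    n = len(seq)
    for s in range(max(0, i - k), min(n - k - 1, i) + 1):
        window = seq[s:s + k + 1]
        if np.all(window == window[0]):
            return True
    return False


def _arrange_with_max_run(level_idx_counts: np.ndarray, max_run: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Arrange a multiset of level indices with no run longer than ``max_run``.

    Random shuffle followed by local repair swaps; exact counts preserved.
    """
    counts = level_idx_counts
    n = int(counts.sum())
    m = int(counts.max())
    # feasibility: blocks of <= max_run of the majority level need separators
    if int(np.ceil(m / max_run)) > n - m + 1:
        raise DesignError(
            "composition incompatible with the max-consecutive-same constraint")
    seq = np.repeat(np.arange(counts.size), counts)
    rng.shuffle(seq)
    for _ in range(100 * n):
        bad = [i for i in range(max_run, n)
               if np.all(seq[i - max_run:i + 1] == seq[i])]
        if not bad:
            return seq
        i = bad[0]
        for _attempt in range(10 * n):
            j = int(rng.integers(n))
            if seq[j] == seq[i]:
                continue
            seq[i], seq[j] = seq[j], seq[i]
            if not _has_long_run(seq, i, max_run) and not _has_long_run(seq, j, max_run):
                break
            seq[i], seq[j] = seq[j], seq[i]
        else:
            rng.shuffle(seq)
    raise DesignError("could not satisfy the trial-order constraint")


def simulate_session(observer: ObserverParams, design: SessionDesign,
                     laser_observers: dict | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one behavioral session as a trial table.

    Licks are Bernoulli draws from the observer's psychometric curve evaluated
    at the level's ordinal coordinate; the no-go level sits at x = 0 so the
    guess rate g is the asymptotic false-alarm rate.  ``laser_observers`` may
    map a laser condition to a different :class:`ObserverParams` to model a
    behavioral laser effect; unlisted conditions use ``observer``.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    levels = design.stimulus_levels
    n_go_levels = len(levels) - 1
    probs = np.full(len(levels), (1.0 - design.nogo_fraction) / n_go_levels)
    probs[0] = design.nogo_fraction
    counts = rng.multinomial(design.n_trials, probs)
    order = _arrange_with_max_run(counts, design.max_consecutive_same, rng)

    laser_names = list(design.laser_fractions)
    laser_p = np.array([design.laser_fractions[k] for k in laser_names])
    laser = rng.choice(laser_names, size=design.n_trials, p=laser_p)

    laser_observers = laser_observers or {}
    rows = []
    u = rng.random(design.n_trials)
    for t in range(design.n_trials):
        level = levels[order[t]]
        obs = laser_observers.get(laser[t], observer)
        p_lick = obs.lick_probability(design.coordinate(level))
        licked = bool(u[t] < p_lick)
        is_go = level != design.nogo_level
        rows.append({
            "trial_id": t,
            "stimulus_level": level,
            "is_go": is_go,
            "laser": laser[t],
            "licked": licked,
            "outcome": classify_trial(is_go, licked),
            "bias_correction": False,
            "aborted": False,
        })
    return pd.DataFrame(rows)


@dataclass
class CalciumSimParams:
    """Parameters of the simulated two-photon recording.

    Amplitudes are transient peaks in dF/F percent.  ``amp_by_group`` maps a
    "<texture>-<outcome>" group key to the mean amplitude of *selective*
    cells; non-selective cells (and unlisted groups) use ``nonselective_amp``.
    ``laser_amp_scale`` optionally scales amplitudes on laser trials (default:
    control values).  Each trial spans ``pre_s`` seconds before the sensory
    onset (the 4 s pre-stimulus epoch) and ``post_s`` after the sensory window
    (delay + response + inter-trial gap).
    """

    n_cells: int = 100
    frac_selective: float = 0.30
    amp_by_group: dict = field(default_factory=lambda: {"G5-hit": 20.0, "G0-CR": 5.0})
    nonselective_amp: float = 12.5
    amp_sd: float = 4.0
    kernel_rise: float = 0.2
    kernel_decay: float = 1.5
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    drift_period: float = 120.0
    baseline_f0: float = 100.0
    sampling_rate: float = 7.5
    baseline_window_s: float = 3.8
    sensory_window_s: float = 3.8
    pre_s: float = 4.0
    post_s: float = 5.6
    laser_amp_scale: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise ParameterError("need kernel_decay > kernel_rise > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.baseline_window_s <= 0 or self.sensory_window_s <= 0:
            raise ParameterError("analysis windows must be > 0")
        if self.baseline_window_s > self.pre_s:
            raise ParameterError("baseline window cannot exceed the pre-stimulus epoch")
        if not (0.0 <= self.frac_selective <= 1.0):
            raise ParameterError("frac_selective must lie in [0, 1]")


def make_kernel(rise_s: float, decay_s: float, sampling_rate: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient kernel, unit peak.

    k(t) = exp(-t/decay) - exp(-t/rise), rescaled to peak 1 and truncated once
    it falls below 1e-3 of the peak.
    """
    if not (decay_s > rise_s > 0):
        raise ParameterError("need decay_s > rise_s > 0")
    t_peak = np.log(decay_s / rise_s) * rise_s * decay_s / (decay_s - rise_s)
    t_end = t_peak + decay_s * np.log(1e3) + 1.0
    t = np.arange(0.0, t_end, 1.0 / sampling_rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    k /= k.max()
    above = np.nonzero(k >= 1e-3)[0]
    return k[: above[-1] + 1]


def unit_kernel_auc(params: CalciumSimParams) -> float:
    """Discrete trapezoidal area of the unit-peak kernel over the sensory window.

    Multiplying by a transient's peak amplitude (dF/F %) gives the expected
    ``texture_responsiveness`` contribution of that transient (dF/F % * s).
    """
    k = make_kernel(params.kernel_rise, params.kernel_decay, params.sampling_rate)
    n_win = int(np.floor(params.sensory_window_s * params.sampling_rate + 1e-9))
    seg = np.zeros(n_win)
    seg[: min(n_win, k.size)] = k[:n_win]
    return float(np.trapezoid(seg, dx=1.0 / params.sampling_rate))


def _group_key(texture: str, outcome: str) -> str:
    return f"{texture}-{outcome}"


def simulate_calcium_experiment(session: pd.DataFrame, params: CalciumSimParams):
    """Simulate raw fluorescence aligned to a behavioral session.

    Returns ``(traces, alignment, ground_truth)``:

    * ``traces`` — :class:`texdisc.traces.TraceMatrix`, cells x frames raw
      fluorescence;
    * ``alignment`` — one row per trial with half-open baseline and sensory
      windows (both ``baseline_window_s``/``sensory_window_s`` long, the
      baseline being the last part of the pre-stimulus epoch) and the trial's
      texture/outcome/laser labels;
    * ``ground_truth`` — per cell: selectivity label and the mean transient
      amplitudes used for the G5-hit and G0-CR groups.
    """
    from .traces import TraceMatrix  # local import to avoid a cycle

    if session.empty:
        raise AlignmentError("session is empty")
    rng = np.random.default_rng(params.seed)
    r_cells, r_amp, r_noise = rng.spawn(3)

    fs = params.sampling_rate
    n_trials = len(session)
    trial_len_s = params.pre_s + params.sensory_window_s + params.post_s
    frames_per_trial = int(round(trial_len_s * fs))
    n_frames = n_trials * frames_per_trial
    frame_times = np.arange(n_frames) / fs

    selective = np.zeros(params.n_cells, dtype=bool)
    n_sel = int(round(params.frac_selective * params.n_cells))
    selective[r_cells.choice(params.n_cells, size=n_sel, replace=False)] = True
    phases = r_cells.uniform(0, 2 * np.pi, size=params.n_cells)

    kernel = make_kernel(params.kernel_rise, params.kernel_decay, fs)
    signal = np.zeros((params.n_cells, n_frames))
    records = []
    for t, row in enumerate(session.itertuples(index=False)):
        t0 = t * frames_per_trial / fs
        onset = t * frames_per_trial + int(round(params.pre_s * fs))
        key = _group_key(row.stimulus_level, row.outcome)
        mean_sel = params.amp_by_group.get(key, params.nonselective_amp)
        scale = params.laser_amp_scale.get(row.laser, 1.0)
        means = np.where(selective, mean_sel, params.nonselective_amp) * scale
        amps = np.clip(r_amp.normal(means, params.amp_sd), 0.0, None)
        seg = min(kernel.size, n_frames - onset)
        if seg <= 0:
            raise AlignmentError("trial window exceeds the trace length")
        signal[:, onset:onset + seg] += amps[:, None] / 100.0 * kernel[:seg]
        records.append({
            "trial_id": getattr(row, "trial_id", t),
            "base_start_s": t0 + params.pre_s - params.baseline_window_s,
            "base_end_s": t0 + params.pre_s,
            "sens_start_s": t0 + params.pre_s,
            "sens_end_s": t0 + params.pre_s + params.sensory_window_s,
            "texture": row.stimulus_level,
            "outcome": row.outcome,
            "laser": row.laser,
        })
    alignment = pd.DataFrame(records)

    drift = (params.drift_amplitude / 100.0) * np.sin(
        2 * np.pi * frame_times[None, :] / params.drift_period + phases[:, None])
    noise = r_noise.normal(0.0, params.noise_sd / 100.0,
                           size=(params.n_cells, n_frames)) if params.noise_sd > 0 \
        else np.zeros((params.n_cells, n_frames))
    raw = params.baseline_f0 * (1.0 + drift + signal + noise)

    ground_truth = pd.DataFrame({
        "cell_id": np.arange(params.n_cells),
        "selective": selective,
        "amp_hit": np.where(selective,
                            params.amp_by_group.get("G5-hit", params.nonselective_amp),
                            params.nonselective_amp),
        "amp_cr": np.where(selective,
                           params.amp_by_group.get("G0-CR", params.nonselective_amp),
                           params.nonselective_amp),
    })
    traces = TraceMatrix(values=raw, sampling_rate=fs)
    return traces, alignment, ground_truth
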