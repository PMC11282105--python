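# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `texdisc`, and what the test suite does and does not
establish about real recordings.

## Task model and trial classification

Two go/no-go designs are supported.  *Discrimination*: six textures G0–G5
ordered by grating coarseness, G0 (smooth foil) the punished no-go presented
on 30% of trials by default, all gratings rewarded.  *Detection*: panel
deflections M1–M6 (20.5, 13.7, 6.9, 3.4, 1.7, 0.89°) plus no-movement (NoM)
catch trials as the no-go.  Stimuli are coded on an ordinal axis (G0→0 …
G5→5; NoM→0, M6→1 … M1→6) because performance is defined over ordered
categories, not a physical continuum; the detection angles are carried as
metadata only.

Outcomes follow signal detection: go∧lick→hit, go∧¬lick→miss, ¬go∧lick→FA,
¬go∧¬lick→CR.  Aborted trials (licks during the delay epoch) and
bias-correction trials are excluded from every analysis; aborted trials are
never counted as FAs.  Percent correct, d′ and error rate are restricted to
the trained pair (G5/G0, or M1/NoM for detection).

**d′ clipping.**  Hit and FA rates are clipped to [1/(2N), 1 − 1/(2N)] per
response category before the inverse-normal transform (the standard
log-linear correction), keeping d′ finite for perfect sessions.  The choice
of correction is a package decision; no rule is implied by the metric
itself.

**Whisk rate.**  A whisk is one protraction sweep: an upward excursion
between alternating local extrema of the whisker-angle trace whose
peak-to-trough amplitude exceeds a threshold (default 5°; the qualitative
definition of a whisk leaves this to the analyst).  Window endpoints count
as candidate extrema so a single monotonic sweep is one whisk.  The rate is
sweeps per 3.84 s sensory period.

## Psychometric model

y(x) = g + (1 − g − l)·½·(1 + erf((x − u)/√(2v²))).  Fitting minimizes the
trial-count-weighted squared error between observed and predicted per-level
lick probabilities (a binomial negative log-likelihood objective is
available behind `objective="nll"`); weighted least squares is the default
because the typical use fits per-mouse averaged points.  Bounds: g, l ∈
[0, 0.6]; u ∈ [min x − 2, max x + 2]; v ∈ (10⁻³, 10] on the ordinal axis;
g + l ≤ 1 enforced by a quadratic penalty.  Optimization is L-BFGS-B from a
deterministic 4×4 multi-start grid over (u, v) with asymptote starts read
off the endpoint probabilities; the best objective across restarts is
reported with bound-hit flags.  Duplicate levels are pooled
(count-weighted) before fitting, which makes the fit invariant to splitting
a level's trials across rows.  Paired fit comparisons test each parameter's
differences with a Shapiro–Wilk normality gate (n < 30): paired t when
normality is not rejected, Wilcoxon matched-pairs otherwise.

## Calcium-trace processing

Frame rate 7.5 Hz (layer 2/3 two-photon imaging); all windows are expressed
in seconds and converted to frames internally.

**Baseline / ΔF/F.**  The time-varying baseline is estimated per cell by
clipping each frame to a running 10th percentile (centred 81-frame window,
~10.8 s), smoothing with a 4th-order 81-point Savitzky–Golay filter
(mirror-padded edges), and recentring by adding back the per-cell median
residual.  Rationale: with a GCaMP-like transient (0.2 s rise, 1.5 s decay,
truncated at 10⁻³ of peak) the decay tail occupies ~80% of the frames of a
13 s trial, so a running *median* rides up on tail frames and systematically
underestimates transient amplitude (measured ~8–16% low under the
generator's defaults).  A low percentile is robust to that duty cycle but
sits below the trace's central level; the recentring constant restores an
unbiased ΔF/F around zero on transient-free data and, being a per-cell
constant, cancels exactly in every sensory-minus-baseline contrast.
ΔF/F = 100·(raw − baseline)/baseline.  Traces shorter than the filter
window raise an error instructing a window reduction via the config.

**Windows.**  Each trial has a 4 s pre-stimulus epoch and a 3.8 s sensory
(texture) period; the analysis baseline window is the last 3.8 s of the
pre-stimulus epoch.  A window [start, end) selects the first frame at time
≥ start and then a fixed count of ⌊duration·fs⌋ frames.  The fixed count —
rather than "all frames with time < end" — guarantees the two equal-duration
windows always contain equally many frames, so constant trace components
cancel exactly in AUC differences (3.8 s × 7.5 Hz = 28.5 is non-integral,
and naive half-open selection would give 28 frames in one window and 29 in
the other depending on grid alignment).  Consequently the discrete
trapezoidal AUC of a unit step spanning the sensory window is 27·(1/7.5) =
3.6 ΔF/F%·s, the frame-grid counterpart of the continuous 3.8.

**Responsiveness screen.**  For each of the four groups {G5, G0} ×
{no-laser, sensory-laser} (outcomes pooled) with ≥ 5 trials, the per-trial
differences (sensory-window mean − baseline-window mean) are tested against
zero: Wilcoxon signed-rank when the adjusted Fisher–Pearson |skew| < 0.6,
two-sided sign test (ties dropped) otherwise, with |skew| = 0.6 routed to
the sign test.  A cell is responsive when any group's p < 0.05; no
multiplicity correction is applied across the four groups, so the null
family-wise rate is 1 − 0.95⁴ ≈ 0.19 by construction (verified by Monte
Carlo in the tests).

**Texture responsiveness and sign flip.**  Group responsiveness is the mean
over trials of (trapezoidal AUC over the sensory window − AUC over the
baseline window), in ΔF/F%·s.  Cells whose no-laser G5 value is negative
(suppressed cells) have all *other* group values negated — the reference
itself is untouched — so suppression and enhancement share a sign
convention.  The transform is applied exactly once by the pipeline.

## Discrimination index

Per cell and laser condition, per-trial AUC-difference responses on G5-hit
trials (group a) versus G0-CR trials (group b) build an ROC: 1000 thresholds
evenly spaced from the pooled minimum to maximum; each threshold plots the
fraction of a-trials against the fraction of b-trials whose response
*strictly exceeds* it; the curve is closed at (0,0) and (1,1) and integrated
by trapezoid.  DI = (AUC − 0.5) × 2.  The per-trial AUC-difference response
(rather than the window-mean ΔF/F) is the default response variable; the
mean is available by passing different trial values.  The threshold sweep
converges to the Mann–Whitney statistic U/(nₐn_b) with ties counted ½; the
exact rank computation is provided as `method="rank"` and serves as the
independent oracle in the tests, never as the default.  The sweep's
resolution is (range/999): responses closer than one grid step but not
exactly equal merge into a diagonal segment, an inherent property of the
linear threshold construction.

**Permutation significance.**  The null distribution is the DI over 1000
trial-label shuffles preserving group sizes; the observed DI is significant
when outside the [2.5th, 97.5th] percentile interval (no p-value
interpolation).  Each cell uses an independent RNG substream spawned from
the run seed, making results reproducible and cell-order invariant.  The
shuffled AUCs are computed by a label-matrix × exceedance-matrix product, so
the full 1000-shuffle null for a 40-trial cell costs two 1000×40 × 40×1000
matrix multiplies.  Constant (zero-variance) cells are flagged degenerate,
AUC 0.5, not significant.

**Population statistics.**  Fractions of significant-positive and
significant-negative cells per condition; paired fraction comparisons (same
cells) by McNemar's test (χ² without continuity correction by default — the
discordant-pair closed form (n₁₀ − n₀₁)²/(n₁₀ + n₀₁) — exact binomial
optional; no discordant pairs → p = 1); unpaired comparisons by a two-sided
two-proportion z-test.  Hit-vs-CR responsiveness slopes per condition are
OLS, with the condition difference tested as the x-by-condition interaction
in a pooled regression.  The encoding model regresses per-trial
responsiveness on texture (G5 = 1, G0 = 0) and choice (lick = 1) per cell,
reporting coefficients with 95% CIs; texture ≡ choice sessions are flagged
collinear.

## Optics helpers

Fiber-tip irradiance = power / core area (4 mW through a 200 µm core ≈
127.3 mW/mm²).  The opsin-activation metric is expression area ×
irradiance-loss fraction; the tissue-attenuation model producing the loss
fraction is deliberately outside the package, keeping it free of
tissue-optics assumptions.

## Synthetic-data generator

The generator defines the study conditions the pipeline is tested under.

*Sessions*: level counts drawn from the exact multinomial (no-go fraction
0.30, go levels uniform), then arranged with no more than two identical
levels in a row via shuffle-with-repair swaps (full-sequence rejection
sampling cannot terminate at session sizes, and per-trial conditional
redraws bias the no-go marginal low).  Infeasible compositions raise a
design error.  Laser conditions are i.i.d. per trial (none/sensory at 50%
each by default).  Licks are Bernoulli draws from the observer's
psychometric curve at the level's ordinal coordinate — the no-go level sits
on the same curve at x = 0, so g is the asymptotic FA rate; a per-condition
observer map models behavioral laser effects.

*Calcium*: raw fluorescence f0·(1 + drift + transients + noise) at 7.5 Hz.
Each trial spans 4 s pre-stimulus + 3.8 s sensory + 5.6 s post (delay,
response, inter-trial gap ≈ the task's timing).  One transient per trial per
cell at the sensory onset: difference-of-exponentials kernel (rise 0.2 s,
decay 1.5 s, unit peak, truncated at 10⁻³), amplitude drawn
N(group mean, amp_sd = 4 ΔF/F%) clipped at zero — trial-to-trial amplitude
variability is what gives the ROC/DI analysis a realistic operating regime.
Selective cells (30% by default) use group means 20 ΔF/F% on G5-hit and
5 ΔF/F% on G0-CR trials; non-selective cells and unlisted groups share
12.5 ΔF/F%.  Laser trials keep control amplitudes unless a scale factor is
configured.  Drift is a single slow sinusoid (2 ΔF/F%, 120 s period, random
phase per cell) and noise is i.i.d. Gaussian per frame (1 ΔF/F%) — the
simplest structure that exercises the time-varying baseline estimator.
`unit_kernel_auc` gives the closed-form discrete kernel area over the
sensory window, so ground-truth responsiveness is amp × that area.

*Randomness*: a single run seed is split into documented substreams
(session, calcium, permutations) via NumPy's `SeedSequence`/`spawn`; equal
seeds reproduce every artifact bit for bit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: within-trial lick dynamics, motivational drift and
satiation, correlated (shared) noise across cells, neuropil contamination,
motion artifacts, non-sinusoidal slow drift, multi-transient trials, and any
biophysical laser effect (the laser enters only as amplitude scaling and as
a different behavioral observer).  Ground-truth recovery results quantify
the statistics pipeline, not imaging preprocessing.

## Problem sizes and defaults in the test suite

The acceptance tests use the conditions stated above: 10 000 trials for the
session-composition check; 200 random instances (n ≤ 20 per group) for the
ROC/Mann–Whitney oracle; 1000 null cells × 1000 shuffles (20 + 20 trials)
for permutation-null calibration; 100 replicates at 200 trials/level for
psychometric recovery; a 200-trial, 100-cell (30% selective) experiment for
end-to-end ground-truth recovery.  The unit suite uses smaller sizes chosen
for statistical validity of each check (e.g. joint χ² bounds rather than
per-level 3σ bounds when six levels are tested at once).

## Known limitations

- The ROC threshold sweep cannot separate responses closer than one grid
  step (range/999); use `method="rank"` when exact tie handling matters.
- The psychometric fit reports boundary flags rather than profile-likelihood
  intervals; degenerate (all-0/all-1) data return a flagged boundary fit.
- McNemar's χ² form is used by default; for very small discordant counts
  pass `exact=True`.
- The baseline estimator assumes transients are positive-going; purely
  inhibitory (negative) transients would be clipped as baseline.
- `is_responsive` applies no multiplicity correction across trial groups by
  design; interpret the per-cell responsive fraction accordingly.
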