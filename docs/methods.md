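# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `sahpkit`.  It states how things are
computed; every empirical number it refers to is produced by the test suite
or `scripts/acceptance.py`, not asserted here.

## Sweep model and units

A sweep is a uniformly sampled membrane-potential record (mV) with its
current protocol: holding current keeping the baseline near −70 mV, a
−20 pA / 200 ms hyperpolarizing probe (onset 200 ms), a 600 ms depolarizing
step from the 150–450 pA grid in 25 pA increments (onset 700 ms), recording
out to 8 s, and a 200 ms zero-current segment appended at the end.  Time is
seconds on the in-memory grid and milliseconds in metadata and reports;
resistances are MΩ and currents pA, so Ohm's law carries a single conversion
constant (`MV_PER_PA_MOHM = 1e-3`) defined once in `sahpkit.io`.

On disk, cells are stored either as per-cell TSV sweep tables with a JSON
protocol sidecar, or as an HDF5 cohort container; both round-trip losslessly.
Vendor acquisition formats are out of scope.

## Synthetic sweep generator

The generator produces traces as an exact sum of components — baseline +
passive response + spike templates + AHP tail + noise — and returns that
decomposition, so downstream recovery can always be scored against truth.

* **Passive response.**  The probe and the zero-current step follow the
  two-branch linear charging model exactly (series/pipette branch R_a, τ_p;
  membrane branch R_in, τ_m).  The depolarizing step instead charges toward a
  sub-threshold plateau 5 mV below spike threshold with τ_m, because at
  150–450 pA the linear extrapolation (tens of mV above threshold) is
  unphysical — spiking clamps a real membrane near threshold — and would also
  defeat the +40 mV spike-detection criterion.  At step offset the
  depolarization ends instantly (active repolarization), so the AHP rides on
  a clean baseline.
* **Spikes.**  Stereotyped piecewise templates: a 2 ms sub-threshold approach
  ramp, an exponential upstroke from a threshold kink (rise τ 0.12 ms), and
  an exponential repolarization (fall τ 1.1 ms), peaking 80 mV above resting
  potential.  No conductance model: the analysis under test needs realistic
  geometry (sharp threshold kink, ~1 ms half-width, >40 mV height), and
  templates keep ground truth exact.  Spike count per sweep is
  `round(spike_gain × (I − 125 pA))` with `spike_gain = 0.05` spikes/pA, so
  counts grow from ~1 at 150 pA to ~16 at 450 pA; inter-spike intervals
  stretch geometrically so last/first ISI equals the accommodation parameter
  (default 2.0).  The first peak sits 10 ms after step onset and the last
  30 ms before offset, so templates never contaminate the AHP window.
* **AHP.**  From the first sample after step offset to the end of the 8 s
  record, `V_med·e^(−t/τ_med) + V_slow·e^(−t/τ_slow)` is added relative to
  baseline (defaults −3.5 mV / 150 ms and −1.4 mV / 6 s, the scale of the
  validation measurements the analysis is aimed at).
* **Noise.**  White Gaussian noise low-passed (zero-phase 4th-order
  Butterworth) at 2 kHz to mimic 0–2 kHz acquisition, rescaled so the added
  noise has exactly `noise_sd`.  Recording-noise amplitude is not something
  the source measurements pin down; the default 0.2 mV sits in the middle of
  the plausible 0.1–0.3 mV range and is a free realism parameter.
* **Cohorts.**  Cell *i*, step *s*:
  `|v_slow|(i,s) = a0 + u0_i + (b + u1_i + γ·T_i)(s − 300)` with treated
  indicator T, random intercept u0 ~ N(0, 0.3² mV²), random slope
  u1 ~ N(0, 0.001² (mV/pA)²), residual sd 0.3 mV, base amplitude
  a0 = 1.6 mV and base growth b = 0.004 mV/pA.  a0 is set high enough that
  amplitudes stay positive over the whole step range at the default effect
  sizes (amplitudes are floored at zero, and a floor engaged at low steps
  would bend the generative line the inference assumes straight).  γ is the
  generative treatment × current interaction; the default 0.003 mV/pA gives
  a clearly detectable effect at 20+15 cells, while 0.001 mV/pA is the
  "under-powered study" regime used in the power analysis.  Missingness is
  MCAR (the corruption mechanism being emulated is unspecified beyond
  "random noise"); outliers displace observations by a multiple of the
  residual sd.  Cell counts default to 20 vehicle + 15 treated, patterned on
  typical per-region cohort sizes.

What the generator deliberately does **not** emulate: conductance-based spike
dynamics, electrode drift and seal instability, sag/rebound (Ih), bursting,
non-MCAR missingness, and region differences beyond parameter presets.
Passing tests therefore demonstrate that the pipeline recovers what it
claims under realistic geometry, kinetics and noise — not that it is robust
to every pathology of real recordings.

## Passive fitting

The probe segment of the 1 ms-smoothed trace is fitted by Nelder–Mead over
(τ_p, τ_m) with the offset and both amplitudes profiled out by linear least
squares at every simplex vertex (they enter the model linearly); τ_p is
constrained to (0, 10] ms by a sigmoid transform and τ_m by positivity
(log transform), with a method-of-moments seed and two perturbed restarts.
Because the local-linear midpoint smoother is a boxcar average, inside the
step it maps `e^(−t/τ)` to `c(τ)·e^(−t/τ)` with
`c(τ) = sinh(wΔ/2τ)/(w·sinh(Δ/2τ))`; the fit uses this smoothed forward
model and excludes the half-window at each step edge where the kernel
straddles the current kink — without this the fast branch is biased by
several percent.  The segment is subsampled to 10 kHz for speed (the
smoothing has already band-limited it).

The fast/slow labels are assigned by time constant (fast = pipette/series,
slow = membrane, τ_p < 10 ms); this is the only physically consistent
reading of a two-saturating-exponential charging model.  A direct estimator
(steady-state deflection for the total resistance; weighted log-linear
regression of the late phase for R_in and τ_m) provides a fit-free
cross-check, valid when τ_p ≪ τ_m and the step reaches steady state.  The
cell-inclusion filter keeps 100 ≤ R_in ≤ 450 MΩ, inclusive on both ends
(the conservative reading of "between").  Resting potential falls back to
the zero-current tail mean (last half of the segment, letting the membrane
relax) when no break-in value exists — synthetic data has none.

## Spike analysis

Detection runs on the 1 ms-smoothed trace: peaks more than 40 mV above the
pre-step baseline (mean of the 100 ms before the depolarizing step), with a
2 ms minimum separation — below any physiological ISI, above noise-peak
spacing.  Waveform measurements (threshold, rise time, slope, half-width)
run on a lightly smoothed copy (0.2 ms window): the 20–80% rise of a
pyramidal spike spans only ~8–10 samples at 50 kHz, and a 1 ms local-linear
window smears the threshold kink by about half a window, biasing the
20 mV/ms crossing several mV hyperpolarized.  The light window suppresses
band-limited noise in the derivative (whose sd is a few mV/ms, far below
the 20 mV/ms criterion) without destroying sub-millisecond geometry.

Threshold is found by walking backward from the peak into the contiguous
run of samples whose centered-difference dV/dt stays ≥ 20 mV/ms and taking
that run's earliest sample; scanning backward avoids noise-triggered early
crossings.  Crossing times for the 20%/80%/50% levels are sub-sample
interpolated (at 50 kHz a ~170 µs rise time is 8–10 samples, so
interpolation materially reduces quantization error).  Both the absolute
peak potential and the peak-minus-threshold amplitude are reported, since
both conventions appear in the literature.  The accommodation ratio
100 × (last ISI / first ISI) requires ≥ 3 spikes; with exactly two the
first and last interval coincide and the ratio is reported missing.
Cell-level active properties are the feature-wise mean of each step's first
spike.

## AHP decomposition

The AHP peak is the most negative excursion relative to the pre-probe
baseline within 100 ms after step offset, on the smoothed trace.  The fit
window runs from that peak to the end of the record minus 1 ms (the
smoothing kernel straddles the zero-current kink in that last millisecond),
baseline-subtracted.  The window is decimated to 1 kHz by **block
averaging** rather than FIR decimation: an anti-aliasing filter's impulse
response rings for tens of milliseconds around the step-offset kink and
contaminates exactly the early samples that identify the medium component,
whereas block averaging has one-sample support and merely rescales each
exponential by a factor that is negligible for τ ≥ 50 ms.

SSE is minimized by Nelder–Mead over (V_med, τ_med, V_slow, τ_slow) with
each τ mapped onto its bound interval — (0, 400] ms medium, (400, 8000] ms
slow — through a logit-style transform; nine starts from the
(50, 150, 350) × (1000, 3000, 6000) ms τ grid with linear-least-squares
amplitudes, best SSE wins, ties broken toward smaller τ_slow.  Components
are labeled by bound interval, never by amplitude; amplitudes are signed,
negative-down.  r² is the squared Pearson correlation of fit and (smoothed,
decimated) data over the window.  Flags: `at_bound` when a τ carrying
non-negligible amplitude (> 5% of the peak) sits within 1% of a bound;
`ill_conditioned` when τ_slow/τ_med < 1.6 — when both generative decays
fall near the 400 ms boundary the two-component problem is genuinely
ill-posed and the flag rate is high by design rather than hidden.  The
ablation contrast averages each component's fitted amplitude over the
325–450 pA steps before/after a manipulation and reports percent changes.

## Cohort inference

The mixed model regresses the response on treatment, current step, and
their interaction, with per-cell random intercepts and slopes.  Step enters
as a centered continuous covariate in 100 pA units: the single-χ²
interaction tests being reproduced are 1-df trend tests, which a 13-level
factor interaction (12 df) cannot produce; the factor coding remains
available behind `step_factor=True`.  Estimation is maximum likelihood
(statsmodels `MixedLM`; lbfgs with bfgs/powell fallbacks) — never REML,
because the LRTs compare fixed-effect structures.  A singular
random-effects covariance triggers a refit with independent intercept and
slope, and the two fits of an LRT are forced onto the same random-effects
structure so the models nest; a slightly negative LR statistic (optimizer
noise on the boundary) clips to zero, grossly negative raises.

Influence screening computes observation-level Cook's distances
`D_i = (β − β₍ᵢ₎)ᵀ Cov(β)⁻¹ (β − β₍ᵢ₎)/p` by actually refitting the model
without each observation (warm-started from the full fit), matching
case-deletion semantics; a fast approximation that whitens each cell's
block by the Cholesky factor of its marginal covariance and applies the
OLS hat-matrix formula is available (`method="gls"`) but is only an
approximation because it conditions on the full-fit variance components.
Observations above 4/n are set missing and re-imputed.

Imputation models the per-cell response profile across the 13 steps,
augmented with the group indicator, as multivariate normal.  For each of m
imputations (default 20) the cells are bootstrap-resampled, (μ, Σ)
re-estimated by EM on the resample, and the original missing entries drawn
from the conditional normal — EM-with-bootstrapping, so each imputation
carries parameter uncertainty.  With ~35 cells in 14 dimensions Σ is barely
identified; a light ridge (2 pseudo-observations of the diagonal) plus 5%
shrinkage of off-diagonal correlations keeps EM stable at the cost of
slightly conservative imputed correlations.  Estimates pool by Rubin's
rules (Barnard–Rubin df); LRT statistics pool by the D2
chi-square-combination statistic against its F reference.  Both
pool-the-fits and average-then-fit workflows are possible; pooling is the
default and the one the pipeline uses.

The sAHP-vs-spike-count correlation uses per-(group, step) means — 13
paired points per group — with a two-sided Pearson test; per-observation
pairing would mix within- and between-cell variation.

Power analysis simulates table-level cohorts from a generative effect
specification (either ground truth or `effect_spec_from_lme` of a fitted
model), runs the full fit + LRT on each, and reports rejection fractions
with Monte-Carlo standard errors over a grid of total cell counts.  A
closed form for the 1-df test — noncentral χ²₁ with
λ = γ²/[(σ_u1² + σ²/Sxx)(1/n₁ + 1/n₂)] — serves as an analytic cross-check.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; cohort- and sweep-level
seeds derive from it through `numpy` generators, and identical seeds give
bit-identical traces, tables and pipeline outputs.  The analysis scripts
and the acceptance script run sweep generation at 25 kHz (the protocol
default is the 50 kHz acquisition rate; both are supported and tested —
halving the rate leaves every sub-millisecond feature with 4+ samples while
halving runtime), with 20+15-cell cohorts, 10–20 imputations, and a few
hundred Monte-Carlo replicates per calibration quantity; these sizes are
the package's choice of a desk-scale experiment and are set in one place in
each script.

## Limitations

* Spike templates are additive and stereotyped; features of overlapping or
  bursting spikes are not modeled.
* The depolarizing-step plateau is a modeling convenience; sub-threshold
  nonlinearities (Ih sag, persistent sodium) are absent.
* The bi-exponential AHP model is assumed, not selected; a third component
  or conductance-based decay would be absorbed into the two fitted terms.
* MCAR is assumed by both the generator and the imputation model; informative
  missingness (e.g. losing exactly the large-amplitude sweeps) would bias
  the pooled estimates.
* The EM ridge/shrinkage slightly attenuates imputed between-step
  correlations; with ≤ 20 cells per group this is the price of a stable Σ.
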