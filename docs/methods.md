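# Methods

## The estimation problem

During fixation, monkeys make microsaccades (~0.1–0.3°).  If a peripheral
stimulus appears, extra-foveal SC neurons emit a visual burst 30–100 ms
later; a microsaccade triggered in that window is executed while
movement-unrelated spikes are present on the SC map.  The package's central
quantity is the per-spike amplitude gain β₁ of

    amplitude_i = β₀ + β₁ · S_i + ε_i,

where S_i is the number of spikes the recorded neuron fired in the 0–20 ms
window after movement onset (half-open, like every window in the package).
The model is fit by OLS to movement-level rows, never to per-level means;
predictor levels with fewer than `min_trials_per_level = 15` movements are
excluded first, as are counts above `max_spike_level = 5`.  "GLM" in this
literature means exactly this Gaussian identity-link model; the reported t,
p and model-vs-constant F statistics are the classical linear-model ones,
and F = t² holds for the single-predictor fit.  Alongside the classical
standard errors the fits report HC1 heteroskedasticity-robust ones, because
amplitude scatter in both real and synthetic data grows with the conditional
mean; recovery tests use the robust errors.

Movements are classified *toward* a neuron's RF when their direction lies
within ±90° (inclusive) of the RF direction on the circle, otherwise
*opposite*.  Movement selection modes: `post_stimulus` (onset 0–200 ms after
stimulus onset, first qualifying movement per trial), `sustained` (onset
>550 ms after stimulus onset, all movements), `baseline` (500–1500 ms before
stimulus onset).

## Microsaccade detection

The detection algorithm is unspecified in the source analyses, so the
package uses the field-standard adaptive-velocity-threshold detector,
fully parameterized in `DetectParams`:

* positions are smoothed with a 5-sample moving average and differentiated
  by central differences (one-sided at the ends);
* the noise spread of each velocity component is estimated robustly as
  √(median(v²) − median(v)²) — computed per signed component, since on the
  nonnegative radial speed this estimator is identically zero;
* samples exceeding the elliptic threshold at λ = 6 noise SDs mark
  candidate events; candidates must stay above threshold for ≥3 ms
  (rejecting single-sample noise exceedances), are extended outward to a
  λ = 3 ellipse and then down the flanks to the local speed minimum (which
  removes the threshold-crossing bias from onset/offset times), merged when
  closer than 20 ms, and kept if ≥6 ms long;
* amplitude is the Euclidean displacement between the *smoothed* positions
  at onset and offset — using raw samples would add the fixation noise of
  two samples to every amplitude and measurably inflate the fitted β₀.

On generator output at default noise (σ = 0.005°), recall for movements
≥0.1° exceeds 99%, onset error is ≈0 ± 1.5 ms, and the false-positive rate
is ~0.001 events/s (tests assert the weaker bounds: recall ≥98%, median
onset error ≤2 ms, false positives <0.5/s).

## Timing, spatial and population analyses

* **Amplitude time course** — running mean over 50-ms windows stepped 10 ms
  across −100…+150 ms relative to stimulus onset; empty windows are NaN.
* **Eccentricity profile** — β₁ refit in 2-deg-wide windows of neuron
  preferred eccentricity slid in 1-deg steps from 1 deg.  Window membership
  is inclusive on both edges (a neuron at exactly 3 deg contributes to the
  2-, 3- and 4-deg windows); this is the one deliberate exception to the
  package-wide half-open convention.
* **Interaction model** — amplitude ~ 1 + S + ecc + S·ecc by OLS; the
  interaction coefficient is the change of per-spike gain per degree of
  neuron eccentricity.
* **Burst-timing sort** — trials sorted by (burst peak time − movement
  onset), cut into 30-trial bins (trailing partial bin dropped); each bin is
  compared with the first by a pooled-variance two-sample t-test at a
  Bonferroni-corrected α (divisor = number of non-baseline bins, which the
  source leaves unstated).  Effect onset = first bin opening a run of three
  consecutive significant bins; offset = first bin after that opening a
  three-bin non-significant run.  Bin indices are 0-based.
* **Influence window** — per 0.1-deg amplitude bin (0.1–0.8°, smaller
  movements excluded), mean spike count in 5-ms bins over ±100 ms around
  movement onset.  `influence_window_halfwidth` compares enlarged-amplitude
  bins against the 0.1–0.3° baseline bins per time bin (one-sided t,
  α = 0.01) and reports the outermost edge of the contiguous significant
  run around onset.
* **Efferent lag** — both curves are interpolated to a common 1-ms grid,
  mean-subtracted, and cross-correlated with full overlap only over lags
  0–100 ms; the reported lag maximizes the normalized correlation, positive
  = behavior follows the burst.
* **Movement fields** — mean firing rate ±15 ms around movement onset on a
  (log(amplitude/0.03°), direction) grid; a rotated 2-D Gaussian with
  baseline ≥ 0 is fit by least squares after locally unwrapping direction
  around the map peak (the fitting coordinates are not stated in the source;
  log-polar matches how such maps are displayed).  The "preferred" movement
  set is everything within 2 Mahalanobis SDs of the fitted mean.
* **Population averaging** — each neuron's curves are divided by that
  neuron's own reference peak (one divisor across all of its conditions)
  before averaging.  The paired baseline/burst-coincident comparison uses a
  Wilcoxon signed-rank test implemented in-package (exact sign-flip
  distribution by dynamic programming for ≤25 nonzero pairs, tie-corrected
  normal approximation above; midranks for ties, zero differences dropped).
  The phrase "paired ranksum" in this literature is ambiguous; the signed-
  rank reading is the default and a rank-sum variant is provided.

## The synthetic-data generator

`simulate_session` produces trials with one recorded caudal neuron each
(trials cycle through the configured neuron list, emulating sessions that
record one analyzed neuron at a time; a dual-site mode adds a rostral
motor neuron with log-polar Gaussian movement tuning).  Components:

* **Spikes** — inhomogeneous Poisson at 1-ms resolution: baseline
  (10 sp/s) + a gamma-shaped visual burst whose latency falls (45/40/35 ms)
  and peak rate rises (150/250/350 sp/s) with stimulus contrast
  (20/40/80%) + a sustained plateau (20 sp/s) ramping in ~120 ms after
  stimulus onset.  The burst rates are generator choices that reproduce the
  qualitative ordering of real SC responses, not measured values.
* **Microsaccades** — gamma renewal process (shape 4, mean ISI 700 ms);
  directions uniform, with a configurable toward bias (default P = 0.7)
  for movements 0–250 ms after stimulus onset, emulating the congruence of
  post-stimulus microsaccades with stimulus location.
* **Coupling rule** — each movement's spike count S is taken in the
  influence window: `count_window` mode counts [onset, onset+20) ms
  (matching the analysis window); `boxcar_kernel` mode counts
  [onset − delay − h, onset − delay + h) with half-width h = 30 ms and
  efferent delay 20 ms, so the spikes that matter precede their kinematic
  expression.  The gain is β₁ᵗᵒʷᵃʳᵈ for toward movements (0.066294
  deg/spike by default, the reported near-eccentricity value), β₁ᵒᵖᵖ = 0
  for opposite ones, optionally declining linearly with neuron eccentricity
  via `gain_vs_ecc`.
* **Amplitudes** — A = floor + (β₀ + β₁·S − floor)·exp(σz − σ²/2) with
  floor = 0.07°, σ = 0.8.  This shifted-lognormal scatter keeps
  E[A | S] = β₀ + β₁·S *exactly* linear, guarantees positive right-skewed
  amplitudes like real microsaccade distributions, and keeps every
  generated movement above the detector's sensitivity floor — an additive
  Gaussian of realistic spread would either truncate at zero (biasing the
  fit) or put a third of baseline movements below what any velocity
  detector can see.  Additive Gaussian noise remains available
  (`noise_model="gaussian"`).
* **Eye traces** — raised-cosine radial velocity waveforms,
  duration = max(15, 20·A^0.4) ms (peak velocity 2A/D, ≈20 deg/s at 0.15°,
  main-sequence-like), plus white fixational position noise (σ = 0.005°),
  sampled at 1 kHz.
* **Reproducibility** — three independent RNG streams (spikes, events,
  noise) spawned from the master seed; a fixed seed gives bit-identical
  sessions.

What the generator does *not* emulate: microsaccadic rate
inhibition/rebound after stimulus onset, drift/tremor structure in the
fixation noise, binocular disconjugacy, session-to-session neuron
heterogeneity beyond eccentricity, and spike-sorting artifacts.  Passing
recovery tests therefore demonstrate that the *pipeline* is unbiased and
correctly calibrated under the stated generative assumptions — not that
real recordings satisfy those assumptions.

## Numerical and design choices

* Firing-rate curves: 1-ms bins, Gaussian kernel σ = 10 ms (mass-
  conserving; single-trial curves integrate to the trial's spike count
  within 1e-6).  Error bands are SEM over trials; the source's 95% CIs are
  built by unstated means, so no CI construction is claimed.
* Argmax ties (flat burst curves) resolve to the earliest grid point.
* t statistics are assembled from closed forms in-package; p-values use the
  Student-t CDF (`scipy.special.stdtr`).  scipy/statsmodels serve only as
  independent oracles in the test suite.
* The trial↔neuron link is "the caudal neuron with spikes on that trial";
  at realistic baseline rates a trial without a single spike is a ~1e-4
  event and such trials are skipped.
* Degenerate inputs fail loudly: zero-variance t-tests, all-zero Wilcoxon
  differences, flat RF maps, rank-deficient designs and infeasible
  generator configurations all raise typed errors rather than returning
  NaNs.

## Problem sizes

Study-scale recovery runs (`scripts/acceptance.py`) use ~5000 selected
toward movements for the near/far amplitude models (28 000 / 48 000
simulated trials), ~24 000 movements across a 1–10 deg population for the
interaction model, ~18 000 sustained movements, and 6 000 / 9 000 trials
for the influence-window and efferent-lag analyses; sessions are simulated
in 2 000-trial chunks so memory stays flat.  The pytest acceptance suite
runs the same experiments at the same or moderately reduced sizes with
tolerances tied to the fitted standard errors, so the statistical strength
of the checks is size-independent.
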