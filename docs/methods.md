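# Methods

This note documents the models implemented in `stridepower`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish about real gait recordings.

## DFA estimator

For a series *x* of length *N* the estimator (module `stridepower.dfa`):

1. integrates the mean-centred series, y_k = Σ_{i≤k}(x_i − x̄) — always,
   since stride intervals are a noise-like (stationary) signal;
2. for each window size *w*, splits *y* into K = ⌊N/w⌋ non-overlapping
   windows anchored at the start (the trailing N mod w samples are
   discarded; an optional `backward` pass adds end-anchored windows but is
   off by default);
3. removes the OLS line within each window and computes the mean squared
   residual with divisor *w* (no degrees-of-freedom correction — this is the
   conventional definition of the local detrended variance, and the choice
   only tilts the log–log line deterministically);
4. sets F(w) = √(mean over windows of the local variance) and estimates α as
   the unweighted OLS slope of log₁₀F(w) on log₁₀w.

**Window set.** Every integer *w* in [4, ⌊N/4⌋] is used, not a log-spaced
subset. At the short lengths this package targets (100–200 strides) there
are only 21–46 admissible sizes, and discarding any of them increases the
variance of α̂; both log-spaced and all-integer policies are exposed
(`log_spaced=`) so users can reproduce either convention. The lower limit 4
is the smallest window that supports a meaningful linear fit; the upper
limit N/4 keeps at least four windows in the average. Log base 10 is used
throughout (the slope is base-invariant; the intercept is reported in
base 10).

A series must have at least 16 samples to admit the minimum window and at
least 20 to admit the two distinct sizes a slope requires. Constant series
have F ≡ 0 and raise a degenerate-series error rather than returning a
meaningless α.

## Fractional Gaussian noise and the trial-SD calibration

fGn with Hurst exponent H ∈ (0,1) has autocovariance
γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); for fGn the DFA
exponent α ≈ H, so fGn at a target α is the natural generative model for
persistent stride dynamics. Synthesis (module `stridepower.fgn`) uses
circulant embedding (Davies–Harte): γ(0..n) is wrapped into a length-2n
circulant, its eigenvalues are obtained by FFT (nonnegative for fGn; a
materially negative eigenvalue signals an implementation bug and raises),
and a draw with exactly this covariance is synthesised from independent
Gaussians in the frequency domain. The method is exact, not asymptotic.

`estimate_trial_sd` measures the sampling SD of α̂ as a function of series
length by generating replicate fGn series and re-estimating α with the
default window policy. At H = 0.9 (a deliberately conservative, strongly
persistent setting — α̂ variability grows with persistence) and 1000
replicates, this implementation yields SD(α̂) ≈ 0.126, 0.109 and 0.099 at
lengths 100, 150 and 200. The power engine nevertheless ships the
conventional defaults 0.16/0.12/0.10 for those lengths
(`TRIAL_SD_DEFAULTS`, used by `--strides`), treating them as the standard
planning inputs for this design; users who prefer this implementation's own
calibration can pass `--sd-trial` directly. The difference matters at 100
strides only: no windowing policy admissible within [4, N/4] (all-integer,
log-spaced, powers of two, two-point, constant-only detrending) produces an
SD as large as 0.16 at N = 100 with this estimator, so the larger
conventional value should be read as a conservative planning margin rather
than a reproducible property of the estimator.

## Variance-component power model

A subject's trial-averaged DFA estimate under group mean μ is modelled
(module `stridepower.power`) as

    α̂ = μ + b + (1/t) Σ_{j=1..t} (d_j + e_j),

with independent Gaussian components:

| component | meaning | default SD |
|---|---|---|
| b | inter-subject individual differences | 0.09 |
| d_j | per-trial estimation noise of α̂ (σ_DFA, length-dependent) | 0.16 (100 strides) |
| e_j | per-measurement experimental error | 0.018 |

The error SD defaults to 0.018 — 20% of the between-subject SD. It is added
per trial, before averaging, so its contribution shrinks with t; this is a
deliberate choice (an alternative, one error per subject-condition, would
not shrink) and it is configurable. No practice effect or drift across
trials is modelled.

**Between-subjects design:** two groups with independent subject effects;
pooled-variance two-sample two-sided t-test (the two groups have equal
variance by construction). **Within-subject design:** the two subject
effects are bivariate normal with equal SDs and correlation ρ = 0.89
(equivalently covariance 0.0072 at variance 0.0081); trial and error
deviations are independent across conditions; paired two-sided t-test. The
correlation applies to the subject effects only.

Power is the rejection proportion over `n_replicates` simulated experiments
(default 5000; binomial SE ≤ 0.007) at test level 0.05, one independent RNG
substream per (design, n, t) cell, so surfaces are bit-reproducible for a
fixed seed and cell values do not depend on grid order.

**Analytic oracle.** Because the model is exactly Gaussian, power is also
available in closed form from the noncentral t distribution with

* between: per-group variance σ²_S + (σ²_DFA + σ²_E)/t, df = 2n − 2;
* within: difference variance 2σ²_S(1 − ρ) + 2(σ²_DFA + σ²_E)/t, df = n − 1.

Every Monte Carlo path is tested against this oracle to 3 binomial SEs;
the oracle also drives monotonicity checks (power increases in n, t, effect
size and ρ; decreases in every SD). One caveat the oracle itself exposes:
the within design does not dominate the between design *strictly*
pointwise — the paired test halves the degrees of freedom, so at very small
n and t the between design can be ahead by less than 10⁻³ power.

At the defaults this machinery gives, e.g., within-design power 0.826 at
(25 subjects, 2 trials) and 0.736 at (12 subjects, 4 trials), between-design
power 0.823 at (25 per group, 4 trials), and a minimum of 6 subjects for 80%
power at a large effect (0.75 vs 0.98) with single 200-stride trials — all
with 5000 replicates and confirmed by the closed form.

## Observed power by subject resampling

Given one long recording per subject per condition
(`stridepower.empirical`), the recording is cut into consecutive
non-overlapping windows of a fixed stride count (anchored at the start,
configurable offset; if fewer windows fit than requested, all available ones
are used and the shortfall is recorded). α̂ is estimated per window with the
same [4, w/4] policy and averaged per subject-condition. Observed power at
subset size s draws `n_resamples` (default 1000) subject subsets uniformly
without replacement within a subset (subsets may recur across resamples —
the procedure read literally), applies a paired two-sided t-test at 0.05,
and reports the rejection proportion. Sweeping s (default 3..13) yields the
empirical power curve.

Observed power conditional on one completed experiment is a noisy quantity:
with 15 subjects the realized mean condition difference has an SE of ≈ 0.02
in α̂ units, and the power curve is steep in the effect, so a single
experiment's curve routinely sits 0.2 or more away from its expectation.
Consistency between the resampling procedure and the variance-component
prediction is therefore asserted on the *mean* curve over many replicate
synthetic experiments, not on a single dataset (see the acceptance test).

## Synthetic experiment generator

`stridepower.synthetic.generate_experiment` emulates a two-condition
treadmill experiment: per subject a correlated pair of target exponents
(bivariate normal around the condition means 0.77/0.87, SD 0.09, ρ = 0.89,
clipped to [0.05, 0.99] with a warning — fGn requires H < 1), then per
condition an fGn series with H equal to the target (800 and 750 strides by
default), affinely rescaled to a 1.2 s mean stride time with 3% CV. The CV
is a fixture choice: stride-time dispersion is not part of the α model
(DFA α is scale- and shift-invariant, which the tests assert), so it
affects realism only. Subject heterogeneity is injected into the
*generating* H, so the data exhibit subject variance, condition correlation
and length-dependent estimation variance organically rather than as added
noise.

What the generator does **not** emulate: multifractality and
nonstationarity of real stride series, practice or fatigue drift across a
session, metronome synchronization dynamics, or measurement artifacts
(missed heel-strikes, outliers). Passing tests therefore show that the
analysis chain is correct *under the monofractal fGn model*, not that real
gait data satisfy that model.

**Measurement-scale calibration.** For model-vs-experiment comparisons the
design parameters must be translated to the scale of the windowed DFA
estimate: target clipping and the nonlinear small-sample bias of α̂ make the
estimated-α effect slightly smaller than the nominal 0.10 (≈ 0.09 at
100-stride windows), and the per-subject paired-difference SD slightly
larger than the raw components imply. `calibrate_measurement` runs one
large simulated experiment (default 2000 subjects at a fixed calibration
seed) and returns the α̂-scale condition means, the pooled within-subject
between-window SD, and the paired-difference SD;
`MeasurementCalibration.variance_components` back-solves the subject SD so
the engine's difference variance matches the calibrated one exactly. The
end-to-end consistency test feeds these to the power engine and compares
against the mean empirical curve over 150 replicate experiments (three
standard errors of that mean ≈ 0.06), at a tolerance of 0.10 per subset
size, for 100- and 200-stride windows.

## Numerical and interface choices

* All randomness flows from one integer seed through named substreams
  (`numpy` `SeedSequence` keyed by labels such as ("trial-sd", length,
  replicate)); no global RNG state; repeated runs are byte-identical.
* Degenerate inputs: constant series raise; zero-variance null designs
  return power 0 with a warning rather than NaN.
* Problem sizes in the shipped tests: 5000 Monte Carlo replicates per power
  cell, 1000 fGn replicates per calibration length, 500 replicates for
  estimator-consistency checks, 150 replicate experiments for the
  end-to-end comparison — sizes at which binomial/replicate SEs are small
  relative to every asserted tolerance.
* Files are plain text: one stride interval per line, CSV manifests,
  JSON/TSV results with an embedded provenance block (configuration and
  seed, floats at 6 significant digits).

## Known limitations

* The estimator implements first-order DFA only (no higher-order
  detrending, overlapping windows, multifractal spectra, or crossover
  detection).
* The power model assumes exchangeable trials (no practice effect), equal
  group sizes, exactly two levels, and Gaussian components; it is not a
  mixed-model analysis.
* The trial-SD defaults for 100-stride trials (0.16) exceed what this
  estimator reproduces (≈ 0.126); predictions made with the default are
  conservative for that length.
* Observed-power estimates from a single small experiment are intrinsically
  noisy; treat single-dataset empirical curves as descriptive, not as a
  validation of a power prediction.
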