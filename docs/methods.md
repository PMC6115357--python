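# Methods

This note documents the models implemented in `sweepvep`, the default
parameters and why they were chosen, what the synthetic benchmark does and
does not establish, and the numerical choices that matter.

## The sweep SSVEP measurement model

A sweep trial is 10 s long: ten contiguous 1-s bins, each holding exactly
two cycles of the 2 Hz stimulation, with the monocular dot displacement
stepped through a geometric grid (adults 0.5–16 arcmin, infants 2–32; ratio
`(d_max/d_min)^(1/9)` between bins). The steady-state response in bin *k* is
a sum of phase-locked sinusoids at harmonics *h*·2 Hz whose amplitude
follows the displacement response function evaluated at the bin's grid
value. All analysis frequencies (harmonics 2, 4, 6, 8 Hz and their ±1 Hz
sidebands) complete whole cycles in a 1-s bin, so per-bin Fourier
projections are leakage-free by construction.

Harmonic content encodes the condition design. Symmetric motion alternation
drives even harmonics only; the first harmonic appears only when the display
alternates between a uniform and a segmented (disparate) configuration,
which requires anti-phase motion, binocularly matchable (full-cue) dots, a
correlated static reference, and a one-sided motion trajectory
(`expected_harmonic_signature`). Removing any ingredient — in-phase motion,
interocularly uncorrelated or anticorrelated dots, a noise/absent reference,
or endpoints that straddle zero disparity — removes the 1F response.

## Synthetic data generator

`synthesize_trial` renders, for channel *c* and bin *k*,

    x_c(t) = Σ_h A_h(d_k) · w_c(h) · cos(2π h f t + φ_h) + noise,

with `A_h` the harmonic's Naka–Rushton curve, `w(h)` a fixed smooth scalp
topography (Gaussian in chord distance on a Fibonacci-spiral montage of 128
adult / 124 infant channels), and `φ_h` fixed phases — response phases are
free parameters of the generator since nothing constrains their relation
across harmonics; the defaults are arbitrary fixed values, which preserves
the one property that matters: phase constancy over repeated trials.

Default planted parameters (adult, in-phase, full-cue, full-reference):

| harmonic | Rmax (µV) | d50 (arcmin) | n   | b |
|----------|-----------|--------------|-----|---|
| 1F (when present) | 1.5 | 3.0 | 1.5 | 0 |
| 2F       | 3.0       | 2.0          | 1.5 | 0 |
| 4F       | 1.2       | 2.0          | 1.5 | 0 |

These magnitudes mirror the µV-scale component-level response functions
typical of high-density sweep-VEP recordings. Condition effects are planted
as: anti-phase ⇒ every d50 ×2 (the rightward shift that operationalises
suppression; configurable), non-full reference ⇒ Rmax ×0.5, and an infant
preset in which the reference manipulation has no effect and anti-phase
responses are 1.5× in-phase with *no* d50 shift (the adult pattern
reversed), with the displacement scale doubled to match the infant grid.

Background noise is the minimal model matching "background EEG" behaviour:
20 independent 1/f^α sources (α = 1) mixed through random smooth
topographies (4 µV RMS per channel) plus white sensor noise (2 µV RMS).
With these levels a single trial's channel-level coefficient SNR at 2F
saturation is ≈ 5–10, and clean trials pass the 30/60 µV rejection rules —
both properties of real usable recordings. Cohorts add per-participant
lognormal amplitude scaling (10 % coefficient of variation) and a small
random rotation of topography centres; sub-seeds derive from the master
seed through a counter-based `SeedSequence` scheme, so any subset of the
cohort regenerates bit-identically.

`simulate_coefficient_cohort` is a scaled-down companion that draws
component-space complex coefficients directly (signal from the planted
curves, complex Gaussian trial noise of 0.25 µV per component — the scale
of a single-trial sideband estimate after spatial filtering). It exists for
Monte-Carlo calibration (power, type-I error), where thousands of cohorts
are needed and rendering EEG would add nothing: the statistics under test
consume exactly these coefficients.

**What the generator does not emulate:** non-stationary background spectra,
ocular/muscle artifacts beyond the stylised blink/spike/bad-channel
injector, volume-conduction-accurate topographies, eye movements,
inter-bin amplitude dynamics (planted amplitudes are constant within a
bin), or any dependence of noise on the stimulus. Passing tests therefore
demonstrate correctness of the *analysis* under the stated signal model,
not robustness to every pathology of real EEG.

## Preprocessing

Fixed order: band-pass → resample → bad-sensor handling → common-average
re-reference → segment → reject. Choices:

- **Filter**: 4th-order Butterworth 0.3–50 Hz, zero-phase
  (forward–backward), the whole filter applied twice in cascade. Zero-phase
  realisation preserves the response phases on which the complex-domain
  statistics depend. Note that on a 10-s excerpt the 0.3 Hz edge produces
  long start-up transients; the pipeline's synthetic path skips filtering by
  default (`apply_filter=False`) because the generated data are already
  band-limited and exactly periodic — the filter is exercised directly by
  its own tests.
- **Resampling**: polyphase rational resampling (21/25 for 500→420 Hz) with
  anti-aliasing.
- **Thresholds** are strict inequalities ("more than"): a sensor is excluded
  iff > 15 % of samples exceed the amplitude threshold (adult 30 µV; infant
  30–100 µV accepted); a channel-epoch is rejected iff > 10 % of samples
  exceed 30 µV or any sample exceeds 60 µV; an epoch is rejected for all
  channels iff > 7 sensors violate the peak threshold. Boundary equality
  never triggers. The bad-sensor rule is evaluated per recording (trial)
  by default; this is configurable.
- **Interpolation**: a bad sensor is replaced by the arithmetic mean of its
  six nearest *good* sensors, Euclidean distance in 3-D montage
  coordinates, ties broken by channel index. Bad sensors never contribute
  to each other.

A `CleaningReport` records every decision; with artifacts injected through
the ledger, rejection output is checked for exact equality.

## Harmonic extraction

Two estimators, cross-validated against each other:

- **RLS** (default): joint exponentially weighted recursive least squares
  over cos/sin regressors at all unique target and sideband frequencies
  (shared sidebands such as 3 Hz are deduplicated — a duplicated regressor
  would make the solve singular). Forgetting factor λ = 1 − 1/M with memory
  M = 420 samples (the 1-s bin), inverse-covariance initialisation
  P₀ = 10⁴·I, coefficients read out at each bin's final sample. The first
  bin is flagged as burn-in (cold start) but is used by the group
  statistics like every other bin. Because the exponential window extends
  ≈ 1/e into the previous bin, per-bin amplitudes are slightly smoothed
  along the sweep; this shifts both curves of a condition pair similarly
  and leaves d50 *ratios* essentially unbiased (verified end-to-end).
- **DFT**: per-bin least-squares cos/sin projection, equal to the scaled
  DFT bin for integer cycles. On stationary noiseless input the two agree
  to < 10⁻⁶ µV after three memory constants.

Coefficient convention: `x(t) = Re[c·e^{iωt}]`, so `c = A·e^{iφ}` for a
cosine of amplitude A and phase φ.

Noise is estimated at F ± 1 Hz of each harmonic with the same estimator and
the scalar per-trial noise level is the incoherent mean of the two sideband
amplitudes.

## Reliable Components Analysis

Input rows are the real and imaginary coefficient values of each 1-s epoch
across sensors (2 rows per epoch), pooled over trials and participants.
`R_xy` averages `X_iᵀX_j` over all ordered pairs of distinct trials within
the same condition cell (computed via the sum identity, symmetrized);
`R_pool` is the pooled within-trial covariance. The generalized
eigenproblem is solved in the top-`rank` (default 60) principal subspace of
`R_pool` — the standard stabilisation for 128-channel data; eigenvalues
sort descending and weight columns are sign-normalised (largest-magnitude
entry positive; amplitudes are sign-invariant, phases are reported under
this convention).

Definitional summaries (reported without formulas in the field, so defined
here): `reliability_explained_k = ρ_k / Σ ρ_j⁺` over the retained rank
(positive eigenvalues only), and `variance_explained_k` is the share of
total input variance accounted for by reconstructing the data from
component *k* through its forward topography `A = R_pool W (Wᵀ R_pool W)⁻¹`
(the raw projection variance is degenerate — generalized eigenvectors are
R_pool-normalized, giving every component unit projected variance).

Components are derived separately per harmonic; RC1 is the default
read-out, and `select_component` chooses by topography similarity to a
template for cohorts (infants) where the physiological component appears
further down the eigenvalue spectrum. Missing channel-epochs enter the
covariances as zero rows — they contribute no covariance rather than
biased values.

## Group statistics

The group response is the **vector average**: real and imaginary parts
averaged across participants (each participant's value being their
trial-level complex mean), amplitude taken last. Displacement averages
average complex parts across the 10 bins within participant first. For
inference, each participant's complex vector is projected onto the unit
group-mean vector; the projections' mean equals the group vector-average
amplitude *exactly*, which forces the group mean to include the projected
participant — this identity is asserted to 10⁻¹². SEMs and paired
two-tailed *t* tests (with paired-sample Cohen's d) operate on the
projections, per bin and for the displacement average. No multiple-testing
correction is applied across bins by default (per-bin p values are reported
alongside displacement averages); a Bonferroni option exists.

Two noise floors are provided. `noise_floor` is the incoherent mean of
per-trial sideband levels — a single-trial noise scale. `coherent_noise_floor`
passes the complex sideband coefficients through the *same* two-stage vector
averaging as the signal; since sideband phases are random across trials it
shrinks with the number of averaged trials exactly as the noise inside the
signal's vector average does, making it the correct background level for
deciding whether a vector-averaged component is present. Presence checks
(the 1F signature analysis) compare participant-level vector amplitudes to
participant-level coherent sideband floors averaged the same way, so under
the null both statistics have identical distributions and their ratio
concentrates at 1.

## Response fitting

`NakaRushtonModel` fits `R(d) = Rmax·dⁿ/(dⁿ+d50ⁿ) + b` by bounded weighted
least squares (bounds: Rmax ∈ [0, 10·max amp], d50 ∈ [0.1·d_min, 10·d_max],
n ∈ (0, 6], b ∈ [0, max amp]; b is bounded below by zero because amplitudes
are magnitudes). A deterministic multi-start grid (d50 at the displacement
quartiles × n ∈ {0.5, 1, 2, 4}) guards against local minima; the best
converged start is reported with an approximate Jacobian-based covariance.
Weights are inverse group SEMs when available, else uniform — the fits are
primarily descriptive and the loss choice is documented rather than claimed
optimal. Flat data yield the canonical degenerate solution (Rmax → 0, b =
mean) with a flag; degenerate fits refuse to produce a suppression index.

**Identifiability caveat**: with all four parameters free, d50 precision
depends strongly on the true exponent. On the adult grid with noise at 10 %
of Rmax, the Cramér–Rao bound alone puts the relative d50 standard error
near 38 % for n = 1.5 but ~19 % for n = 2; parameter-recovery benchmarks
therefore use the canonical energy-form exponent n = 2, and users fitting
shallow response functions should expect (and will see, in the reported
standard errors) wide d50 uncertainty.

The suppression index is `d50(anti-phase) / d50(in-phase)`; values > 1 mean
the anti-phase function is shifted rightward. On full end-to-end synthetic
cohorts (15 participants × 5 trials per condition, 128 channels, RLS
estimator) the planted ×2 shift is recovered within [1.6, 2.4].

## Problem sizes and calibration choices

- End-to-end suppression recovery: 15 participants × 5 trials × 2
  conditions of full 128-channel synthesis (the generator's default of 15
  trials per condition is used where trial-level statistics are the point;
  5 suffice for the group-level index).
- Power and type-I calibration: 200 and 500 cohorts respectively at the
  coefficient level (15 participants × 15 trials), where the planted
  suppression yields > 80 % power for the displacement-average comparison
  at α = 0.05 and the null (two cells with identical planted responses)
  rejects at the nominal rate.
- Harmonic-signature analysis: 5 participants × 15 trials × 5 condition
  types on a 64-channel montage, DFT estimator, RCA fit separately on the
  1F coefficients of all conditions pooled.
- Naka–Rushton Monte-Carlo: 100–300 replicates (the sample median of the
  d50 error is itself noisy; 300 replicates reduce its spread below 1
  percentage point).

## Known limitations

- The generator's linear superposition model cannot produce harmonic
  interactions or nonlinear cross-talk between components.
- The RLS bin read-out mixes ≈ 1/e of the previous bin into each estimate;
  per-bin amplitudes are mildly smoothed along the sweep (ratios and
  displacement averages are robust to this; single-bin values near steep
  parts of the curve are biased toward their neighbour).
- EDF export quantises to 16 bits over ±500 µV (step ≈ 0.015 µV); lossless
  storage uses the npz + JSON container.
- The psychophysical threshold procedure associated with this paradigm is
  out of scope, as is stimulus rendering; infant analyses are supported
  through configuration presets and the component-selection override, not a
  separately validated infant pipeline.
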