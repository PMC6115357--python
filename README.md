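# sweepvep

Frequency-domain analysis of **sweep steady-state visually evoked potentials
(SSVEPs)** recorded while observers view dichoptic random-dot motion — the
paradigm used to study binocular motion-in-depth mechanisms (interocular
velocity differences, changing disparity, relative-motion references) in
adults and infants.

In this paradigm, dots in the two eyes undergo 2 Hz apparent motion whose
displacement is swept through 10 log-spaced values (0.5–16 arcmin for
adults, 2–32 for infants) within a single 10-s trial, one value per 1-s bin.
The EEG response at harmonics *h·F* of the 2 Hz stimulation frequency,
measured bin by bin, traces out a *displacement response function*.
Conditions differ in interocular phase (in-phase vs anti-phase motion),
interocular dot correlation (+1 full-cue, 0 or −1 IOVD-isolating), and the
content of non-moving reference bands (static dots, noise dots, blank) — a
2 × 2 × 2 design whose harmonic content is diagnostic: symmetric motion
drives only even harmonics (2F, 4F), while the asymmetric alternation
between uniform and segmented percepts under anti-phase full-cue referenced
motion adds a first-harmonic (1F) response.

Because no public recording of these experiments exists, the package ships a
first-class synthetic-data module that generates 128-channel sweep trials
with known planted structure, so the entire chain is quantitatively
testable.

## What the package does

- **`sweepvep.synth`** — synthetic dichoptic-motion EEG: per-bin harmonic
  amplitudes follow Naka–Rushton functions of displacement, mixed through
  fixed scalp topographies, over spatially correlated 1/f background noise;
  artifact injection (blinks, spikes, bad channels) with an exact ledger;
  cohort generation with per-participant variability.
- **`sweepvep.preprocess`** — the cleaning chain: 0.3–50 Hz zero-phase
  band-pass (applied twice), resampling to 420 Hz, bad-sensor detection
  (> 15 % of samples above threshold) and 6-nearest-neighbour interpolation,
  common-average re-referencing, segmentation into ten 1-s epochs (two
  stimulus cycles each), and channel-epoch / whole-epoch artifact rejection.
- **`sweepvep.harmonics`** — complex coefficients of harmonics 1F–4F per
  displacement bin, via a joint multi-frequency exponentially weighted
  recursive least-squares filter (memory = the 1-s bin) or a per-bin DFT
  projection, plus noise estimates at the F ± 1 Hz sidebands.
- **`sweepvep.rca`** — Reliable Components Analysis: sensor weightings that
  maximise trial-to-trial consistency by solving the generalized
  eigenproblem `R_xy w = ρ R_pool w` between cross-trial and pooled
  covariance, statsmodels-style (`ReliableComponents(...).fit()` →
  `RCAResults` with weights, forward topographies, reliability/variance
  summaries, `summary()`).
- **`sweepvep.groupstats`** — vector averaging of complex coefficients,
  projected amplitudes (whose mean equals the group vector-average amplitude
  exactly), displacement averages, paired *t* comparisons, noise floors.
- **`sweepvep.nakarushton`** — the response model
  `R(d) = Rmax·dⁿ/(dⁿ + d50ⁿ) + b` (`NakaRushtonModel(...).fit()` →
  `NakaRushtonResults`), and the anti-phase **suppression index**
  `d50(anti) / d50(in)` quantifying the rightward shift of the response
  function.
- **`sweepvep.pipeline` / CLI** — `sweepvep all --config cfg.yaml` runs
  simulate → preprocess → extract → rca → stats → fit with full seeded
  provenance; EDF and npz+JSON recording I/O.

## Worked example

```python
import numpy as np
import sweepvep as sv

protocol = sv.SweepProtocol.adult()          # 2 Hz, 10 bins, 0.5-16 arcmin
grid = sv.make_sweep_grid(protocol)
# grid: [ 0.5  0.735  1.08  1.587  2.333  3.429  5.04  7.407  10.886  16. ]

params = sv.NakaRushtonParams(rmax=3.0, d50=2.0, n=1.5, b=0.0)
rng = np.random.default_rng(0)
amps = np.clip(sv.nr_eval(grid, params) + 0.15 * rng.standard_normal(10), 0, None)
print(sv.fit_nr(grid, amps).summary())
```

```
Naka-Rushton displacement-response fit
==============================================
parameter         estimate     std err
----------------------------------------------
Rmax (uV)            2.563       0.258
d50 (arcmin)         2.003       0.205
n                    2.023       0.418
b (uV)              0.2522       0.188
----------------------------------------------
RSS 0.08318   converged True   degenerate False
```

The true half-saturation displacement (2 arcmin) is recovered as
2.003 ± 0.205 from amplitudes carrying 0.15 µV of noise.

The full pipeline, on a synthetic cohort with anti-phase suppression planted
as a ×2 shift of d50:

```python
from sweepvep.pipeline import PipelineConfig, run_pipeline
cfg = PipelineConfig(n_participants=8, n_trials=5, n_channels=64, seed=7,
                     rca_rank=40, outdir="demo_out")
run_pipeline(cfg)
```

prints (via the generated `suppression.csv` / `comparisons.csv` tables):

```
suppression index: 1.792
displacement-average paired t: t(7) = 7.91, p = 9.8e-05, d = 2.80
```

i.e. the anti-phase response function's d50 is recovered ~1.8× the in-phase
one (planted: 2×), and in-phase amplitudes are significantly larger than
anti-phase ones — the anti-phase suppression effect.

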