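"""Synthetic dichoptic-motion sweep EEG with known ground truth.

Every downstream stage of the pipeline (preprocessing, harmonic extraction,
reliable components, group statistics, response fitting) is tested against
recordings produced here, because no public recording of the modelled
experiments exists.  A recording is a channels x time array at 420 Hz
containing, within each 1-s displacement bin, phase-locked sinusoids at
harmonics of the 2 Hz stimulation frequency whose amplitudes follow
Naka-Rushton functions of the bin's displacement, mixed through fixed smooth
scalp topographies, plus spatially correlated 1/f background noise and white
sensor noise.  The exact planted parameters travel with the recording so
recovery can be checked quantitatively.

Condition structure that the generator plants (configurable):

* even harmonics (2F, 4F) in every condition — symmetric motion alternation;
* 1F only for anti-phase, full-cue, full-reference, one-sided-trajectory
  conditions — the asymmetric uniform/segmented alternation;
* anti-phase suppression as a d50 multiplier (default x2) relative to
  in-phase — the rightward shift of the response function;
* reference removal (noise or blank reference bands) as a global Rmax
  reduction;
* an infant preset in which reference removal has no effect and anti-phase
  responses exceed in-phase ones (the adult pattern reversed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import MontageSpec, make_montage
from .nakarushton import NakaRushtonParams, nr_eval
from .protocol import ConditionSpec, SweepProtocol, expected_harmonic_signature, make_sweep_grid

__all__ = [
    "HarmonicTruth",
    "GroundTruthResponse",
    "NoiseSpec",
    "ArtifactSpec",
    "ArtifactLedger",
    "SyntheticRecording",
    "CohortSpec",
    "default_ground_truth",
    "make_topography",
    "synthesize_trial",
    "inject_artifacts",
    "generate_cohort",
    "simulate_coefficient_cohort",
]


@dataclass(frozen=True)
class HarmonicTruth:
    """Planted response of one harmonic: Naka-Rushton amplitude curve, a
    fixed response phase (radians) and a fixed scalp topography."""

    params: NakaRushtonParams
    phase: float
    topography: np.ndarray  # (n_channels,), unitless weights

    def amplitude(self, d) -> np.ndarray:
        return nr_eval(d, self.params)


@dataclass(frozen=True)
class GroundTruthResponse:
    """Planted responses per harmonic for one condition.

    ``components`` maps harmonic number (1..4) to its planted response;
    harmonics outside the condition's signature must carry Rmax = 0 or be
    absent (symmetry rule).
    """

    components: dict[int, HarmonicTruth]
    condition: ConditionSpec

    def __post_init__(self):
        sig = expected_harmonic_signature(self.condition)
        for h, comp in self.components.items():
            if h % 2 == 1 and h not in sig and comp.params.rmax != 0:
                raise ValueError(
                    f"harmonic {h}F is outside the condition's signature; its Rmax must be 0"
                )

    def scaled(self, amp_scale: float) -> "GroundTruthResponse":
        comps = {
            h: HarmonicTruth(
                params=replace(c.params, rmax=c.params.rmax * amp_scale, b=c.params.b * amp_scale),
                phase=c.phase,
                topography=c.topography,
            )
            for h, c in self.components.items()
        }
        return GroundTruthResponse(components=comps, condition=self.condition)


# response phases are free parameters of the generator (no constraint relates
# them across harmonics); fixed defaults keep trials phase-locked
DEFAULT_PHASES = {1: 0.9, 2: 0.4, 3: 2.1, 4: -1.2}

# topography centres on the unit sphere: occipital-ish pole for the motion
# response, slightly more dorsal for higher harmonics
_TOPO_CENTERS = {
    1: np.array([0.0, -0.80, 0.60]),
    2: np.array([0.0, -0.90, 0.44]),
    3: np.array([0.15, -0.85, 0.50]),
    4: np.array([0.0, -0.70, 0.71]),
}


def make_topography(montage: MontageSpec, center: np.ndarray, width: float = 0.8) -> np.ndarray:
    """Smooth scalp map: Gaussian in chord distance from ``center`` on the
    sphere, peak-normalised to 1."""
    c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    d = np.linalg.norm(montage.positions - c[None, :], axis=1)
    w = np.exp(-(d**2) / (2 * width**2))
    return w / w.max()


def default_ground_truth(
    cond: ConditionSpec,
    montage: MontageSpec,
    protocol: SweepProtocol | None = None,
    *,
    suppression_factor: float = 2.0,
    reference_removal_gain: float = 0.5,
    infant_reversal_gain: float = 1.5,
    phases: dict[int, float] | None = None,
) -> GroundTruthResponse:
    """Planted parameters for one condition under the modelled study design.

    Adult baseline (in-phase, full-cue, full-reference): 2F Rmax 3 uV with
    d50 2 arcmin, 4F Rmax 1.2 uV, exponent 1.5, zero baseline; 1F (where the
    signature allows it) Rmax 1.5 uV with d50 3 arcmin.  Anti-phase
    multiplies every d50 by ``suppression_factor``; a noise or absent
    reference multiplies Rmax by ``reference_removal_gain``.  The infant
    preset shifts the displacement scale (d50 doubled, matching the 2-32
    arcmin sweep), ignores the reference manipulation and reverses the
    phase effect: anti-phase Rmax is ``infant_reversal_gain`` x in-phase,
    with no d50 shift.
    """
    phases = dict(DEFAULT_PHASES, **(phases or {}))
    infant = cond.population == "infant"
    d50_scale = 2.0 if infant else 1.0

    base = {
        1: NakaRushtonParams(rmax=1.5, d50=3.0 * d50_scale, n=1.5, b=0.0),
        2: NakaRushtonParams(rmax=3.0, d50=2.0 * d50_scale, n=1.5, b=0.0),
        4: NakaRushtonParams(rmax=1.2, d50=2.0 * d50_scale, n=1.5, b=0.0),
    }
    sig = expected_harmonic_signature(cond)
    components: dict[int, HarmonicTruth] = {}
    for h, p in base.items():
        rmax, d50 = p.rmax, p.d50
        if h not in sig:
            rmax = 0.0
        if cond.interocular_phase == "anti_phase":
            if infant:
                rmax *= infant_reversal_gain
            else:
                d50 *= suppression_factor
        if cond.reference_type != "full" and not infant:
            rmax *= reference_removal_gain
        components[h] = HarmonicTruth(
            params=NakaRushtonParams(rmax=rmax, d50=d50, n=p.n, b=p.b),
            phase=phases[h],
            topography=make_topography(montage, _TOPO_CENTERS[h]),
        )
    return GroundTruthResponse(components=components, condition=cond)


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise model: ``n_sources`` 1/f^alpha processes mixed
    through random smooth topographies plus independent white sensor noise.
    ``pink_rms`` and ``white_rms`` are per-channel RMS targets in uV."""

    pink_rms: float = 4.0
    white_rms: float = 2.0
    alpha: float = 1.0
    n_sources: int = 20

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(pink_rms=0.0, white_rms=0.0)


@dataclass(frozen=True)
class SyntheticRecording:
    """One synthetic sweep trial: channels x time samples in uV, with the
    protocol, condition, planted ground truth and artifact ledger attached."""

    samples: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    protocol: SweepProtocol
    condition: ConditionSpec
    montage: MontageSpec
    ground_truth: GroundTruthResponse
    seed: int
    participant: str = "P00"
    trial: int = 0
    artifact_ledger: "ArtifactLedger | None" = None

    def __post_init__(self):
        n_ch, n_s = self.samples.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("samples/montage channel mismatch")
        if n_s != self.protocol.n_samples:
            raise ValueError("samples length must equal n_bins * bin_duration * fs")

    @property
    def bin_slices(self) -> list[slice]:
        return self.protocol.bin_slices()


def _pink_noise(rng: np.random.Generator, n_samples: int, n_series: int, alpha: float) -> np.ndarray:
    """(n_series, n_samples) 1/f^alpha noise, unit RMS per series."""
    n_f = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    shaping = np.zeros(n_f)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal((n_series, n_f)) + 1j * rng.standard_normal((n_series, n_f))) * shaping
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _background_noise(
    rng: np.random.Generator, montage: MontageSpec, n_samples: int, noise: NoiseSpec
) -> np.ndarray:
    n_ch = montage.n_channels
    out = np.zeros((n_ch, n_samples))
    if noise.pink_rms > 0 and noise.n_sources > 0:
        sources = _pink_noise(rng, n_samples, noise.n_sources, noise.alpha)
        centers = rng.standard_normal((noise.n_sources, 3))
        mix = np.stack(
            [make_topography(montage, c, width=rng.uniform(0.5, 1.2)) for c in centers], axis=1
        )  # (n_ch, n_sources)
        mix *= rng.choice([-1.0, 1.0], size=(1, noise.n_sources))
        pink = mix @ sources
        rms = np.sqrt(np.mean(pink**2))
        out += pink * (noise.pink_rms / max(rms, 1e-30))
    if noise.white_rms > 0:
        out += noise.white_rms * rng.standard_normal((n_ch, n_samples))
    return out


def synthesize_trial(
    cond: ConditionSpec,
    protocol: SweepProtocol,
    truth: GroundTruthResponse,
    montage: MontageSpec,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    participant: str = "P00",
    trial: int = 0,
) -> SyntheticRecording:
    """Render one sweep trial.

    Within bin k (displacement d_k of the geometric grid), channel c carries

        sum_h  A_h(d_k) * w_c(h) * cos(2 pi h f_stim t + phi_h)

    with t the global trial time, A_h the harmonic's Naka-Rushton amplitude,
    w(h) its topography and phi_h its fixed phase — plus background noise.
    Deterministic for a given seed.
    """
    noise = noise if noise is not None else NoiseSpec()
    for h, comp in truth.components.items():
        if comp.topography.shape != (montage.n_channels,):
            raise ValueError(f"harmonic {h}F topography length != n_channels")
    rng = np.random.default_rng(seed)
    grid = make_sweep_grid(protocol)
    t = np.arange(protocol.n_samples) / protocol.fs
    x = np.zeros((montage.n_channels, protocol.n_samples))
    for h, comp in truth.components.items():
        if comp.params.rmax == 0 and comp.params.b == 0:
            continue
        carrier = np.cos(2 * np.pi * h * protocol.f_stim * t + comp.phase)
        amp = np.repeat(comp.amplitude(grid), protocol.samples_per_bin)
        x += comp.topography[:, None] * (amp * carrier)[None, :]
    x += _background_noise(rng, montage, protocol.n_samples, noise)
    return SyntheticRecording(
        samples=x,
        fs=protocol.fs,
        protocol=protocol,
        condition=cond,
        montage=montage,
        ground_truth=truth,
        seed=seed,
        participant=participant,
        trial=trial,
    )


# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifacts to inject.

    blinks: (start_sample, n_samples, amplitude_uV, channel indices) — slow
    half-sine deflections. spikes: (sample, amplitude_uV, channel indices).
    bad_channels: (channel, amplitude_uV, fraction of samples driven).
    """

    blinks: tuple[tuple[int, int, float, tuple[int, ...]], ...] = ()
    spikes: tuple[tuple[int, float, tuple[int, ...]], ...] = ()
    bad_channels: tuple[tuple[int, float, float], ...] = ()


@dataclass
class ArtifactLedger:
    """Exact record of every sample/channel the artifact injector modified."""

    entries: list[dict] = field(default_factory=list)

    def modified_mask(self, n_channels: int, n_samples: int) -> np.ndarray:
        m = np.zeros((n_channels, n_samples), dtype=bool)
        for e in self.entries:
            for c in e["channels"]:
                m[c, e["samples"]] = True
        return m


def inject_artifacts(
    rec: SyntheticRecording, spec: ArtifactSpec, seed: int = 0
) -> SyntheticRecording:
    """Add blinks, spikes and continuously-bad channels; return a new
    recording whose ledger lists the exact samples and channels modified."""
    rng = np.random.default_rng(seed)
    n_ch, n_s = rec.samples.shape
    x = rec.samples.copy()
    ledger = ArtifactLedger()

    for start, dur, amp, channels in spec.blinks:
        if start < 0 or start + dur > n_s or dur <= 0:
            raise IndexError("blink outside recording bounds")
        wave = amp * np.sin(np.pi * np.arange(dur) / dur)  # slow half-sine
        for c in channels:
            if not 0 <= c < n_ch:
                raise IndexError(f"blink channel {c} out of range")
            x[c, start : start + dur] += wave
        ledger.entries.append(
            {"kind": "blink", "channels": list(channels), "samples": list(range(start, start + dur)),
             "amplitude": amp}
        )

    for sample, amp, channels in spec.spikes:
        if not 0 <= sample < n_s:
            raise IndexError("spike outside recording bounds")
        for c in channels:
            if not 0 <= c < n_ch:
                raise IndexError(f"spike channel {c} out of range")
            x[c, sample] += amp
        ledger.entries.append(
            {"kind": "spike", "channels": list(channels), "samples": [sample], "amplitude": amp}
        )

    for channel, amp, frac in spec.bad_channels:
        if not 0 <= channel < n_ch:
            raise IndexError(f"bad channel {channel} out of range")
        n_bad = int(round(frac * n_s))
        idx = rng.choice(n_s, size=n_bad, replace=False)
        x[channel, idx] += amp * rng.choice([-1.0, 1.0], size=n_bad)
        ledger.entries.append(
            {"kind": "bad_channel", "channels": [channel], "samples": sorted(int(i) for i in idx),
             "amplitude": amp}
        )

    return replace(rec, samples=x, artifact_ledger=ledger)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Between-participant variability: lognormal overall amplitude scaling
    with coefficient of variation ``amp_spread`` (default 10%) and a small
    random rotation of topography centres (``topo_jitter`` radians RMS)."""

    n_participants: int = 15
    n_trials: int = 15  # trials per condition per participant
    amp_spread: float = 0.10
    topo_jitter: float = 0.05

    def __post_init__(self):
        # single-participant "cohorts" can be generated (the group
        # statistics refuse them later); zero cannot
        if self.n_participants < 1:
            raise ValueError("a cohort needs at least 1 participant")


def _rotation_matrix(rng: np.random.Generator, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.eye(3)
    ax = rng.standard_normal(3)
    ax /= np.linalg.norm(ax)
    ang = rng.normal(0.0, sigma)
    k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)


def _participant_truth(
    cond: ConditionSpec,
    montage: MontageSpec,
    base_truth: GroundTruthResponse,
    rng: np.random.Generator,
    cohort: CohortSpec,
) -> GroundTruthResponse:
    if cohort.amp_spread > 0:
        sigma = np.sqrt(np.log1p(cohort.amp_spread**2))
        scale = float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))
    else:
        scale = 1.0
    truth = base_truth.scaled(scale)
    if cohort.topo_jitter > 0:
        rot = _rotation_matrix(rng, cohort.topo_jitter)
        comps = {}
        for h, c in truth.components.items():
            center = _TOPO_CENTERS.get(h, np.array([0.0, -0.9, 0.44]))
            topo = make_topography(montage, rot @ center)
            comps[h] = HarmonicTruth(params=c.params, phase=c.phase, topography=topo)
        truth = GroundTruthResponse(components=comps, condition=cond)
    return truth


def generate_cohort(
    n_participants: int,
    conditions: list[ConditionSpec],
    protocol: SweepProtocol,
    seed: int = 0,
    *,
    montage: MontageSpec | None = None,
    noise: NoiseSpec | None = None,
    cohort: CohortSpec | None = None,
    truth_factory=default_ground_truth,
) -> list[SyntheticRecording]:
    """Simulate a cohort: per participant, ``cohort.n_trials`` trials of each
    condition.  Sub-seeds are derived from the master seed with a counter so
    regeneration is bit-identical; per-participant amplitude scaling and
    topography jitter are drawn once per participant.
    """
    cohort = cohort if cohort is not None else CohortSpec(n_participants=n_participants)
    if cohort.n_participants != n_participants:
        cohort = replace(cohort, n_participants=n_participants)
    montage = montage if montage is not None else make_montage(
        124 if conditions and conditions[0].population == "infant" else 128
    )
    noise = noise if noise is not None else NoiseSpec()

    recordings: list[SyntheticRecording] = []
    for p in range(n_participants):
        p_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(p,)))
        pid = f"P{p:02d}"
        for ci, cond in enumerate(conditions):
            base = truth_factory(cond, montage, protocol)
            truth = _participant_truth(cond, montage, base, p_rng, cohort)
            for tr in range(cohort.n_trials):
                counter = (p * len(conditions) + ci) * cohort.n_trials + tr
                sub_seed = np.random.SeedSequence(entropy=seed, spawn_key=(1, counter))
                trial_rng_seed = int(sub_seed.generate_state(1)[0] % (2**31))
                recordings.append(
                    synthesize_trial(
                        cond, protocol, truth, montage,
                        noise=noise, seed=trial_rng_seed, participant=pid, trial=tr,
                    )
                )
    return recordings


# ---------------------------------------------------------------------------
# coefficient-level cohort simulator (for Monte-Carlo calibration)


def simulate_coefficient_cohort(
    conditions: list[ConditionSpec],
    protocol: SweepProtocol,
    *,
    n_participants: int = 15,
    n_trials: int = 15,
    harmonic: int = 2,
    coef_noise: float = 0.25,
    amp_spread: float = 0.10,
    seed: int = 0,
    truth_factory=None,
) -> dict[str, np.ndarray]:
    """Simulate component-space complex coefficients directly.

    Emulates the end of the pipeline — per-trial complex coefficients of one
    harmonic after spatial filtering — without rendering EEG: participant p,
    trial t, bin k yields  A_h^p(d_k) e^{i phi_h} + eps,  with eps complex
    Gaussian (std ``coef_noise`` uV per real/imaginary component, the scale
    of a single-trial sideband estimate) and per-participant lognormal
    amplitude scaling of spread ``amp_spread``.  Returns a mapping from
    condition label to an (n_participants, n_trials, n_bins) complex array.
    Used for power and type-I calibration where thousands of cohorts are
    needed.
    """
    rng = np.random.default_rng(seed)
    grid = make_sweep_grid(protocol)
    phase = DEFAULT_PHASES[harmonic]
    out: dict[str, np.ndarray] = {}
    if truth_factory is None:
        mont = make_montage(16)  # topography unused at coefficient level
        truth_factory = lambda c: default_ground_truth(c, mont, protocol)  # noqa: E731
    scales = np.ones(n_participants)
    if amp_spread > 0:
        sigma = np.sqrt(np.log1p(amp_spread**2))
        scales = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_participants)
    for cond in conditions:
        truth = truth_factory(cond)
        amps = truth.components[harmonic].amplitude(grid)  # (n_bins,)
        z = scales[:, None, None] * amps[None, None, :] * np.exp(1j * phase)
        eps = coef_noise * (
            rng.standard_normal((n_participants, n_trials, grid.size))
            + 1j * rng.standard_normal((n_participants, n_trials, grid.size))
        )
        out[cond.label] = z + eps
    return out
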