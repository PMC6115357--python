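"""Experimental design objects for dichoptic-motion sweep SSVEP studies.

The experiments this package models present random-dot displays whose test
bands undergo 2 Hz apparent motion, with the monocular displacement stepped
through a geometric (log-spaced) grid of ten values within a single 10-s
trial — one displacement per 1-s bin.  Conditions form a 2 x 2 x 2 design:
interocular phase (in-phase vs anti-phase) crossed with either reference
quality (full / noise / none) or interocular correlation (+1 full-cue,
0 IOVD-uncorrelated, -1 IOVD-anticorrelated), crossed with display
orientation (horizontal / vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

__all__ = [
    "ConditionSpec",
    "SweepProtocol",
    "StimulusSpec",
    "make_sweep_grid",
    "expected_harmonic_signature",
    "design_conditions",
]

INTEROCULAR_PHASES = ("in_phase", "anti_phase")
REFERENCE_TYPES = ("full", "noise", "none")
TEST_CORRELATIONS = (1.0, 0.0, -1.0)
ORIENTATIONS = ("horizontal", "vertical")
TRAJECTORIES = ("one_sided", "straddle_zero")
POPULATIONS = ("adult", "infant")


class InvalidProtocolError(ValueError):
    """Raised when a sweep protocol violates its structural invariants."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the 2 x 2 x 2 experimental design.

    Parameters
    ----------
    interocular_phase : {"in_phase", "anti_phase"}
        Temporal phase relation (0 or 180 degrees) of test-band motion
        between the two eyes.
    test_correlation : {1.0, 0.0, -1.0}
        Interocular correlation of the moving dots: +1 full-cue,
        0 IOVD-uncorrelated, -1 IOVD-anticorrelated.
    reference_type : {"full", "noise", "none"}
        Content of the non-moving reference bands: static correlated dots,
        temporally/interocularly uncorrelated dots, or blank.
    orientation : {"horizontal", "vertical"}
        Direction of the apparent motion on screen.
    trajectory : {"one_sided", "straddle_zero"}
        Whether the monocular motion endpoints stay on one side of zero
        disparity, or straddle it (which removes the uniform/segmented
        perceptual asymmetry and with it the odd-harmonic response).
    population : {"adult", "infant"}
    """

    interocular_phase: str = "in_phase"
    test_correlation: float = 1.0
    reference_type: str = "full"
    orientation: str = "horizontal"
    trajectory: str = "one_sided"
    population: str = "adult"

    def __post_init__(self):
        if self.interocular_phase not in INTEROCULAR_PHASES:
            raise ValueError(f"interocular_phase must be one of {INTEROCULAR_PHASES}")
        if float(self.test_correlation) not in TEST_CORRELATIONS:
            raise ValueError(f"test_correlation must be one of {TEST_CORRELATIONS}")
        if self.reference_type not in REFERENCE_TYPES:
            raise ValueError(f"reference_type must be one of {REFERENCE_TYPES}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"trajectory must be one of {TRAJECTORIES}")
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")

    @property
    def label(self) -> str:
        corr = {1.0: "fullcue", 0.0: "iovd-u", -1.0: "iovd-a"}[float(self.test_correlation)]
        lab = f"{self.interocular_phase}_{corr}_{self.reference_type}ref_{self.orientation}"
        if self.trajectory == "straddle_zero":
            lab += "_straddle"
        if self.population == "infant":
            lab += "_infant"
        return lab

    @property
    def is_symmetric(self) -> bool:
        """True when the stimulus alternation is symmetric, so the evoked
        response carries even harmonics only (planted odd harmonics are 0)."""
        return 1 not in expected_harmonic_signature(self)

    def replace(self, **kwargs) -> "ConditionSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "interocular_phase": self.interocular_phase,
            "test_correlation": float(self.test_correlation),
            "reference_type": self.reference_type,
            "orientation": self.orientation,
            "trajectory": self.trajectory,
            "population": self.population,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        return cls(**d)


@dataclass(frozen=True)
class StimulusSpec:
    """Spatial layout of the random-dot display.

    The display alternates moving test bands and non-moving reference bands;
    one band pair is one spatial cycle, so the band spatial frequency is the
    number of pairs divided by the display extent.
    """

    display_extent_deg: float = 40.0
    n_test_bands: int = 20
    n_reference_bands: int = 20
    dot_diameter_arcmin: float = 4.5
    dot_density_per_deg2: float = 5.0
    update_rate_hz: float = 20.0

    @property
    def band_spatial_frequency_cpd(self) -> float:
        """Spatial frequency of the test/reference band pattern (cycles/deg)."""
        if self.n_test_bands != self.n_reference_bands:
            raise ValueError("band pattern requires equal test and reference band counts")
        return self.n_test_bands / self.display_extent_deg


@dataclass(frozen=True)
class SweepProtocol:
    """Timing and displacement-sweep layout of a single trial.

    A trial consists of ``n_bins`` contiguous bins of ``bin_duration``
    seconds; within bin k the monocular displacement takes the k-th value of
    a geometric grid from ``d_min`` to ``d_max`` arcmin.  The stimulation
    frequency ``f_stim`` is 2 Hz, so each 1-s bin holds exactly two stimulus
    cycles, and responses are analysed at harmonics h * f_stim for
    h = 1..n_harmonics.
    """

    f_stim: float = 2.0
    n_bins: int = 10
    d_min: float = 0.5
    d_max: float = 16.0
    bin_duration: float = 1.0
    fs: float = 420.0
    n_harmonics: int = 4

    def __post_init__(self):
        if self.d_min <= 0 or self.d_max < self.d_min:
            raise InvalidProtocolError("displacements must satisfy 0 < d_min <= d_max")
        if self.n_bins < 2:
            raise InvalidProtocolError("a sweep needs at least 2 bins")
        cyc = self.bin_duration * self.f_stim
        if abs(cyc - round(cyc)) > 1e-9:
            raise InvalidProtocolError("bin_duration must hold whole stimulus cycles")
        ns = self.fs * self.bin_duration
        if abs(ns - round(ns)) > 1e-9:
            raise InvalidProtocolError("fs * bin_duration must be an integer sample count")
        if self.n_harmonics < 1:
            raise InvalidProtocolError("need at least one harmonic")

    @classmethod
    def adult(cls, **kwargs) -> "SweepProtocol":
        return cls(d_min=kwargs.pop("d_min", 0.5), d_max=kwargs.pop("d_max", 16.0), **kwargs)

    @classmethod
    def infant(cls, **kwargs) -> "SweepProtocol":
        return cls(d_min=kwargs.pop("d_min", 2.0), d_max=kwargs.pop("d_max", 32.0), **kwargs)

    @property
    def samples_per_bin(self) -> int:
        return int(round(self.fs * self.bin_duration))

    @property
    def n_samples(self) -> int:
        return self.n_bins * self.samples_per_bin

    @property
    def trial_duration(self) -> float:
        return self.n_bins * self.bin_duration

    @property
    def harmonics(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_harmonics + 1))

    def bin_slices(self) -> list[slice]:
        """Half-open [start, start + samples_per_bin) slices per bin."""
        spb = self.samples_per_bin
        return [slice(k * spb, (k + 1) * spb) for k in range(self.n_bins)]

    def to_dict(self) -> dict:
        return {
            "f_stim": self.f_stim,
            "n_bins": self.n_bins,
            "d_min": self.d_min,
            "d_max": self.d_max,
            "bin_duration": self.bin_duration,
            "fs": self.fs,
            "n_harmonics": self.n_harmonics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepProtocol":
        return cls(**d)


def make_sweep_grid(protocol: SweepProtocol) -> np.ndarray:
    """Geometric displacement grid of the sweep, ``d_min`` to ``d_max``
    inclusive, in arcmin.

    Consecutive entries are in the constant ratio
    ``(d_max / d_min) ** (1 / (n_bins - 1))``.
    """
    return np.geomspace(protocol.d_min, protocol.d_max, protocol.n_bins)


def expected_harmonic_signature(cond: ConditionSpec) -> frozenset[int]:
    """Harmonics at which the condition plants a nonzero evoked response.

    Even harmonics (2F, 4F) are always driven: the motion alternation is
    left/right (or up/down) symmetric regardless of interocular phase.  The
    odd first harmonic indexes the asymmetric alternation between a uniform
    and a segmented (disparate) global configuration, which requires
    anti-phase motion, binocularly matchable dots (full-cue correlation, the
    disparity/CDOT route), a correlated zero-disparity reference, and a
    motion trajectory that stays on one side of zero disparity.  Removing
    any ingredient — in-phase motion, uncorrelated or anticorrelated dots,
    a noise or absent reference, or a trajectory straddling zero — removes
    the asymmetry and with it the 1F response.
    """
    signature = {2, 4}
    if (
        cond.interocular_phase == "anti_phase"
        and float(cond.test_correlation) == 1.0
        and cond.reference_type == "full"
        and cond.trajectory == "one_sided"
    ):
        signature.add(1)
    return frozenset(signature)


def design_conditions(
    experiment: str = "reference",
    trajectory: str = "one_sided",
    population: str = "adult",
) -> list[ConditionSpec]:
    """Enumerate the eight conditions of one 2 x 2 x 2 experiment.

    ``experiment="reference"`` crosses phase x {full, noise} reference x
    orientation (full-cue dots); ``experiment="correlation"`` crosses phase x
    {0, -1} test correlation x orientation (full reference).
    """
    conds = []
    if experiment == "reference":
        for phase, ref, ori in product(INTEROCULAR_PHASES, ("full", "noise"), ORIENTATIONS):
            conds.append(
                ConditionSpec(
                    interocular_phase=phase,
                    test_correlation=1.0,
                    reference_type=ref,
                    orientation=ori,
                    trajectory=trajectory,
                    population=population,
                )
            )
    elif experiment == "correlation":
        for phase, corr, ori in product(INTEROCULAR_PHASES, (0.0, -1.0), ORIENTATIONS):
            conds.append(
                ConditionSpec(
                    interocular_phase=phase,
                    test_correlation=corr,
                    reference_type="full",
                    orientation=ori,
                    trajectory=trajectory,
                    population=population,
                )
            )
    else:
        raise ValueError("experiment must be 'reference' or 'correlation'")
    assert len(conds) == 8
    return conds
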