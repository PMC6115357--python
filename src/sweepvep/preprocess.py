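"""Channel- and epoch-level cleaning of raw sweep trials.

Fixed pipeline order: band-pass filter (0.3-50 Hz, run twice) -> resample to
420 Hz -> bad-sensor detection and nearest-neighbour interpolation ->
common-average re-reference -> segmentation into 1-s epochs (two stimulus
cycles each) -> channel-epoch and whole-epoch artifact rejection.  All
thresholds use strict inequalities ("more than"): boundary equality does not
trigger.  Every decision is recorded in a CleaningReport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .montage import MontageSpec

__all__ = [
    "CleaningReport",
    "EpochedData",
    "bandpass_filter",
    "resample_to_420",
    "detect_bad_sensors",
    "interpolate_sensors",
    "rereference_common_average",
    "segment_epochs",
    "reject_epochs",
    "preprocess_trial",
    "PreprocessedTrial",
]

TARGET_FS = 420.0


class PreprocessingError(ValueError):
    pass


@dataclass
class CleaningReport:
    """Record of every cleaning decision for one trial."""

    excluded_sensors: list[int] = field(default_factory=list)
    interpolated_sensors: dict[int, tuple[int, ...]] = field(default_factory=dict)
    rejected_channel_epochs: dict[int, list[int]] = field(default_factory=dict)
    rejected_epochs: list[int] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not set(self.interpolated_sensors) <= set(self.excluded_sensors):
            raise ValueError("interpolated sensors must be a subset of excluded sensors")

    def to_dict(self) -> dict:
        return {
            "excluded_sensors": list(map(int, self.excluded_sensors)),
            "interpolated_sensors": {
                str(k): list(map(int, v)) for k, v in self.interpolated_sensors.items()
            },
            "rejected_channel_epochs": {
                str(k): list(map(int, v)) for k, v in self.rejected_channel_epochs.items()
            },
            "rejected_epochs": list(map(int, self.rejected_epochs)),
            "thresholds": dict(self.thresholds),
        }


@dataclass
class EpochedData:
    """epochs x channels x samples (uV) with a per-channel validity mask.

    Epoch k of a sweep trial corresponds to displacement bin k; each epoch
    spans ``bin_duration`` seconds, i.e. exactly two cycles at 2 Hz.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    valid: np.ndarray  # (n_channels, n_epochs) bool
    trial_bins: list[tuple[int, int]] | None = None  # (trial, bin) per epoch

    def __post_init__(self):
        n_e, n_c, _ = self.data.shape
        if self.valid.shape != (n_c, n_e):
            raise ValueError("valid mask must be (n_channels, n_epochs)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def bandpass_filter(
    raw: np.ndarray, fs: float, low: float = 0.3, high: float = 50.0, passes: int = 2, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, the whole filter run ``passes``
    times in cascade.

    Zero-phase (forward-backward) filtering preserves the phase of the
    steady-state components that the downstream complex statistics depend on.
    """
    if fs <= 2 * high:
        raise PreprocessingError(f"fs={fs} too low for band edge {high} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    out = np.asarray(raw, dtype=float)
    for _ in range(passes):
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return out


def resample_to_420(signal: np.ndarray, fs_in: float) -> np.ndarray:
    """Polyphase rational resampling to 420 Hz with anti-aliasing.

    420 Hz gives seven samples per 60 Hz video frame; native acquisition is
    typically 500 Hz (ratio 21/25).  Other input rates are accepted with a
    warning.
    """
    if fs_in == TARGET_FS:
        return np.asarray(signal, dtype=float)
    if fs_in not in (420.0, 500.0):
        warnings.warn(f"unusual input rate {fs_in} Hz; resampling anyway", stacklevel=2)
    frac = Fraction(int(round(TARGET_FS * 1000)), int(round(fs_in * 1000)))
    return sps.resample_poly(np.asarray(signal, dtype=float), frac.numerator, frac.denominator, axis=-1)


def detect_bad_sensors(trial: np.ndarray, amp_thresh_uv: float = 30.0, frac: float = 0.15) -> list[int]:
    """Sensors for which strictly more than ``frac`` of samples exceed
    ``amp_thresh_uv`` in absolute value (adult threshold 30 uV; infant
    thresholds range 30-100 uV)."""
    x = np.asarray(trial)
    exceed = np.mean(np.abs(x) > amp_thresh_uv, axis=-1)
    return [int(i) for i in np.flatnonzero(exceed > frac)]


def interpolate_sensors(
    trial: np.ndarray, bad: list[int], montage: MontageSpec
) -> tuple[np.ndarray, dict[int, tuple[int, ...]]]:
    """Replace each bad sensor by the arithmetic mean of its six nearest
    *good* sensors (Euclidean distance in 3-D montage coordinates, ties
    broken by channel index).  Bad sensors never contribute to each other."""
    x = np.asarray(trial, dtype=float).copy()
    bad_set = set(bad)
    pos = montage.positions
    neighbor_map: dict[int, tuple[int, ...]] = {}
    for b in bad:
        d = np.linalg.norm(pos - pos[b][None, :], axis=1)
        order = np.argsort(d, kind="stable")
        good = [int(i) for i in order if i != b and i not in bad_set]
        if len(good) < 6:
            raise PreprocessingError(f"sensor {b}: fewer than 6 good neighbours available")
        nb = tuple(good[:6])
        neighbor_map[b] = nb
        x[b] = trial[list(nb)].mean(axis=0)
    return x, neighbor_map


def rereference_common_average(trial: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across all sensors from every sensor."""
    x = np.asarray(trial, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


def segment_epochs(trial: np.ndarray, fs: float, epoch_ms: float = 1000.0) -> np.ndarray:
    """Cut a channels x time trial into consecutive non-overlapping epochs,
    returning (n_epochs, n_channels, samples_per_epoch).  Epoch k is aligned
    to displacement bin k of the sweep."""
    x = np.asarray(trial, dtype=float)
    spe = fs * epoch_ms / 1000.0
    if abs(spe - round(spe)) > 1e-9:
        raise PreprocessingError("epoch length is not an integer sample count")
    spe = int(round(spe))
    n = x.shape[-1]
    if n % spe != 0:
        raise PreprocessingError(f"trial length {n} is not a multiple of epoch length {spe}")
    n_epochs = n // spe
    return np.stack([x[:, k * spe : (k + 1) * spe] for k in range(n_epochs)], axis=0)


def reject_epochs(
    epochs: np.ndarray,
    noise_thresh: float = 30.0,
    frac: float = 0.10,
    peak_thresh: float = 60.0,
    max_peak_sensors: int = 7,
) -> tuple[np.ndarray, CleaningReport]:
    """Channel-epoch and whole-epoch rejection.

    A channel-epoch is rejected if strictly more than ``frac`` of its samples
    exceed ``noise_thresh`` or any sample exceeds ``peak_thresh``.  If
    strictly more than ``max_peak_sensors`` sensors violate the peak/blink
    threshold within one epoch, the whole epoch is rejected for all channels
    (the typical blink signature).  Returns (valid mask (channels x epochs),
    report)."""
    if noise_thresh <= 0 or peak_thresh <= 0:
        raise PreprocessingError("thresholds must be positive")
    x = np.asarray(epochs)
    n_e, n_c, _ = x.shape
    absx = np.abs(x)
    noisy = np.mean(absx > noise_thresh, axis=-1) > frac  # (n_epochs, n_channels)
    peaked = np.any(absx > peak_thresh, axis=-1)
    whole = np.sum(peaked, axis=1) > max_peak_sensors  # (n_epochs,)
    invalid = noisy | peaked | whole[:, None]
    valid = ~invalid.T  # (n_channels, n_epochs)

    report = CleaningReport(
        thresholds={
            "noise_thresh_uV": noise_thresh,
            "noise_frac": frac,
            "peak_thresh_uV": peak_thresh,
            "max_peak_sensors": max_peak_sensors,
        }
    )
    report.rejected_epochs = [int(k) for k in np.flatnonzero(whole)]
    for c in range(n_c):
        rej = [int(k) for k in np.flatnonzero(invalid[:, c])]
        if rej:
            report.rejected_channel_epochs[c] = rej
    return valid, report


@dataclass
class PreprocessedTrial:
    """Output of the full cleaning chain: the continuous cleaned trial (for
    the recursive estimator), its segmentation, and the cleaning report."""

    continuous: np.ndarray  # (n_channels, n_samples) at fs
    fs: float
    epochs: EpochedData
    report: CleaningReport


def preprocess_trial(
    samples: np.ndarray,
    fs: float,
    montage: MontageSpec,
    *,
    bandpass: tuple[float, float] = (0.3, 50.0),
    filter_passes: int = 2,
    bad_amp_thresh: float = 30.0,
    bad_frac: float = 0.15,
    epoch_ms: float = 1000.0,
    noise_thresh: float = 30.0,
    noise_frac: float = 0.10,
    peak_thresh: float = 60.0,
    max_peak_sensors: int = 7,
    apply_filter: bool = True,
) -> PreprocessedTrial:
    """Run the full fixed-order cleaning chain on one trial.

    ``apply_filter=False`` skips filtering/resampling for data that is
    already band-limited and at 420 Hz (e.g. noiseless synthetic input where
    filter transients would be the only distortion).
    """
    x = np.asarray(samples, dtype=float)
    if apply_filter:
        x = bandpass_filter(x, fs, *bandpass, passes=filter_passes)
        x = resample_to_420(x, fs)
        fs = TARGET_FS
    bad = detect_bad_sensors(x, bad_amp_thresh, bad_frac)
    interp_map: dict[int, tuple[int, ...]] = {}
    if bad:
        x, interp_map = interpolate_sensors(x, bad, montage)
    x = rereference_common_average(x)
    epochs = segment_epochs(x, fs, epoch_ms)
    valid, report = reject_epochs(
        epochs, noise_thresh, noise_frac, peak_thresh, max_peak_sensors
    )
    report.excluded_sensors = list(bad)
    report.interpolated_sensors = interp_map
    report.thresholds.update({"bad_amp_thresh_uV": bad_amp_thresh, "bad_frac": bad_frac})
    report.validate()
    return PreprocessedTrial(
        continuous=x, fs=fs, epochs=EpochedData(data=epochs, fs=fs, valid=valid), report=report
    )
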