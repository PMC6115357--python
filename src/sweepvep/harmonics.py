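"""Complex SSVEP coefficient estimation per displacement bin.

Two estimators of the complex Fourier coefficient (re, im) of each harmonic
of the 2 Hz stimulation frequency within each 1-s bin:

* ``rls_coefficients`` — a joint multi-frequency exponentially weighted
  recursive least-squares adaptive filter over cos/sin regressors at every
  target and sideband frequency, forgetting factor lambda = 1 - 1/M with
  memory M equal to the 1-s bin length; the coefficient is read out at each
  bin's final sample.
* ``dft_coefficients`` — least-squares projection of a bin onto cos/sin at
  each frequency, which equals the scaled DFT bin when the bin holds an
  integer number of cycles.  Serves as the independent oracle estimator and
  a config-selectable alternative.

Coefficients use the convention  x(t) = Re[c * exp(i*omega*t)]  so that a
signal A*cos(omega*t + phi) yields c = A*exp(i*phi): amplitude |c|, phase
arg(c).  Noise is estimated at the two sideband bins F +/- 1 Hz of each
harmonic frequency F, with the scalar noise level the mean of the two
sideband amplitudes (incoherent average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import SweepProtocol

__all__ = [
    "HarmonicSet",
    "CoefficientSet",
    "rls_coefficients",
    "dft_coefficients",
    "sideband_noise",
    "extract_trial",
]


class EstimatorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonicSet:
    """Target harmonics of the stimulation frequency and their sidebands."""

    f_stim: float = 2.0
    harmonics: tuple[int, ...] = (1, 2, 3, 4)
    sideband_offset: float = 1.0

    def target_frequencies(self) -> np.ndarray:
        return np.array([h * self.f_stim for h in self.harmonics])

    def sideband_frequencies(self, harmonic: int) -> tuple[float, float]:
        f = harmonic * self.f_stim
        lo = f - self.sideband_offset
        if lo < self.sideband_offset:
            raise EstimatorConfigError(f"lower sideband of {f} Hz falls below 1 Hz")
        return (lo, f + self.sideband_offset)

    def all_frequencies(self) -> np.ndarray:
        """Unique sorted target + sideband frequencies (shared sidebands,
        e.g. 3 Hz between 1F and 2F, appear once)."""
        freqs: set[float] = set()
        for h in self.harmonics:
            freqs.add(h * self.f_stim)
            freqs.update(self.sideband_frequencies(h))
        return np.array(sorted(freqs))


def _regressors(freqs: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(n_samples, 2K) matrix of cos/sin regressors."""
    w = 2 * np.pi * np.asarray(freqs)[None, :] * t[:, None]
    reg = np.empty((t.size, 2 * len(freqs)))
    reg[:, 0::2] = np.cos(w)
    reg[:, 1::2] = np.sin(w)
    return reg


def dft_coefficients(bin_samples: np.ndarray, fs: float, frequencies) -> np.ndarray:
    """Least-squares cos/sin projection of one bin.

    ``bin_samples`` has shape (..., n_samples); returns complex coefficients
    of shape (..., n_freqs).  With an integer number of cycles per bin this
    equals the (scaled) DFT bin; otherwise a leakage warning is issued and a
    full least-squares solve is used.
    """
    x = np.asarray(bin_samples, dtype=float)
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    n = x.shape[-1]
    t = np.arange(n) / fs
    cycles = freqs * n / fs
    if np.any(np.abs(cycles - np.round(cycles)) > 1e-9):
        warnings.warn("non-integer cycles per bin: spectral leakage likely", stacklevel=2)
        reg = _regressors(freqs, t)  # (n, 2K)
        coef, *_ = np.linalg.lstsq(reg, np.moveaxis(x, -1, 0).reshape(n, -1), rcond=None)
        coef = coef.reshape(2 * len(freqs), *x.shape[:-1])
        a, b = coef[0::2], coef[1::2]
        return np.moveaxis(a - 1j * b, 0, -1)
    cosr = np.cos(2 * np.pi * freqs[:, None] * t[None, :])
    sinr = np.sin(2 * np.pi * freqs[:, None] * t[None, :])
    a = (2.0 / n) * x @ cosr.T
    b = (2.0 / n) * x @ sinr.T
    return a - 1j * b


def rls_coefficients(
    stream: np.ndarray,
    fs: float,
    frequencies,
    memory_samples: int,
    report_samples=None,
    delta: float = 1e4,
) -> np.ndarray:
    """Joint multi-frequency exponentially weighted RLS coefficient tracker.

    Parameters
    ----------
    stream : (n_channels, n_samples) or (n_samples,)
        Continuous recording (one trial).
    frequencies : array_like
        Target frequencies; duplicates raise (singular regressor covariance).
    memory_samples : int
        Memory length M; the forgetting factor is lambda = 1 - 1/M.
    report_samples : array_like of int, optional
        Sample indices at which to report the coefficient state (after
        processing that sample).  Defaults to the final sample only.
    delta : float
        Inverse-covariance initialisation P(0) = delta * I.

    Returns
    -------
    complex ndarray of shape (n_reports, n_freqs, n_channels)
        Convention c = A*exp(i*phi) for an input A*cos(2*pi*f*t + phi);
        regressor time t is the global stream time.
    """
    x = np.atleast_2d(np.asarray(stream, dtype=float))
    n_ch, n_samples = x.shape
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if len(np.unique(np.round(freqs, 9))) != len(freqs):
        raise EstimatorConfigError("duplicate target frequencies make the solve singular")
    if np.any(freqs >= fs / 2):
        raise EstimatorConfigError("target frequencies must be below fs/2")
    if memory_samples < 2:
        raise EstimatorConfigError("memory must be at least 2 samples")
    if report_samples is None:
        report_samples = [n_samples - 1]
    report_samples = np.asarray(report_samples, dtype=int)

    lam = 1.0 - 1.0 / memory_samples
    k2 = 2 * len(freqs)
    t = np.arange(n_samples) / fs
    reg = _regressors(freqs, t)

    P = delta * np.eye(k2)
    W = np.zeros((k2, n_ch))
    report_set = {int(i): j for j, i in enumerate(report_samples)}
    out = np.zeros((len(report_samples), len(freqs), n_ch), dtype=complex)

    for i in range(n_samples):
        phi = reg[i]
        Pphi = P @ phi
        g = Pphi / (lam + phi @ Pphi)
        err = x[:, i] - W.T @ phi
        W += np.outer(g, err)
        P = (P - np.outer(g, Pphi)) / lam
        P = 0.5 * (P + P.T)  # keep symmetric against drift
        j = report_set.get(i)
        if j is not None:
            out[j] = W[0::2] - 1j * W[1::2]
    return out


@dataclass
class CoefficientSet:
    """Complex coefficients of one trial: (n_bins, n_harmonics, n_channels)
    arrays for the signal and the two sidebands, with a validity mask."""

    signal: np.ndarray
    sb_lower: np.ndarray
    sb_upper: np.ndarray
    harmonics: tuple[int, ...]
    valid: np.ndarray  # (n_channels, n_bins) bool
    estimator: str = "dft"
    burn_in_bins: tuple[int, ...] = ()  # bins where the adaptive filter starts cold
    participant: str = "P00"
    trial: int = 0
    condition_label: str = ""

    @property
    def noise_level(self) -> np.ndarray:
        """Scalar sideband noise level per bin/harmonic/channel: mean of the
        two sideband amplitudes (incoherent average)."""
        return 0.5 * (np.abs(self.sb_lower) + np.abs(self.sb_upper))

    def to_dataframe(self) -> pd.DataFrame:
        n_bins, n_harm, n_ch = self.signal.shape
        bins, harms, chans = np.meshgrid(
            np.arange(n_bins), np.asarray(self.harmonics), np.arange(n_ch), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "participant": self.participant,
                "trial": self.trial,
                "condition": self.condition_label,
                "harmonic": harms.ravel(),
                "bin": bins.ravel(),
                "channel": chans.ravel(),
                "re": self.signal.real.ravel(),
                "im": self.signal.imag.ravel(),
                "noise_re_lo": self.sb_lower.real.ravel(),
                "noise_im_lo": self.sb_lower.imag.ravel(),
                "noise_re_hi": self.sb_upper.real.ravel(),
                "noise_im_hi": self.sb_upper.imag.ravel(),
                "valid": self.valid[chans.ravel(), bins.ravel()],
            }
        )
        return df


def sideband_noise(bin_samples: np.ndarray, fs: float, harmonic: int, hset: HarmonicSet | None = None):
    """Complex coefficients at F +/- 1 Hz of one harmonic for one bin, and
    the scalar noise level (mean of the two amplitudes).

    Returns (c_lower, c_upper, level)."""
    hset = hset or HarmonicSet()
    lo, hi = hset.sideband_frequencies(harmonic)
    c = dft_coefficients(bin_samples, fs, [lo, hi])
    c_lo, c_hi = c[..., 0], c[..., 1]
    return c_lo, c_hi, 0.5 * (np.abs(c_lo) + np.abs(c_hi))


def extract_trial(
    samples: np.ndarray,
    protocol: SweepProtocol,
    hset: HarmonicSet | None = None,
    estimator: str = "rls",
    valid: np.ndarray | None = None,
    participant: str = "P00",
    trial: int = 0,
    condition_label: str = "",
) -> CoefficientSet:
    """Estimate signal and sideband coefficients for every bin of one
    cleaned trial (channels x time, at the protocol's sampling rate)."""
    hset = hset or HarmonicSet(f_stim=protocol.f_stim, harmonics=protocol.harmonics)
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch = x.shape[0]
    if x.shape[1] != protocol.n_samples:
        raise ValueError("trial length does not match the protocol")
    freqs = hset.all_frequencies()
    fmap = {round(float(f), 9): i for i, f in enumerate(freqs)}
    spb = protocol.samples_per_bin

    if estimator == "rls":
        report = [(k + 1) * spb - 1 for k in range(protocol.n_bins)]
        coefs = rls_coefficients(x, protocol.fs, freqs, memory_samples=spb, report_samples=report)
    elif estimator == "dft":
        coefs = np.stack(
            [dft_coefficients(x[:, sl], protocol.fs, freqs).transpose(1, 0) for sl in protocol.bin_slices()]
        )  # (n_bins, n_freqs, n_channels)
    else:
        raise EstimatorConfigError(f"unknown estimator {estimator!r} (use 'rls' or 'dft')")

    n_bins = protocol.n_bins
    n_harm = len(hset.harmonics)
    sig = np.zeros((n_bins, n_harm, n_ch), dtype=complex)
    lo = np.zeros_like(sig)
    hi = np.zeros_like(sig)
    for j, h in enumerate(hset.harmonics):
        f = h * hset.f_stim
        flo, fhi = hset.sideband_frequencies(h)
        sig[:, j] = coefs[:, fmap[round(f, 9)]]
        lo[:, j] = coefs[:, fmap[round(flo, 9)]]
        hi[:, j] = coefs[:, fmap[round(fhi, 9)]]
    if valid is None:
        valid = np.ones((n_ch, n_bins), dtype=bool)
    return CoefficientSet(
        signal=sig,
        sb_lower=lo,
        sb_upper=hi,
        harmonics=tuple(hset.harmonics),
        valid=np.asarray(valid, dtype=bool),
        estimator=estimator,
        burn_in_bins=(0,) if estimator == "rls" else (),
        participant=participant,
        trial=trial,
        condition_label=condition_label,
    )
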