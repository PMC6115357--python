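"""Complex-domain group statistics for steady-state coefficients.

Vector averaging: the real and imaginary coefficients are averaged across
participants first and the amplitude taken of the result, preserving the
phase consistency of a phase-locked response.  For inferential statistics
each participant's complex vector is projected onto the unit group-mean
vector, yielding a signed scalar amplitude per participant whose mean
exactly equals the group vector-average amplitude; SEMs and paired t tests
operate on these projections.  Displacement averages are computed by
averaging real and imaginary parts across the 10 bins within participant,
then vector averaging across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupVectorEntry",
    "participant_mean",
    "vector_average",
    "displacement_average",
    "projected_amplitude",
    "projected_amplitudes",
    "paired_t_comparison",
    "comparison_table",
    "noise_floor",
]


@dataclass(frozen=True)
class GroupVectorEntry:
    """Group vector average of one harmonic x bin cell."""

    mean: complex
    amplitude: float
    sem: float
    n: int

    @property
    def phase(self) -> float:
        return float(np.angle(self.mean))


def participant_mean(values: np.ndarray, valid: np.ndarray | None = None) -> complex:
    """Trial-level vector mean for one participant: re and im averaged over
    that participant's valid epochs."""
    v = np.asarray(values, dtype=complex).ravel()
    if valid is not None:
        v = v[np.asarray(valid, dtype=bool).ravel()]
    if v.size == 0:
        return complex(np.nan, np.nan)
    return complex(v.mean())


def vector_average(per_participant: np.ndarray) -> GroupVectorEntry:
    """Vector average across participants of per-participant complex values
    (each already a trial-level vector mean)."""
    v = np.asarray(per_participant, dtype=complex).ravel()
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("vector averaging requires >= 2 participants with valid data")
    mean = complex(v.mean())
    proj = projected_amplitudes(v)
    sem = float(np.std(proj, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupVectorEntry(mean=mean, amplitude=abs(mean), sem=sem, n=v.size)


def displacement_average(per_participant_bins: np.ndarray) -> GroupVectorEntry:
    """Average across displacement bins, then across participants.

    ``per_participant_bins`` is (n_participants, n_bins) complex; the
    within-participant complex mean over bins is taken first, then the group
    vector average.  The order matters: this is not the pooled epoch mean
    when validity is unbalanced.
    """
    v = np.asarray(per_participant_bins, dtype=complex)
    if v.ndim != 2:
        raise ValueError("expected (n_participants, n_bins)")
    per_part = np.nanmean(v, axis=1)
    return vector_average(per_part)


def projected_amplitude(x: complex, group_mean: complex) -> float:
    """Signed scalar projection of one participant's complex vector onto the
    unit group-mean vector (2-D dot product of (re, im) pairs).

    The group mean must be computed *including* the participant, which makes
    the mean of the projections equal the group vector-average amplitude."""
    g = abs(group_mean)
    if g == 0:
        raise ValueError("group mean has zero amplitude; projection undefined")
    return float((x.real * group_mean.real + x.imag * group_mean.imag) / g)


def projected_amplitudes(per_participant: np.ndarray, group_mean: complex | None = None) -> np.ndarray:
    v = np.asarray(per_participant, dtype=complex).ravel()
    g = complex(v.mean()) if group_mean is None else group_mean
    return np.array([projected_amplitude(x, g) for x in v])


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of projected amplitudes between two conditions."""

    t: float
    df: int
    p: float
    cohens_d: float
    n: int
    label_a: str = "A"
    label_b: str = "B"
    bin: object = None  # bin index or "average"


def paired_t_comparison(
    projections_a: np.ndarray,
    projections_b: np.ndarray,
    label_a: str = "A",
    label_b: str = "B",
    bin=None,
) -> ComparisonResult:
    """Paired two-tailed t test on per-participant projected amplitudes,
    with Cohen's d for paired samples (mean difference / SD of differences)."""
    a = np.asarray(projections_a, dtype=float)
    b = np.asarray(projections_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs the same participants in both conditions")
    n = a.size
    if n < 3:
        raise ValueError("refusing paired t test with fewer than 3 participants")
    diff = a - b
    sd = np.std(diff, ddof=1)
    if sd == 0:
        t, p = 0.0, 1.0
        d = 0.0
    else:
        t, p = sstats.ttest_rel(a, b)
        d = float(diff.mean() / sd)
    return ComparisonResult(
        t=float(t), df=n - 1, p=float(p), cohens_d=d, n=n, label_a=label_a, label_b=label_b, bin=bin
    )


def comparison_table(
    coefs_a: np.ndarray,
    coefs_b: np.ndarray,
    label_a: str = "A",
    label_b: str = "B",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-bin and displacement-average paired comparisons.

    ``coefs_a``/``coefs_b`` are (n_participants, n_bins) complex arrays of
    per-participant (trial-averaged) coefficients.  No multiple-testing
    correction by default; ``bonferroni=True`` scales per-bin p values by
    the number of bins.
    """
    a = np.asarray(coefs_a, dtype=complex)
    b = np.asarray(coefs_b, dtype=complex)
    if a.shape != b.shape:
        raise ValueError("condition arrays must be aligned (participants x bins)")
    n_bins = a.shape[1]
    rows = []
    for k in range(n_bins):
        pa = projected_amplitudes(a[:, k])
        pb = projected_amplitudes(b[:, k])
        r = paired_t_comparison(pa, pb, label_a, label_b, bin=k)
        rows.append(r)
    pa = projected_amplitudes(a.mean(axis=1))
    pb = projected_amplitudes(b.mean(axis=1))
    rows.append(paired_t_comparison(pa, pb, label_a, label_b, bin="average"))
    df = pd.DataFrame(
        {
            "pair": f"{label_a} vs {label_b}",
            "bin": [r.bin for r in rows],
            "t": [r.t for r in rows],
            "df": [r.df for r in rows],
            "p": [r.p for r in rows],
            "cohens_d": [r.cohens_d for r in rows],
            "n": [r.n for r in rows],
        }
    )
    if bonferroni:
        per_bin = df["bin"] != "average"
        df.loc[per_bin, "p"] = np.minimum(df.loc[per_bin, "p"] * n_bins, 1.0)
    return df


def coherent_noise_floor(sb_lower: np.ndarray, sb_upper: np.ndarray) -> float:
    """Vector-averaged noise floor, directly comparable to vector-averaged
    signal amplitudes.

    The complex sideband coefficients pass through the same two-stage
    averaging as the signal (mean across trials/bins within participant,
    then across participants); the floor is the mean of the two sidebands'
    resulting amplitudes.  Because sideband phases are random across trials,
    this floor shrinks with the number of trials exactly as the noise in the
    signal's vector average does — it is the background level a planted
    component must rise above.
    """
    lo = np.asarray(sb_lower, dtype=complex)
    hi = np.asarray(sb_upper, dtype=complex)
    return float(0.5 * (abs(np.nanmean(lo)) + abs(np.nanmean(hi))))


def noise_floor(sideband_levels: np.ndarray, axis=None) -> np.ndarray:
    """Incoherent average of projected sideband noise levels.

    ``sideband_levels`` holds the per-trial scalar noise levels (mean of the
    two sideband amplitudes, already projected through the same component
    weights as the signal); the floor is their plain mean across trials,
    participants and conditions, kept per displacement bin unless ``axis``
    collapses it."""
    return np.nanmean(np.asarray(sideband_levels, dtype=float), axis=axis)
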