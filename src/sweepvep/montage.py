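"""Electrode montage: positions on the unit sphere and neighbour structure.

High-density geodesic nets (128 channels for adults, 124 for infants) are
modelled as points distributed over a spherical cap covering the scalp.  The
exact manufacturer geometry is not needed by any algorithm here — only
pairwise distances (for nearest-neighbour interpolation) and smooth spatial
structure (for topographies) matter — so positions are generated with a
Fibonacci spiral over the cap, which gives a near-uniform layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MontageSpec", "make_montage"]


@dataclass(frozen=True)
class MontageSpec:
    """Channel labels, 3-D unit-sphere positions and 6-nearest neighbours."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    neighbors: tuple[tuple[int, ...], ...]  # >= 6 per channel

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if pos.shape[0] != len(self.labels):
            raise ValueError("labels/positions length mismatch")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(np.unique(pos.round(12), axis=0)) != pos.shape[0]:
            raise ValueError("positions must be distinct")
        if any(len(nb) < 6 for nb in self.neighbors):
            raise ValueError("every channel needs at least 6 neighbours")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MontageSpec":
        df = pd.read_csv(path)
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        return cls(
            labels=tuple(df["label"].astype(str)),
            positions=pos,
            neighbors=_knn_neighbors(pos, k=6),
        )


def _knn_neighbors(pos: np.ndarray, k: int = 6) -> tuple[tuple[int, ...], ...]:
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # stable sort => ties broken by channel index
    order = np.argsort(d, axis=1, kind="stable")
    return tuple(tuple(int(j) for j in order[i, :k]) for i in range(pos.shape[0]))


def make_montage(n_channels: int = 128, cap_fraction: float = 0.75) -> MontageSpec:
    """Near-uniform montage of ``n_channels`` electrodes over a scalp cap.

    ``cap_fraction`` is the fraction of the full sphere's z-extent covered,
    from the vertex (z = 1) downward; 0.75 reaches below the equator the way
    a dense net does.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    i = np.arange(n_channels)
    golden = (1 + np.sqrt(5)) / 2
    z = 1.0 - (i + 0.5) / n_channels * 2.0 * cap_fraction
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = tuple(f"E{j + 1}" for j in i)
    return MontageSpec(labels=labels, positions=pos, neighbors=_knn_neighbors(pos, k=6))
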