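"""Reliable Components Analysis (RCA).

RCA finds sensor weightings w that maximise trial-to-trial consistency of
the evoked response.  Because the steady-state response phase is constant
over repeated trials of the same stimulus, the real and imaginary Fourier
coefficients of each 1-s epoch, stacked across sensors, correlate across
trials at reliable sensors.  RCA therefore maximises the ratio of
across-trial covariance to pooled within-trial covariance,

    R_xy w = rho * R_pool w,

a generalized eigenvalue problem.  R_xy averages the covariance between all
ordered pairs of distinct trials within the same condition cell (pooled over
conditions and participants, symmetrized); R_pool is the ordinary covariance
of all trials pooled.  The problem is solved in the top-``rank`` principal
subspace of R_pool (default 60) — the standard stabilisation for
128-channel data.  Eigenvalues rho are sorted descending; the first
component (RC1) is the default read-out, with an override for selecting a
component by topography similarity to a template (the infant case, where the
adult-like component may appear further down the spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

__all__ = ["TrialBlock", "RCAInput", "ReliableComponents", "RCAResults",
           "build_rca_input", "project_through", "pool_participants"]


@dataclass(frozen=True)
class TrialBlock:
    """One trial's stacked [re; im] coefficient rows (2 rows per epoch,
    sensors as columns), with identifying keys."""

    X: np.ndarray  # (n_rows, n_channels)
    condition: str
    participant: str
    trial: int
    session: int = 0

    def __post_init__(self):
        if self.X.ndim != 2:
            raise ValueError("trial block must be 2-D (rows x channels)")


@dataclass
class RCAInput:
    """Collection of aligned trial blocks; the RCA design matrix."""

    blocks: list[TrialBlock]
    harmonic: int | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("RCAInput needs at least one trial block")
        n_ch = {b.X.shape[1] for b in self.blocks}
        if len(n_ch) != 1:
            raise ValueError("all trial blocks must share the channel dimension")

    @property
    def n_channels(self) -> int:
        return self.blocks[0].X.shape[1]

    @property
    def n_rows(self) -> int:
        return sum(b.X.shape[0] for b in self.blocks)

    def stacked(self) -> np.ndarray:
        return np.vstack([np.nan_to_num(b.X) for b in self.blocks])

    def participants(self) -> set[str]:
        return {b.participant for b in self.blocks}


def build_rca_input(coefficient_sets, harmonic: int, provenance: str = "") -> RCAInput:
    """Assemble an RCAInput from per-trial CoefficientSet objects for one
    harmonic: each valid epoch contributes one real row and one imaginary
    row across sensors; invalid channel-epochs enter as zeros (they carry no
    covariance)."""
    blocks = []
    for cs in coefficient_sets:
        j = cs.harmonics.index(harmonic)
        sig = cs.signal[:, j, :]  # (n_bins, n_channels)
        mask = cs.valid.T.astype(float)  # (n_bins, n_channels)
        rows = np.empty((2 * sig.shape[0], sig.shape[1]))
        rows[0::2] = sig.real * mask
        rows[1::2] = sig.imag * mask
        blocks.append(
            TrialBlock(
                X=rows, condition=cs.condition_label, participant=cs.participant, trial=cs.trial
            )
        )
    return RCAInput(blocks=blocks, harmonic=harmonic,
                    provenance=[provenance] if provenance else [])


def pool_participants(datasets: list[RCAInput], dedup: str = "first_session") -> RCAInput:
    """Pool several experiments' inputs into one.

    A participant present in more than one dataset contributes only their
    first session (``dedup="first_session"``, session ties broken by dataset
    order); disjoint participants concatenate unchanged.
    """
    if dedup != "first_session":
        raise ValueError("only the 'first_session' dedup rule is defined")
    first: dict[str, tuple[int, int]] = {}  # participant -> (dataset idx, session)
    for di, ds in enumerate(datasets):
        for b in ds.blocks:
            key = (di, b.session)
            if b.participant not in first or key < first[b.participant]:
                first[b.participant] = key
    blocks = [
        b
        for di, ds in enumerate(datasets)
        for b in ds.blocks
        if first[b.participant] == (di, b.session)
    ]
    harmonics = {ds.harmonic for ds in datasets}
    prov = [p for ds in datasets for p in ds.provenance]
    return RCAInput(blocks=blocks, harmonic=harmonics.pop() if len(harmonics) == 1 else None,
                    provenance=prov)


class ReliableComponents:
    """RCA model: fit sensor weightings maximizing cross-trial reliability.

    Parameters
    ----------
    data : RCAInput
        Aligned [re; im] rows per trial, grouped by condition cell.
    n_components : int
        Number of components K to retain.
    rank : int
        Dimension of the principal subspace of R_pool in which the
        generalized eigenproblem is solved (regularization).
    """

    def __init__(self, data: RCAInput, n_components: int = 3, rank: int = 60):
        self.data = data
        self.n_components = int(n_components)
        self.rank = int(rank)
        if self.rank > data.n_channels:
            self.rank = data.n_channels
        conds: dict[str, list[TrialBlock]] = {}
        for b in data.blocks:
            conds.setdefault(b.condition, []).append(b)
        if all(len(v) < 2 for v in conds.values()):
            raise ValueError("need >= 2 trials in at least one condition cell")
        self._cond_blocks = conds

    def _covariances(self) -> tuple[np.ndarray, np.ndarray]:
        n_ch = self.data.n_channels
        rxy = np.zeros((n_ch, n_ch))
        rpool = np.zeros((n_ch, n_ch))
        n_pairs = 0
        n_rows = 0
        for blocks in self._cond_blocks.values():
            mats = [np.nan_to_num(b.X) for b in blocks]
            lens = {m.shape[0] for m in mats}
            if len(lens) != 1:
                raise ValueError("trials within a condition cell must have aligned rows")
            s = np.zeros((n_ch, n_ch))
            tot = np.zeros((len(mats[0]), n_ch))
            for m in mats:
                s += m.T @ m
                tot += m
                n_rows += m.shape[0]
            rpool += s
            if len(mats) >= 2:
                rxy += tot.T @ tot - s  # sum over ordered pairs i != j
                n_pairs += len(mats) * (len(mats) - 1) * mats[0].shape[0]
        if n_pairs == 0:
            raise ValueError("no condition cell has >= 2 trials")
        rxy /= n_pairs
        rpool /= n_rows
        rxy = 0.5 * (rxy + rxy.T)
        rpool = 0.5 * (rpool + rpool.T)
        return rxy, rpool

    def fit(self) -> "RCAResults":
        rxy, rpool = self._covariances()
        evals, evecs = np.linalg.eigh(rpool)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = max(evals.max(), 0) * 1e-10
        rank = min(self.rank, int(np.sum(evals > tol)))
        if rank < 1:
            raise np.linalg.LinAlgError(
                "R_pool is rank deficient; lower `rank` or add trials/regularization"
            )
        V = evecs[:, :rank]
        import scipy.linalg as sla

        rho, w_sub = sla.eigh(V.T @ rxy @ V, V.T @ rpool @ V)
        order = np.argsort(rho)[::-1]
        rho, w_sub = rho[order], w_sub[:, order]
        K = min(self.n_components, rank)
        W = V @ w_sub  # all rank components; keep full set for diagnostics
        # sign convention: largest-magnitude entry of each column positive
        for k in range(W.shape[1]):
            j = np.argmax(np.abs(W[:, k]))
            if W[j, k] < 0:
                W[:, k] = -W[:, k]
                w_sub[:, k] = -w_sub[:, k]
        # forward model (topographies) A = Rpool W (W' Rpool W)^-1; the
        # generalized eigenvectors are Rpool-orthonormal so this is Rpool W
        A_full = rpool @ W @ np.linalg.inv(W.T @ rpool @ W)
        WK = W[:, :K]

        X = self.data.stacked()
        total_var = float(np.sum(X * X) / X.shape[0])
        proj = X @ W
        comp_var = np.sum(proj * proj, axis=0) / X.shape[0]
        pos = rho[:rank][rho[:rank] > 0]
        rel_expl = np.where(rho > 0, rho / pos.sum(), 0.0) if pos.size else np.zeros_like(rho)
        # variance accounted by reconstructing the data from component k
        # through its forward topography (projections alone are degenerate:
        # Rpool-normalization gives every component unit projected variance)
        recon_var = comp_var * np.sum(A_full**2, axis=0)
        var_expl = recon_var / total_var if total_var > 0 else np.zeros_like(comp_var)

        return RCAResults(
            model=self,
            W=WK,
            A=A_full[:, :K],
            eigenvalues=rho,
            W_full=W,
            A_forward_full=A_full,
            subspace=V,
            rank=rank,
            reliability_explained=rel_expl,
            variance_explained=var_expl,
            rxy=rxy,
            rpool=rpool,
        )


@dataclass
class RCAResults:
    """Fitted reliable components: weights, forward topographies,
    generalized eigenvalues and explained-reliability/variance summaries."""

    model: ReliableComponents
    W: np.ndarray  # (n_channels, K) retained weight columns
    A: np.ndarray  # (n_channels, K) forward topographies
    eigenvalues: np.ndarray  # (rank,), descending
    W_full: np.ndarray  # (n_channels, rank)
    A_forward_full: np.ndarray  # (n_channels, rank)
    subspace: np.ndarray  # (n_channels, rank) principal basis of R_pool
    rank: int
    reliability_explained: np.ndarray
    variance_explained: np.ndarray
    rxy: np.ndarray
    rpool: np.ndarray

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def project(self, coefficients: np.ndarray, component: int = 1) -> np.ndarray:
        """Project channel-space data (..., n_channels), real or complex,
        through the weights of one component (1-based; RC1 by default).
        Real and imaginary parts pass through the same real weight column, so
        complex arrays project directly."""
        if not 1 <= component <= self.W_full.shape[1]:
            raise ValueError(f"component must be in 1..{self.W_full.shape[1]}")
        x = np.asarray(coefficients)
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError("channel dimension does not match the fitted weights")
        return x @ self.W_full[:, component - 1]

    def select_component(self, template_topography: np.ndarray) -> int:
        """1-based index of the component whose forward topography is most
        similar (absolute correlation) to a template — the documented
        override for cohorts where RC1 is not the physiological component."""
        t = np.asarray(template_topography, dtype=float)
        t = t - t.mean()
        best, best_r = 1, -1.0
        for k in range(self.W_full.shape[1]):
            a = self.A_forward_full[:, k]
            a = a - a.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(t)
            r = abs(float(a @ t) / denom) if denom > 0 else 0.0
            if r > best_r:
                best, best_r = k + 1, r
        return best

    def gevd_residual(self) -> float:
        """Relative residual of R_xy W = R_pool W diag(rho), measured in the
        regularized subspace (components of R_xy outside the retained
        principal subspace of R_pool are not modelled)."""
        Wf = self.W_full
        V = self.subspace
        lhs = V.T @ self.rxy @ Wf
        rhs = V.T @ self.rpool @ Wf @ np.diag(self.eigenvalues[: Wf.shape[1]])
        return float(np.linalg.norm(lhs - rhs) / max(np.linalg.norm(lhs), 1e-30))

    def summary(self) -> str:
        lines = [
            "Reliable Components Analysis",
            "=" * 52,
            f"channels {self.W.shape[0]}  rank {self.rank}  components kept {self.n_components}",
            f"{'RC':<4}{'rho':>10}{'reliability':>14}{'variance':>12}",
            "-" * 52,
        ]
        for k in range(self.n_components):
            lines.append(
                f"{k + 1:<4}{self.eigenvalues[k]:>10.4f}"
                f"{100 * self.reliability_explained[k]:>13.1f}%"
                f"{100 * self.variance_explained[k]:>11.1f}%"
            )
        return "\n".join(lines)

    def topography_dataframe(self, labels=None):
        import pandas as pd

        n_ch = self.W.shape[0]
        labels = labels if labels is not None else [f"E{i + 1}" for i in range(n_ch)]
        df = pd.DataFrame({"channel": labels})
        for k in range(self.n_components):
            df[f"rc{k + 1}_weight"] = self.W[:, k]
            df[f"rc{k + 1}_topography"] = self.A[:, k]
        return df

    def plot_topography(self, montage, component: int = 1, ax=None):
        """Minimal scalp view: forward-topography weights at the montage's
        2-D (x, y) projection."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a = self.A[:, component - 1]
        sc = ax.scatter(montage.positions[:, 0], montage.positions[:, 1], c=a, cmap="RdBu_r")
        ax.set_aspect("equal")
        ax.set_title(f"RC{component} topography")
        plt.colorbar(sc, ax=ax)
        return ax

    def to_json(self, path) -> None:
        payload = {
            "W": self.W.tolist(),
            "A": self.A.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "rank": self.rank,
            "reliability_explained": self.reliability_explained.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "harmonic": self.model.data.harmonic,
            "provenance": self.model.data.provenance,
        }
        with open(path, "w") as f:
            json.dump(payload, f)


def project_through(coefficients: np.ndarray, results: RCAResults, component: int = 1) -> np.ndarray:
    """Project channel-space coefficients (and, with the same weights,
    their sideband noise twins) into component space."""
    return results.project(coefficients, component=component)
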