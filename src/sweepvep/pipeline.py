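"""End-to-end pipeline: simulate -> preprocess -> extract -> rca -> stats -> fit.

A single YAML/JSON config drives every stage; all randomness is seeded, the
config hash is embedded in every results table, and a run manifest records
the stage chain with output hashes so any table can be traced back to the
seed that produced it.  Re-running an identical config reproduces identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .groupstats import comparison_table, noise_floor, participant_mean, vector_average
from .harmonics import HarmonicSet, extract_trial
from .montage import make_montage
from .nakarushton import fit_nr, suppression_index
from .preprocess import preprocess_trial
from .protocol import ConditionSpec, SweepProtocol
from .rca import ReliableComponents, build_rca_input
from .synth import CohortSpec, NoiseSpec, generate_cohort
from .io import save_recording, write_edf

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

STAGES = ("simulate", "preprocess", "extract", "rca", "stats", "fit")


class PipelineConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    protocol: dict = Field(default_factory=dict)
    conditions: list[dict] = Field(
        default_factory=lambda: [
            {"interocular_phase": "in_phase"},
            {"interocular_phase": "anti_phase"},
        ]
    )
    n_participants: int = 5
    n_trials: int = 3
    n_channels: int = 128
    seed: int = 0
    estimator: str = "rls"
    harmonic: int = 2
    rca_rank: int = 60
    rca_components: int = 3
    noise: dict = Field(default_factory=dict)
    cohort: dict = Field(default_factory=dict)
    thresholds: dict = Field(default_factory=dict)
    apply_filter: bool = False
    save_raw: str = "none"  # none | npz | edf
    outdir: str = "pipeline_out"

    @field_validator("estimator")
    @classmethod
    def _check_estimator(cls, v):
        if v not in ("rls", "dft"):
            raise ValueError("estimator must be 'rls' or 'dft'")
        return v

    @field_validator("save_raw")
    @classmethod
    def _check_save_raw(cls, v):
        if v not in ("none", "npz", "edf"):
            raise ValueError("save_raw must be none|npz|edf")
        return v

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))

    def sweep_protocol(self) -> SweepProtocol:
        return SweepProtocol(**self.protocol)

    def condition_specs(self) -> list[ConditionSpec]:
        return [ConditionSpec(**c) for c in self.conditions]

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.model_dump()
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance chain of one run."""

    config_hash: str
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    completed: bool = False

    def record(self, stage: str, outputs: dict[str, str], t0: float) -> None:
        self.stages.append(
            {
                "stage": stage,
                "outputs": outputs,
                "elapsed_s": round(time.time() - t0, 3),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "completed": self.completed,
                },
                f,
                indent=2,
            )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> str:
    df = df.copy()
    df["config_hash"] = config_hash
    df.to_csv(path, index=False)
    return _file_hash(path)


def run_pipeline(config: PipelineConfig, stop_after: str = "fit") -> RunManifest:
    """Execute the pipeline stages in fixed order up to ``stop_after``.

    On a stage failure the manifest records the partial state (stages
    completed so far plus the error) and is re-raised-free: the manifest is
    always written to ``<outdir>/manifest.json``.
    """
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    manifest = RunManifest(config_hash=chash)
    protocol = config.sweep_protocol()
    conditions = config.condition_specs()
    montage = make_montage(config.n_channels)
    stop_idx = STAGES.index(stop_after)

    state: dict = {}
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")

            # --- simulate ---------------------------------------------------
            t0 = time.time()
            recs = generate_cohort(
                config.n_participants,
                conditions,
                protocol,
                seed=config.seed,
                montage=montage,
                noise=NoiseSpec(**config.noise) if config.noise else NoiseSpec(),
                cohort=CohortSpec(
                    n_participants=config.n_participants,
                    n_trials=config.n_trials,
                    **config.cohort,
                ),
            )
            outputs = {"n_recordings": str(len(recs))}
            if config.save_raw != "none":
                rawdir = outdir / "raw"
                rawdir.mkdir(exist_ok=True)
                for r in recs:
                    stem = rawdir / f"{r.participant}_{r.condition.label}_t{r.trial:02d}"
                    if config.save_raw == "npz":
                        save_recording(r, stem)
                    else:
                        write_edf(r, stem.with_suffix(".edf"))
                outputs["raw_dir"] = str(rawdir)
            manifest.record("simulate", outputs, t0)
            state["recordings"] = recs
            if stop_idx < 1:
                raise _Stop

            # --- preprocess -------------------------------------------------
            t0 = time.time()
            pre = [
                preprocess_trial(
                    r.samples, r.fs, montage, apply_filter=config.apply_filter,
                    **config.thresholds,
                )
                for r in recs
            ]
            n_rej = sum(len(p.report.rejected_epochs) for p in pre)
            manifest.record("preprocess", {"whole_epoch_rejections": str(n_rej)}, t0)
            state["preprocessed"] = pre
            if stop_idx < 2:
                raise _Stop

            # --- extract ----------------------------------------------------
            t0 = time.time()
            hset = HarmonicSet(f_stim=protocol.f_stim, harmonics=protocol.harmonics)
            coef_sets = [
                extract_trial(
                    p.continuous,
                    protocol,
                    hset,
                    estimator=config.estimator,
                    valid=p.epochs.valid,
                    participant=r.participant,
                    trial=r.trial,
                    condition_label=r.condition.label,
                )
                for r, p in zip(recs, pre)
            ]
            coef_df = pd.concat([c.to_dataframe() for c in coef_sets], ignore_index=True)
            h = _write_csv(coef_df, outdir / "coefficients.csv", chash)
            manifest.record("extract", {"coefficients.csv": h}, t0)
            state["coef_sets"] = coef_sets
            if stop_idx < 3:
                raise _Stop

            # --- rca --------------------------------------------------------
            t0 = time.time()
            rca_in = build_rca_input(coef_sets, harmonic=config.harmonic,
                                     provenance=f"seed={config.seed}")
            rca_res = ReliableComponents(
                rca_in, n_components=config.rca_components, rank=config.rca_rank
            ).fit()
            rca_res.to_json(outdir / "rc_model.json")
            topo = rca_res.topography_dataframe(labels=list(montage.labels))
            h1 = _write_csv(topo, outdir / "rc_topographies.csv", chash)
            manifest.record(
                "rca", {"rc_model.json": _file_hash(outdir / "rc_model.json"),
                        "rc_topographies.csv": h1}, t0
            )
            state["rca"] = rca_res
            if stop_idx < 4:
                raise _Stop

            # --- stats ------------------------------------------------------
            t0 = time.time()
            j = protocol.harmonics.index(config.harmonic)
            by_cond: dict[str, dict[str, list]] = {}
            nf_levels = []
            for cs in coef_sets:
                sig = rca_res.project(cs.signal[:, j, :])  # (n_bins,) complex
                lo = rca_res.project(cs.sb_lower[:, j, :])
                hi = rca_res.project(cs.sb_upper[:, j, :])
                nf_levels.append(0.5 * (np.abs(lo) + np.abs(hi)))
                by_cond.setdefault(cs.condition_label, {}).setdefault(cs.participant, []).append(sig)
            floor = noise_floor(np.stack(nf_levels), axis=0)  # per bin, all conditions pooled

            cond_part: dict[str, np.ndarray] = {}
            rows = []
            for label, parts in by_cond.items():
                pids = sorted(parts)
                mat = np.stack([np.mean(np.stack(parts[pid]), axis=0) for pid in pids])
                cond_part[label] = mat
                for k in range(mat.shape[1]):
                    gv = vector_average(mat[:, k])
                    rows.append(
                        {"condition": label, "harmonic": config.harmonic, "bin": k,
                         "re": gv.mean.real, "im": gv.mean.imag, "amplitude": gv.amplitude,
                         "sem": gv.sem, "n": gv.n, "noise_floor": floor[k]}
                    )
                gv = vector_average(mat.mean(axis=1))
                rows.append(
                    {"condition": label, "harmonic": config.harmonic, "bin": "average",
                     "re": gv.mean.real, "im": gv.mean.imag, "amplitude": gv.amplitude,
                     "sem": gv.sem, "n": gv.n, "noise_floor": float(floor.mean())}
                )
            group_df = pd.DataFrame(rows)
            h1 = _write_csv(group_df, outdir / "group_vectors.csv", chash)

            comp_frames = []
            labels = sorted(cond_part)
            for i in range(len(labels)):
                for k in range(i + 1, len(labels)):
                    a, b = labels[i], labels[k]
                    if cond_part[a].shape == cond_part[b].shape:
                        comp_frames.append(comparison_table(cond_part[a], cond_part[b], a, b))
            comp_df = (
                pd.concat(comp_frames, ignore_index=True) if comp_frames else pd.DataFrame()
            )
            h2 = _write_csv(comp_df, outdir / "comparisons.csv", chash)
            manifest.record("stats", {"group_vectors.csv": h1, "comparisons.csv": h2}, t0)
            state["group"] = group_df
            state["cond_part"] = cond_part
            if stop_idx < 5:
                raise _Stop

            # --- fit --------------------------------------------------------
            t0 = time.time()
            from .protocol import make_sweep_grid

            grid = make_sweep_grid(protocol)
            fit_rows = []
            fits = {}
            for label in labels:
                sub = group_df[(group_df["condition"] == label) & (group_df["bin"] != "average")]
                amps = sub.sort_values("bin")["amplitude"].to_numpy(dtype=float)
                sems = sub.sort_values("bin")["sem"].to_numpy(dtype=float)
                w = np.where(sems > 0, 1.0 / np.maximum(sems, 1e-12), 1.0)
                res = fit_nr(grid, amps, w)
                fits[label] = res
                fit_rows.append(
                    {"condition": label, "harmonic": config.harmonic,
                     **res.params.to_dict(), "rss": res.rss,
                     "converged": res.converged, "degenerate": res.degenerate}
                )
            fit_df = pd.DataFrame(fit_rows)
            sup_rows = []
            for a in labels:
                for b in labels:
                    if "in_phase" in a and "anti_phase" in b and a.replace("in_phase", "anti_phase") == b:
                        try:
                            idx = suppression_index(fits[a], fits[b])
                            sup_rows.append({"in_phase": a, "anti_phase": b,
                                             "suppression_index": idx})
                        except ValueError as e:
                            manifest.warnings.append(f"suppression index {a}/{b}: {e}")
            h1 = _write_csv(fit_df, outdir / "nr_fits.csv", chash)
            h2 = _write_csv(pd.DataFrame(sup_rows), outdir / "suppression.csv", chash)
            manifest.record("fit", {"nr_fits.csv": h1, "suppression.csv": h2}, t0)
            manifest.completed = True
            for w in wlist:
                manifest.warnings.append(str(w.message))
    except _Stop:
        manifest.completed = True
    except Exception as e:  # stage failure: record partial state
        manifest.warnings.append(f"stage failure: {type(e).__name__}: {e}")
        manifest.completed = False
    manifest.save(outdir / "manifest.json")
    return manifest


class _Stop(Exception):
    """Internal: clean early exit after the requested stage."""
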