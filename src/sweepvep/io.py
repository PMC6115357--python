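"""Recording I/O: EDF export/import and a numpy array container.

EDF (European Data Format) is the standard open exchange format for
multichannel EEG; files written here carry one trial each with channel
labels E1..E128 and 16-bit samples over a configurable physical range
(default +/- 500 uV, which sets the quantization step).  The writer emits
the format directly (plain ASCII header plus little-endian int16 records);
reading goes through :func:`mne.io.read_raw_edf`, which doubles as an
independent check of the files we produce.

The array container is a ``.npz`` holding the raw samples bit-exactly with
a JSON sidecar carrying the condition, protocol, seed and planted ground
truth, for lossless intermediate storage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .montage import MontageSpec, make_montage
from .nakarushton import NakaRushtonParams
from .protocol import ConditionSpec, SweepProtocol
from .synth import GroundTruthResponse, HarmonicTruth, SyntheticRecording

__all__ = ["write_edf", "read_edf", "save_recording", "load_recording"]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: SyntheticRecording, path, physical_range: float = 500.0) -> None:
    """Write one trial as an EDF file (one 1-s data record per sweep bin)."""
    path = Path(path)
    x = rec.samples
    n_ch, n_s = x.shape
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    if n_s % spr != 0:
        raise ValueError("trial length must be a whole number of seconds")
    n_rec = n_s // spr

    pmin, pmax = -physical_range, physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((np.clip(x, pmin, pmax) - pmin) * scale + dmin).astype("<i2")

    header = b""
    header += _pad("0", 8)
    header += _pad(f"participant {rec.participant}", 80)
    header += _pad(f"trial {rec.trial} condition {rec.condition.label}", 80)
    header += _pad("01.01.01", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + n_ch)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(n_ch), 4)
    labels = rec.montage.labels
    header += b"".join(_pad(lab, 16) for lab in labels)
    header += b"".join(_pad("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(_pad("uV", 8) for _ in labels)
    header += b"".join(_pad(f"{pmin:g}", 8) for _ in labels)
    header += b"".join(_pad(f"{pmax:g}", 8) for _ in labels)
    header += b"".join(_pad(str(dmin), 8) for _ in labels)
    header += b"".join(_pad(str(dmax), 8) for _ in labels)
    header += b"".join(_pad("", 80) for _ in labels)
    header += b"".join(_pad(str(spr), 8) for _ in labels)
    header += b"".join(_pad("", 32) for _ in labels)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_rec):
            f.write(dig[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via mne; returns (samples in uV, fs, channel labels)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def _truth_to_dict(truth: GroundTruthResponse) -> dict:
    return {
        "condition": truth.condition.to_dict(),
        "components": {
            str(h): {"params": c.params.to_dict(), "phase": c.phase}
            for h, c in truth.components.items()
        },
    }


def save_recording(rec: SyntheticRecording, stem) -> tuple[Path, Path]:
    """Write ``<stem>.npz`` (samples, topographies, montage positions,
    validity-free raw data) and ``<stem>.json`` (condition, protocol, seed,
    planted parameters).  The npz round-trips bit-identically."""
    stem = Path(stem)
    npz_path = stem.with_suffix(".npz")
    json_path = stem.with_suffix(".json")
    topo = {
        f"topography_{h}": c.topography for h, c in rec.ground_truth.components.items()
    }
    np.savez(npz_path, samples=rec.samples, positions=rec.montage.positions, **topo)
    sidecar = {
        "format": "sweepvep-recording-v1",
        "fs": rec.fs,
        "condition": rec.condition.to_dict(),
        "protocol": rec.protocol.to_dict(),
        "seed": int(rec.seed),
        "participant": rec.participant,
        "trial": int(rec.trial),
        "labels": list(rec.montage.labels),
        "ground_truth": _truth_to_dict(rec.ground_truth),
        "artifact_ledger": rec.artifact_ledger.entries if rec.artifact_ledger else None,
    }
    with open(json_path, "w") as f:
        json.dump(sidecar, f)
    return npz_path, json_path


def load_recording(stem) -> SyntheticRecording:
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as f:
        meta = json.load(f)
    if meta.get("format") != "sweepvep-recording-v1":
        raise ValueError("not a sweepvep recording sidecar")
    arrays = np.load(stem.with_suffix(".npz"))
    cond = ConditionSpec.from_dict(meta["condition"])
    protocol = SweepProtocol.from_dict(meta["protocol"])
    positions = arrays["positions"]
    from .montage import _knn_neighbors

    montage = MontageSpec(
        labels=tuple(meta["labels"]), positions=positions, neighbors=_knn_neighbors(positions)
    )
    comps = {}
    for h_str, c in meta["ground_truth"]["components"].items():
        h = int(h_str)
        comps[h] = HarmonicTruth(
            params=NakaRushtonParams.from_dict(c["params"]),
            phase=c["phase"],
            topography=arrays[f"topography_{h}"],
        )
    truth = GroundTruthResponse(components=comps, condition=cond)
    ledger = None
    if meta.get("artifact_ledger"):
        from .synth import ArtifactLedger

        ledger = ArtifactLedger(entries=meta["artifact_ledger"])
    return SyntheticRecording(
        samples=arrays["samples"],
        fs=meta["fs"],
        protocol=protocol,
        condition=cond,
        montage=montage,
        ground_truth=truth,
        seed=meta["seed"],
        participant=meta["participant"],
        trial=meta["trial"],
        artifact_ledger=ledger,
    )
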