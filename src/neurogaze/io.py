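"""On-disk formats: cohort CSV, montage TSV, recordings, gaze CSV, configs.

Recordings are stored as a flat little-endian float32 binary (channels ×
samples, row-major) next to a JSON sidecar holding labels, sampling rate,
condition and impedances — a deliberately transparent format that any tool
can read.  Everything else is plain CSV/TSV/JSON/YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage
from .preprocess import Recording
from .synth import SubjectRecord, GazeRecording, CohortSpec, GroupParams

__all__ = [
    "write_cohort_csv", "read_cohort_csv", "write_montage_tsv",
    "read_montage_tsv", "write_recording", "read_recording",
    "write_gaze_csv", "read_gaze_csv", "write_config_yaml",
    "read_config_yaml",
]


def write_cohort_csv(cohort, path) -> None:
    """Cohort table: subject_id, group, pc1_score, ground-truth parameters."""
    pd.DataFrame([dataclasses.asdict(s) for s in cohort]).to_csv(path, index=False)


def read_cohort_csv(path) -> list:
    df = pd.read_csv(path)
    return [SubjectRecord(**{k: row[k] for k in
                             SubjectRecord.__dataclass_fields__})
            for _, row in df.iterrows()]


def write_montage_tsv(montage: Montage, path) -> None:
    """Montage table: label, x, y, z, region (adjacency is recomputed on read)."""
    df = pd.DataFrame({
        "label": montage.labels,
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
        "z": montage.positions[:, 2],
        "region": montage.regions,
    })
    df.to_csv(path, sep="\t", index=False)


def read_montage_tsv(path, max_angle_deg: float = 30.0) -> Montage:
    from .montage import delaunay_adjacency
    df = pd.read_csv(path, sep="\t")
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels=tuple(df["label"]), positions=pos,
                   regions=tuple(df["region"]),
                   adjacency=delaunay_adjacency(pos, max_angle_deg))


def write_recording(rec: Recording, stem) -> None:
    """Write ``<stem>.bin`` (float32 channels × samples) + ``<stem>.json``."""
    stem = Path(stem)
    rec.data.astype("<f4").tofile(stem.with_suffix(".bin"))
    meta = {
        "labels": list(rec.labels),
        "fs": rec.fs,
        "condition": rec.condition,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "<f4",
        "order": "C (channels x samples)",
        "units": "uV",
        "impedances_kohm": (None if rec.impedances is None
                            else np.asarray(rec.impedances, dtype=float).tolist()),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(stem) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype="<f4").reshape(
        meta["n_channels"], meta["n_samples"])
    imp = meta.get("impedances_kohm")
    return Recording(data=data, fs=float(meta["fs"]), labels=tuple(meta["labels"]),
                     condition=meta.get("condition", "eyes_open"),
                     impedances=None if imp is None else np.asarray(imp))


def write_gaze_csv(gaze: GazeRecording, path) -> None:
    """Gaze trace: time_s, velocity_deg_s, true_state."""
    t = np.arange(len(gaze.velocity)) / gaze.fs_gaze
    pd.DataFrame({"time_s": t, "velocity_deg_s": gaze.velocity,
                  "true_state": gaze.true_state}).to_csv(path, index=False)


def read_gaze_csv(path) -> GazeRecording:
    df = pd.read_csv(path)
    fs = 1.0 / float(np.median(np.diff(df["time_s"])))
    return GazeRecording(velocity=df["velocity_deg_s"].to_numpy(float),
                         true_state=df["true_state"].to_numpy(np.int8),
                         fs_gaze=round(fs, 6))


def _plain(obj):
    """Recursively convert numpy scalars/arrays to builtin types for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["group_params"] = {g: dataclasses.asdict(p)
                         for g, p in spec.group_params.items()}
    return _plain(d)


def write_config_yaml(spec: CohortSpec, path, extra: dict = None) -> None:
    """All generation parameters in one YAML document with a top-level seed."""
    doc = {"seed": spec.seed, "cohort": _spec_to_dict(spec)}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config_yaml(path) -> CohortSpec:
    doc = yaml.safe_load(Path(path).read_text())
    c = dict(doc["cohort"])
    c["group_params"] = {g: GroupParams(**{k: tuple(v) for k, v in p.items()})
                         for g, p in c["group_params"].items()}
    c["seed"] = doc.get("seed", c.get("seed", 0))
    return CohortSpec(**c)
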