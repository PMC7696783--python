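"""On-disk dataset tree: one subdirectory per subject plus a manifest.

Layout (a file-based stand-in for the instrument's subject database):

    <root>/manifest.csv              subject_id, label, path
    <root>/<subject_id>/signal.csv   t_s, s01, ..., s14 (one row per sample)
    <root>/<subject_id>/meta.json    subject_id, label, age, sex, ...

Floats in signal.csv are written at %.17g precision so a write/load round
trip reproduces the recording bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DatasetError
from .simulate import LABELS, SensorRecording, SubjectRecord

MANIFEST_NAME = "manifest.csv"
SIGNAL_NAME = "signal.csv"
META_NAME = "meta.json"


def _sensor_columns(n_sensors: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n_sensors)]


def write_dataset(records: Sequence[SubjectRecord], root: str | Path) -> Path:
    """Write the subject tree and manifest; returns the manifest path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        sub = root / rec.subject_id
        sub.mkdir(parents=True, exist_ok=True)
        sig = rec.recording
        frame = pd.DataFrame(
            sig.samples.T, columns=_sensor_columns(sig.n_sensors))
        frame.insert(0, "t_s", np.arange(sig.n_timepoints) / sig.sampling_rate)
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(sub / SIGNAL_NAME, index=False, float_format="%.17g")
        meta = {"subject_id": rec.subject_id, "label": rec.label,
                "sampling_rate_hz": sig.sampling_rate, **rec.metadata}
        (sub / META_NAME).write_text(json.dumps(meta, indent=1, sort_keys=True))
        rows.append({"subject_id": rec.subject_id, "label": rec.label,
                     "path": rec.subject_id})
    manifest = root / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(root: str | Path) -> pd.DataFrame:
    root = Path(root)
    path = root / MANIFEST_NAME
    if not path.exists():
        raise DatasetError(f"missing manifest: {path}")
    manifest = pd.read_csv(path)
    required = {"subject_id", "label", "path"}
    if not required.issubset(manifest.columns):
        raise DatasetError(
            f"manifest must have columns {sorted(required)}")
    dup = manifest["subject_id"][manifest["subject_id"].duplicated()]
    if not dup.empty:
        raise DatasetError(
            f"duplicate subject ids in manifest: {sorted(set(dup))}")
    for _, row in manifest.iterrows():
        if not (root / str(row["path"])).is_dir():
            raise DatasetError(
                f"subject {row['subject_id']}: directory "
                f"{row['path']!r} not found under {root}")
    return manifest


def load_dataset(root: str | Path) -> list[SubjectRecord]:
    """Load every subject listed in the manifest, with shape/label checks."""
    root = Path(root)
    manifest = load_manifest(root)
    records: list[SubjectRecord] = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        sub = root / str(row["path"])
        try:
            meta = json.loads((sub / META_NAME).read_text())
            frame = pd.read_csv(sub / SIGNAL_NAME,
                                float_precision="round_trip")
        except (OSError, ValueError) as exc:
            raise DatasetError(f"subject {sid}: unreadable files: {exc}")
        label = str(row["label"])
        if label not in LABELS:
            raise DatasetError(f"subject {sid}: unknown label {label!r}")
        if meta.get("label") != label:
            raise DatasetError(
                f"subject {sid}: manifest label {label!r} does not match "
                f"meta.json label {meta.get('label')!r}")
        sensor_cols = [c for c in frame.columns if c.startswith("s")
                       and c != "subject_id"]
        if not sensor_cols or len(frame) == 0:
            raise DatasetError(f"subject {sid}: empty or channel-less signal")
        samples = frame[sensor_cols].to_numpy(dtype=float).T
        if not np.all(np.isfinite(samples)):
            raise DatasetError(f"subject {sid}: non-finite samples")
        rate = float(meta.get("sampling_rate_hz", 50.0))
        recording = SensorRecording(subject_id=sid, label=label,
                                    samples=samples, sampling_rate=rate)
        metadata = {k: v for k, v in meta.items()
                    if k not in ("subject_id", "label", "sampling_rate_hz")}
        records.append(SubjectRecord(subject_id=sid, label=label,
                                     metadata=metadata, recording=recording))
    return records


def features_to_frame(features) -> pd.DataFrame:
    """Tidy table: subject_id, label, f001...fNNN."""
    n = features[0].values.size
    cols = [f"f{i + 1:03d}" for i in range(n)]
    data = {"subject_id": [f.subject_id for f in features],
            "label": [f.label for f in features]}
    mat = np.stack([f.values for f in features])
    for j, c in enumerate(cols):
        data[c] = mat[:, j]
    return pd.DataFrame(data)
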