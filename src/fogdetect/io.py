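"""Plain-text cohort layout: per-task CSV signal files + JSON manifests.

Layout written by :func:`write_cohort` (and read back by :func:`read_cohort`)::

    <root>/annotations.csv            subject_id,task_id,start_s,end_s
    <root>/<subject>/<task>/manifest.json
    <root>/<subject>/<task>/<modality>.csv   one column per channel

The manifest records channel names, sampling rate and units per modality and
whether the directory holds raw or processed (500 Hz) signals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AnnotationSet, Episode, ModalityData, Recording

RAW_UNITS = {
    "tibia_acc": "g", "tibia_gyro": "dps", "wrist_acc": "g",
    "wrist_gyro": "dps", "eeg": "uV", "sc": "Mohm",
}
PROCESSED_UNITS = {
    "tibia_acc": "z-score", "tibia_gyro": "z-score", "wrist_acc": "z-score",
    "wrist_gyro": "z-score", "eeg": "z-score", "sc": "uS",
}


def write_annotations(annotations: AnnotationSet, path: Path) -> None:
    rows = [
        {"subject_id": e.subject_id, "task_id": e.task_id,
         "start_s": e.start_s, "end_s": e.end_s}
        for e in annotations.episodes
    ]
    pd.DataFrame(rows, columns=["subject_id", "task_id", "start_s", "end_s"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_annotations(path: Path) -> AnnotationSet:
    df = pd.read_csv(path)
    return AnnotationSet(
        [
            Episode(str(r.subject_id), str(r.task_id), float(r.start_s),
                    float(r.end_s))
            for r in df.itertuples()
        ]
    )


def write_cohort(
    recordings: list[Recording],
    annotations: AnnotationSet,
    root: str | Path,
    processed: bool = False,
) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_annotations(annotations, root / "annotations.csv")
    units = PROCESSED_UNITS if processed else RAW_UNITS
    for rec in recordings:
        task_dir = root / rec.subject_id / rec.task_id
        task_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"processed": processed, "modalities": {}}
        for name, mod in rec.modalities.items():
            manifest["modalities"][name] = {
                "channels": list(mod.channel_names),
                "fs": mod.fs,
                "units": units.get(name, "a.u."),
            }
            pd.DataFrame(mod.samples.T, columns=mod.channel_names).to_csv(
                task_dir / f"{name}.csv", index=False, float_format="%.9g"
            )
        with open(task_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return root


def read_cohort(root: str | Path) -> tuple[list[Recording], AnnotationSet]:
    root = Path(root)
    annotations = read_annotations(root / "annotations.csv")
    recordings: list[Recording] = []
    for manifest_path in sorted(root.glob("*/*/manifest.json")):
        task_dir = manifest_path.parent
        subject_id, task_id = task_dir.parent.name, task_dir.name
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        modalities = {}
        for name, meta in manifest["modalities"].items():
            df = pd.read_csv(task_dir / f"{name}.csv")
            modalities[name] = ModalityData(
                list(meta["channels"]), float(meta["fs"]),
                df.to_numpy(dtype=float).T,
            )
        recordings.append(Recording(subject_id, task_id, modalities))
    return recordings, annotations


def write_windows(windows, path: Path) -> None:
    rows = [
        {"subject_id": w.subject_id, "task_id": w.task_id,
         "start_s": w.start_s, "end_s": w.end_s, "label": w.label}
        for w in windows.windows
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "task_id", "start_s", "end_s", "label"]
    ).to_csv(path, index=False, float_format="%.4f")


def write_json(obj: dict, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)


__all__ = [
    "write_annotations",
    "read_annotations",
    "write_cohort",
    "read_cohort",
    "write_windows",
    "write_json",
]
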