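"""Dataset and artifact I/O: 16-bit PCM mono WAV segments, CSV manifests,
JSON configs/metrics."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DataError
from .simulator import AcousticSegment, LabeledDataset

__all__ = ["write_wav", "read_wav", "write_dataset", "load_dataset",
           "write_json", "read_json"]

_PCM_FULL_SCALE = 32767


def write_wav(path, segment: AcousticSegment):
    """Write one segment as RIFF 16-bit PCM mono.  Samples are expected in
    [-1, 1] (the simulator's peak normalization); values are scaled to
    full-scale int16."""
    x = np.asarray(segment.samples, dtype=float)
    if np.max(np.abs(x)) > 1.0 + 1e-9:
        raise DataError("samples exceed [-1, 1]; normalize before writing")
    pcm = np.round(np.clip(x, -1.0, 1.0) * _PCM_FULL_SCALE).astype(np.int16)
    wavfile.write(str(path), int(segment.fs), pcm)


def read_wav(path, label_ug: Optional[float] = None,
             seed: Optional[int] = None) -> AcousticSegment:
    fs, pcm = wavfile.read(str(path))
    if pcm.ndim != 1:
        raise DataError(f"{path}: expected mono audio")
    x = pcm.astype(float) / _PCM_FULL_SCALE
    return AcousticSegment(samples=x, fs=float(fs),
                           duration=len(x) / float(fs),
                           label_ug=label_ug, seed=seed)


def write_dataset(ds: LabeledDataset, outdir) -> Path:
    """Write WAV files plus a ``manifest.csv`` with columns
    path, label_ug, split, seed.  Returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "wav").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, seg in enumerate(ds.segments):
        rel = f"wav/seg_{i:06d}.wav"
        write_wav(outdir / rel, seg)
        rows.append({
            "path": rel,
            "label_ug": float(ds.labels[i]),
            "split": "" if ds.split is None else ds.split[i],
            "seed": -1 if seg.seed is None else int(seg.seed),
        })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(outdir / "classes.json", "w") as fh:
        json.dump({"classes": [float(c) for c in ds.classes],
                   "seed": int(ds.seed)}, fh)
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    table = pd.read_csv(manifest_path, keep_default_na=False)
    segments: List[AcousticSegment] = []
    for _, row in table.iterrows():
        seed = int(row["seed"])
        segments.append(read_wav(root / row["path"],
                                 label_ug=float(row["label_ug"]),
                                 seed=None if seed < 0 else seed))
    labels = table["label_ug"].to_numpy(dtype=float)
    meta_path = root / "classes.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        classes, seed = meta["classes"], meta["seed"]
    else:
        classes, seed = sorted(set(labels.tolist())), 0
    split = None
    if "split" in table and (table["split"].astype(str) != "").all():
        split = table["split"].astype(str).to_numpy()
    return LabeledDataset(segments=segments, labels=labels, classes=classes,
                          seed=seed, split=split)


def write_json(path, obj: dict):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
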