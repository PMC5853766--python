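"""WAV and sidecar I/O.

Recordings travel as mono WAV files (16-bit PCM or 32-bit float) with an
optional JSON annotation sidecar (``<stem>.annotation.json``) carrying the
ground-truth S1/S2 times and label. Datasets are described by a manifest
CSV (path, label, seed, and the generating config fields).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import Annotation, PCGRecording
from .errors import FormatError
from .simulate import SimulationConfig

__all__ = ["read_wav", "write_wav", "read_annotation", "write_annotation",
           "write_dataset", "read_manifest", "save_features", "load_features"]

logger = logging.getLogger(__name__)

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
              np.dtype(np.uint8): 2**7}


def annotation_path(wav_path) -> Path:
    p = Path(wav_path)
    return p.with_name(p.stem + ".annotation.json")


def read_wav(path) -> PCGRecording:
    """Load a WAV file as a PCGRecording scaled to [-1, 1].

    Stereo files keep the first channel (with a warning); an annotation
    sidecar next to the file is attached when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:
        raise FormatError(f"could not read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        logger.warning("%s has %d channels; keeping the first", path.name, data.shape[1])
        data = data[:, 0]
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.uint8:
            data = data.astype(np.float64) - 128.0
        samples = np.asarray(data, dtype=np.float64) / scale
    elif np.issubdtype(data.dtype, np.floating):
        samples = np.asarray(data, dtype=np.float64)
    else:
        raise FormatError(f"unsupported WAV encoding {data.dtype} in {path}")
    samples = np.clip(samples, -1.0, 1.0)
    ann = None
    sidecar = annotation_path(path)
    if sidecar.exists():
        ann = read_annotation(sidecar)
    return PCGRecording(samples=samples, sample_rate_hz=float(rate),
                        annotation=ann, source_id=path.stem)


def write_wav(path, rec: PCGRecording, dtype: str = "float32",
              with_annotation: bool = True) -> None:
    """Write a recording as mono WAV (float32 by default, or 16-bit PCM)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "float32":
        wavfile.write(path, int(rec.sample_rate_hz), rec.samples.astype(np.float32))
    elif dtype == "int16":
        pcm = np.clip(np.round(rec.samples * (2**15 - 1)), -(2**15), 2**15 - 1)
        wavfile.write(path, int(rec.sample_rate_hz), pcm.astype(np.int16))
    else:
        raise FormatError(f"unsupported output dtype {dtype!r}")
    if with_annotation and rec.annotation is not None:
        write_annotation(annotation_path(path), rec.annotation)


def read_annotation(path) -> Annotation:
    path = Path(path)
    try:
        return Annotation.from_dict(json.loads(path.read_text()))
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise FormatError(f"bad annotation sidecar {path}: {exc}") from exc


def write_annotation(path, ann: Annotation) -> None:
    Path(path).write_text(json.dumps(ann.to_dict(), indent=1))


def write_dataset(recordings: list[PCGRecording], out_dir,
                  dtype: str = "float32") -> Path:
    """Write recordings + sidecars + a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        name = f"rec{i:04d}.wav"
        write_wav(out_dir / name, rec, dtype=dtype)
        cfg = rec.meta.get("config")
        row = {"path": name,
               "label": rec.annotation.label.value if rec.annotation else "",
               "source_id": rec.source_id}
        if isinstance(cfg, SimulationConfig):
            row.update(seed=cfg.seed, heart_rate_bpm=cfg.heart_rate_bpm,
                       duration_s=cfg.duration_s, sample_rate_hz=cfg.sample_rate_hz,
                       af_mode=cfg.af_mode, murmur_intensity=cfg.murmur_intensity,
                       snr_db=cfg.snr_db)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def save_features(path, features, recording_ids, labels) -> None:
    """Store cycle features as one dense archive plus a manifest CSV.

    ``features`` is a flat list of SpectrogramFeature; ``recording_ids``
    and ``labels`` align with it. The manifest lands next to the archive
    as ``<stem>.manifest.csv`` with (recording_id, cycle_index, label).
    """
    from .features import SpectrogramFeature  # local import to avoid a cycle

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if not (len(features) == len(recording_ids) == len(labels)):
        raise FormatError("features, recording_ids and labels must align")
    mats = np.stack([f.matrix if isinstance(f, SpectrogramFeature) else np.asarray(f)
                     for f in features])
    np.savez_compressed(path, matrices=mats)
    pd.DataFrame({
        "recording_id": list(recording_ids),
        "cycle_index": [getattr(f, "cycle_index", i) for i, f in enumerate(features)],
        "label": [str(l) for l in labels],
    }).to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_features(path):
    """Load a feature archive; returns (matrices, manifest DataFrame)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such feature archive: {path}")
    with np.load(path) as z:
        mats = z["matrices"]
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    if len(manifest) != len(mats):
        raise FormatError(f"manifest/archive length mismatch for {path}")
    return mats, manifest


def read_manifest(manifest_path) -> list[PCGRecording]:
    """Load every recording listed in a dataset manifest CSV."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"no such manifest: {manifest_path}")
    df = pd.read_csv(manifest_path)
    if "path" not in df.columns:
        raise FormatError(f"manifest {manifest_path} lacks a 'path' column")
    return [read_wav(manifest_path.parent / p) for p in df["path"]]
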