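"""File interchange: mono WAV, tab-separated ROI annotations, dataset manifests.

ROI files are plain text, one ``start_s<TAB>end_s<TAB>class_id`` line per
interval, one file per recording.  The manifest is a CSV with columns
``path,class_id,duration_s`` indexing a directory of WAV/ROI pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import AudioRecording

__all__ = [
    "write_wav", "read_wav", "write_rois", "read_rois",
    "save_dataset", "load_dataset", "write_features_csv",
]


def write_wav(path: str | Path, recording: AudioRecording,
              pcm16: bool = False) -> None:
    """Write a mono WAV (float32 by default, RIFF PCM 16-bit if ``pcm16``)."""
    x = np.clip(recording.samples, -1.0, 1.0)
    if pcm16:
        wavfile.write(path, recording.sample_rate,
                      (x * 32767.0).round().astype(np.int16))
    else:
        wavfile.write(path, recording.sample_rate, x.astype(np.float32))


def read_wav(path: str | Path, class_label: int | None = None,
             rois: list[tuple[float, float]] | None = None) -> AudioRecording:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    else:
        samples = data.astype(float)
    return AudioRecording(samples=samples, sample_rate=int(fs),
                          class_label=class_label, rois=rois or [])


def write_rois(path: str | Path, recording: AudioRecording) -> None:
    label = recording.class_label if recording.class_label is not None else 0
    with open(path, "w") as fh:
        for s, e in recording.rois:
            fh.write(f"{s:.6f}\t{e:.6f}\t{label}\n")


def read_rois(path: str | Path) -> tuple[list[tuple[float, float]], int | None]:
    """Return (intervals, class_id); class_id is None for an empty file."""
    intervals: list[tuple[float, float]] = []
    label: int | None = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        s, e, cid = line.split("\t")
        intervals.append((float(s), float(e)))
        label = int(cid)
    return intervals, label


def save_dataset(directory: str | Path, recordings: list[AudioRecording],
                 pcm16: bool = False) -> Path:
    """Write WAV + ROI files plus a ``manifest.csv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        stem = f"rec_{i:05d}"
        write_wav(directory / f"{stem}.wav", rec, pcm16=pcm16)
        write_rois(directory / f"{stem}.rois.tsv", rec)
        rows.append({"path": f"{stem}.wav",
                     "class_id": rec.class_label if rec.class_label is not None else 0,
                     "duration_s": rec.duration_s})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest: str | Path) -> list[AudioRecording]:
    manifest = Path(manifest)
    root = manifest.parent
    table = pd.read_csv(manifest)
    recordings = []
    for row in table.itertuples():
        wav_path = root / str(row.path)
        roi_path = wav_path.with_suffix("").with_suffix(".rois.tsv")
        rois, _ = read_rois(roi_path) if roi_path.exists() else ([], None)
        recordings.append(read_wav(wav_path, class_label=int(row.class_id) or None,
                                   rois=rois))
    return recordings


def write_features_csv(path: str | Path, values: np.ndarray,
                       frame_times_s: np.ndarray) -> None:
    """Columnar frame-feature table with header ``t_s,c1..cD``."""
    d = values.shape[1]
    table = pd.DataFrame(values, columns=[f"c{j}" for j in range(1, d + 1)])
    table.insert(0, "t_s", frame_times_s)
    table.to_csv(path, index=False)
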