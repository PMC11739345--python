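"""Reading, writing, and segmenting EEG recordings.

Two on-disk formats are supported: EDF/EDF+ (read-only, via mne) and a
lossless internal "array bundle" -- a raw little-endian float32 array
(``signal.f32``, row-major channels x samples) next to a JSON sidecar
(``meta.json``) holding sampling rate, channel labels, events, and shape.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .containers import EEGRecording, Window, WindowedDataset

__all__ = [
    "FormatError",
    "read_edf",
    "write_bundle",
    "read_bundle",
    "segment_sliding",
    "segment_event_locked",
    "write_dataset",
    "read_dataset",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    Annotations become events at the nearest sample to their onset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed headers
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne loads volts
    fs = float(raw.info["sfreq"])
    events = [
        (int(round(ann["onset"] * fs)), str(ann["description"]))
        for ann in raw.annotations
    ]
    n = data_uv.shape[1]
    events = [(min(i, n - 1), lab) for i, lab in events]
    return EEGRecording(data_uv, fs, list(raw.ch_names), events)


def write_bundle(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a float32 array bundle; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arr = rec.data.astype("<f4")
    (path / "signal.f32").write_bytes(arr.tobytes(order="C"))
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "events": [[int(i), str(lab)] for i, lab in rec.events],
        "shape": list(arr.shape),
        "unit": "uV",
        "dtype": "<f4",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_bundle(path: str | Path) -> EEGRecording:
    """Read an array bundle written by :func:`write_bundle` (bit-exact)."""
    path = Path(path)
    meta_file = path / "meta.json"
    sig_file = path / "signal.f32"
    if not meta_file.exists() or not sig_file.exists():
        raise FormatError(f"{path} is not an array bundle (missing meta/signal)")
    meta = json.loads(meta_file.read_text())
    c, t = (int(x) for x in meta["shape"])
    raw = np.frombuffer(sig_file.read_bytes(), dtype="<f4")
    if raw.size != c * t:
        raise FormatError(
            f"signal.f32 holds {raw.size} samples, sidecar declares {c}x{t}"
        )
    data = raw.reshape(c, t)
    events = [(int(i), str(lab)) for i, lab in meta.get("events", [])]
    return EEGRecording(data, float(meta["fs"]), list(meta["channel_labels"]), events)


def segment_sliding(
    rec: EEGRecording,
    window_s: float,
    step_s: float,
    source_id: str = "rec",
) -> list[Window]:
    """Cut overlapping fixed-length windows.

    Windows are half-open ``[start, start + W)`` starting at 0, step, 2*step,
    ...; a trailing partial window is discarded so every window has the same
    shape.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    w = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    t = rec.n_samples
    if w > t:
        raise ValueError(
            f"window of {w} samples longer than recording ({t} samples)"
        )
    if step < 1:
        raise ValueError("step shorter than one sample")
    n = (t - w) // step + 1
    return [
        Window(rec.data[:, i * step : i * step + w].copy(), source_id, i * step)
        for i in range(n)
    ]


def segment_event_locked(
    rec: EEGRecording,
    post_stimulus_s: float,
    event_filter: set[str] | None = None,
    source_id: str = "rec",
) -> list[Window]:
    """One window per matching event, starting at the event sample.

    Events whose window would run past the end of the recording are skipped.
    An empty result (no matching events) is not an error.
    """
    if post_stimulus_s <= 0:
        raise ValueError("post_stimulus_s must be positive")
    w = int(round(post_stimulus_s * rec.fs))
    out: list[Window] = []
    for idx, label in rec.events:
        if event_filter is not None and label not in event_filter:
            continue
        if idx + w > rec.n_samples:
            continue  # overruns the recording
        out.append(Window(rec.data[:, idx : idx + w].copy(), source_id, idx))
    return out


def write_dataset(ds: WindowedDataset, path: str | Path) -> Path:
    """Write a windowed dataset as one bundle per window plus labels.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["window_id,label"]
    for i, (win, lab) in enumerate(zip(ds.windows, ds.labels)):
        wid = f"w{i:05d}"
        rec = EEGRecording(
            win.data,
            fs=1.0,
            channel_labels=[f"ch{j}" for j in range(win.n_channels)],
        )
        write_bundle(rec, path / wid)
        lines.append(f"{wid},{int(lab)}")
    (path / "labels.csv").write_text("\n".join(lines) + "\n")
    meta = {"K": ds.K, "class_names": ds.class_names}
    (path / "dataset.json").write_text(json.dumps(meta))
    return path


def read_dataset(path: str | Path, fs: float | None = None) -> WindowedDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    labels_file = path / "labels.csv"
    if not labels_file.exists():
        raise FormatError(f"{path} has no labels.csv")
    meta = json.loads((path / "dataset.json").read_text())
    windows, labels = [], []
    for line in labels_file.read_text().splitlines()[1:]:
        wid, lab = line.split(",")
        rec = read_bundle(path / wid)
        windows.append(Window(rec.data, wid, 0))
        labels.append(int(lab))
    return WindowedDataset(windows, np.asarray(labels), int(meta["K"]),
                           list(meta["class_names"]))


def sliding_window_count(t: int, w: int, step: int) -> int:
    """Closed-form count of full windows: floor((T - W)/step) + 1."""
    if w > t:
        return 0
    return math.floor((t - w) / step) + 1
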