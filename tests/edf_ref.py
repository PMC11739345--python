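"""Minimal reference EDF+ writer used to build read-path test fixtures.

Writes one data record per second: each signal's samples as little-endian
int16 plus an EDF+ annotation signal carrying time-stamped annotation lists
(TALs). Only what the fixtures need is implemented; physical scaling is
chosen per channel from the data range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field too long: {text!r} > {width}")
    return b + b" " * (width - len(b))


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: float,
    channel_labels: list[str],
    annotations: list[tuple[float, str]] | None = None,
) -> Path:
    """Write (C, T) microvolt data at integer fs; T must be a multiple of fs.

    ``annotations`` are (onset_seconds, label) pairs.
    """
    path = Path(path)
    data_uv = np.asarray(data_uv, dtype=float)
    c, t = data_uv.shape
    fs = int(fs)
    if t % fs:
        raise ValueError("length must be a whole number of seconds")
    n_records = t // fs
    annotations = annotations or []

    # per-channel physical scaling to int16
    phys_min, phys_max, scaled = [], [], []
    for ch in data_uv:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled.append(
            np.round((ch - lo) / (hi - lo) * 65535 - 32768).astype("<i2")
        )

    ann_bytes_per_record = 64  # room for the timestamp TAL + one annotation
    n_signals = c + 1

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # patient id
    header += _pad("Startdate 01-JAN-2020 X X X", 80)  # recording id
    header += _pad("01.01.20", 8)
    header += _pad("00.00.00", 8)
    header_len = 256 * (1 + n_signals)
    header += _pad(str(header_len), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)  # record duration, seconds
    header += _pad(str(n_signals), 4)

    labels = channel_labels + ["EDF Annotations"]
    transducer = [""] * n_signals
    dims = ["uV"] * c + [""]
    pmins = [f"{v:.6g}"[:8] for v in phys_min] + ["-1"]
    pmaxs = [f"{v:.6g}"[:8] for v in phys_max] + ["1"]
    dmins = ["-32768"] * c + ["-32768"]
    dmaxs = ["32767"] * c + ["32767"]
    prefilter = [""] * n_signals
    samples_per_record = [str(fs)] * c + [str(ann_bytes_per_record // 2)]

    for values, width in [
        (labels, 16), (transducer, 80), (dims, 8), (pmins, 8), (pmaxs, 8),
        (dmins, 8), (dmaxs, 8), (prefilter, 80), (samples_per_record, 8),
    ]:
        for v in values:
            header += _pad(str(v), width)
    header += b" " * (32 * n_signals)  # reserved

    # group annotations by the record whose second they fall in
    per_record: dict[int, list[tuple[float, str]]] = {}
    for onset, label in annotations:
        per_record.setdefault(int(onset), []).append((onset, label))

    body = b""
    for r in range(n_records):
        for ch in scaled:
            body += ch[r * fs : (r + 1) * fs].tobytes()
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for onset, label in per_record.get(r, []):
            tal += f"+{onset:g}\x14{label}\x14\x00".encode("utf-8")
        if len(tal) > ann_bytes_per_record:
            raise ValueError("too many annotations in one record")
        body += tal + b"\x00" * (ann_bytes_per_record - len(tal))

    path.write_bytes(header + body)
    return path
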