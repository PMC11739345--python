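"""In-memory containers for continuous EEG and windowed datasets.

The classification unit throughout the package is a fixed-length window
(channels x samples, microvolts); continuous recordings carry sampling rate,
channel labels, and event markers from which windows are cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording", "Window", "WindowedDataset"]


@dataclass
class EEGRecording:
    """Continuous multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (C, T)
        Signal in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, length C.
    events : list of (int, str)
        (sample_index, label) markers; sample indices are 0-based and must
        lie inside the recording.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        c, t = self.data.shape
        if c < 1 or t < 1:
            raise ValueError("recording must have at least 1 channel and 1 sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != c:
            raise ValueError(
                f"got {len(self.channel_labels)} channel labels for {c} channels"
            )
        if len(set(self.channel_labels)) != c:
            raise ValueError("channel labels must be unique")
        for idx, label in self.events:
            if not 0 <= idx < t:
                raise ValueError(f"event {label!r} at sample {idx} outside [0, {t})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), self.fs, list(self.channel_labels), list(self.events)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EEGRecording):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.channel_labels == other.channel_labels
            and self.events == other.events
            and self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
        )


@dataclass
class Window:
    """Fixed-length segment of a recording (channels x samples, microvolts)."""

    data: np.ndarray
    source_recording: str
    start_sample: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("window data must be (C, W) with W >= 1")
        if self.start_sample < 0:
            raise ValueError("start_sample must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowedDataset:
    """Labelled collection of equally shaped windows.

    Labels are integers in {1..K}; ``class_names[k-1]`` names class ``k``.
    """

    windows: list[Window]
    labels: np.ndarray
    K: int
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.windows):
            raise ValueError("one label per window required")
        if len(self.windows):
            shapes = {w.data.shape for w in self.windows}
            if len(shapes) != 1:
                raise ValueError(f"windows have inconsistent shapes: {shapes}")
            if self.labels.min() < 1 or self.labels.max() > self.K:
                raise ValueError(f"labels must lie in [1, {self.K}]")
        if self.class_names is None:
            self.class_names = [f"class_{k}" for k in range(1, self.K + 1)]
        if len(self.class_names) != self.K:
            raise ValueError("need one class name per class")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def shape(self) -> tuple[int, int]:
        """(C, W) shape shared by every window."""
        return self.windows[0].data.shape

    def stack(self) -> np.ndarray:
        """All windows as one (N, C, W) array."""
        return np.stack([w.data for w in self.windows])

    def subset(self, indices) -> "WindowedDataset":
        indices = np.asarray(indices)
        return WindowedDataset(
            [self.windows[i] for i in indices],
            self.labels[indices],
            self.K,
            list(self.class_names),
        )
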