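"""EEG cleaning chain: band-pass filtering, ICA artifact removal, bad-channel
handling, and per-window normalization.

The chain follows standard EEG practice: a fourth-order Butterworth band-pass
(0.5-50 Hz by default) applied forward-backward for zero phase, ICA with
automated component-rejection criteria (blink template correlation, line-noise
band fraction, high-frequency muscle fraction), SNR-based bad-channel
flagging with neighbor-mean interpolation, and per-channel z-scoring of
windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, Window, WindowedDataset

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "remove_artifacts_ica",
    "flag_bad_channels",
    "interpolate_channels",
    "normalize_windows",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain.

    band_low/band_high bound the pass band in Hz; filter_order is the
    Butterworth design order (applied forward-backward, so the effective
    order doubles). snr_threshold_db flags channels whose in-band vs
    out-of-band power ratio falls below it. line_freq is the mains frequency
    checked by the ICA line-noise criterion.
    """

    band_low: float = 0.5
    band_high: float = 50.0
    filter_order: int = 4
    snr_threshold_db: float = 20.0
    line_freq: float = 50.0
    ica_components: int | str = "auto"
    # automated ICA rejection thresholds (stand-in for manual review)
    blink_corr_threshold: float = 0.7
    line_power_fraction: float = 0.5
    muscle_power_fraction: float = 0.6
    muscle_low_hz: float = 30.0
    frontal_channels: tuple[int, ...] = (0, 1)
    ica_seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")


def _design_bandpass(cfg: PreprocessConfig, fs: float):
    if cfg.band_high >= fs / 2:
        raise ValueError(
            f"band_high={cfg.band_high} Hz is at or above Nyquist for fs={fs} Hz"
        )
    return sps.butter(
        cfg.filter_order,
        [cfg.band_low, cfg.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass_filter(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase Butterworth band-pass, each channel independently."""
    cfg = cfg or PreprocessConfig()
    sos = _design_bandpass(cfg, rec.fs)
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(out, rec.fs, list(rec.channel_labels), list(rec.events))


def _band_power_fraction(source: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Fraction of total Welch power inside [lo, hi] Hz."""
    nper = min(len(source), 512)
    f, p = sps.welch(source, fs=fs, nperseg=nper)
    total = p.sum()
    if total <= 0:
        return 0.0
    mask = (f >= lo) & (f <= hi)
    return float(p[mask].sum() / total)


def _estimate_blink_template(rec: EEGRecording, cfg: PreprocessConfig) -> np.ndarray:
    """Low-frequency (< 5 Hz) mean of the frontal channels, as a blink proxy."""
    idx = [i for i in cfg.frontal_channels if i < rec.n_channels]
    frontal = rec.data[idx].mean(axis=0)
    sos = sps.butter(4, 5.0, btype="lowpass", fs=rec.fs, output="sos")
    return sps.sosfiltfilt(sos, frontal)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def remove_artifacts_ica(
    rec: EEGRecording,
    cfg: PreprocessConfig | None = None,
    templates: list[np.ndarray] | None = None,
) -> tuple[EEGRecording, list[dict]]:
    """ICA decomposition with automated artifact-component rejection.

    Components are rejected when (a) their absolute correlation with a blink
    template (supplied, or estimated as the low-passed frontal mean) exceeds
    ``blink_corr_threshold``; (b) more than ``line_power_fraction`` of their
    power lies within +-1 Hz of ``line_freq``; or (c) more than
    ``muscle_power_fraction`` of their power lies above ``muscle_low_hz``.
    The recording is reconstructed from the retained components.

    Returns the cleaned recording and a list of rejection records
    ``{"component": i, "reason": ..., "score": ...}``. If ICA fails to
    converge, the input is returned unmodified with an empty list.
    """
    cfg = cfg or PreprocessConfig()
    if rec.n_channels < 2:
        raise ValueError("ICA needs at least 2 channels")
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    n_comp = (
        rec.n_channels if cfg.ica_components == "auto" else int(cfg.ica_components)
    )
    x = rec.data.T  # samples x channels
    mean = x.mean(axis=0)
    ica = FastICA(
        n_components=n_comp,
        random_state=cfg.ica_seed,
        max_iter=2000,
        whiten="unit-variance",
    )
    try:
        with warnings.catch_warnings():
            # near-Gaussian background sources stall the fixed-point
            # iteration without invalidating the unmixing estimate, so a
            # convergence warning is logged but the decomposition is kept
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(x)  # samples x comps
    except Exception as exc:
        log.warning("ICA failed (%s); recording left unmodified", exc)
        return rec.copy(), []
    if not np.isfinite(sources).all():
        log.warning("ICA produced non-finite sources; recording left unmodified")
        return rec.copy(), []

    if templates:
        blink_templates = [np.asarray(t, dtype=float) for t in templates]
    else:
        blink_templates = [_estimate_blink_template(rec, cfg)]

    rejected: list[dict] = []
    for i in range(sources.shape[1]):
        s = sources[:, i]
        blink_scores = [abs(_safe_corr(s, t)) for t in blink_templates]
        blink = max(blink_scores) if blink_scores else 0.0
        if blink > cfg.blink_corr_threshold:
            rejected.append({"component": i, "reason": "blink", "score": blink})
            continue
        line = _band_power_fraction(
            s, rec.fs, cfg.line_freq - 1.0, cfg.line_freq + 1.0
        )
        if line > cfg.line_power_fraction:
            rejected.append({"component": i, "reason": "line_noise", "score": line})
            continue
        muscle = _band_power_fraction(s, rec.fs, cfg.muscle_low_hz, rec.fs / 2)
        if muscle > cfg.muscle_power_fraction:
            rejected.append({"component": i, "reason": "muscle", "score": muscle})

    bad = {r["component"] for r in rejected}
    kept = sources.copy()
    for i in bad:
        kept[:, i] = 0.0
    clean = kept @ ica.mixing_.T + mean
    out = EEGRecording(clean.T, rec.fs, list(rec.channel_labels), list(rec.events))
    return out, rejected


def channel_snr_db(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Per-channel SNR estimate: 10*log10(pass-band power / out-of-band power).

    Computed from the raw (pre-filter) signal with Welch spectra; the pass
    band is [band_low, band_high].
    """
    cfg = cfg or PreprocessConfig()
    snrs = np.empty(rec.n_channels)
    nper = min(rec.n_samples, 1024)
    for i in range(rec.n_channels):
        f, p = sps.welch(rec.data[i], fs=rec.fs, nperseg=nper)
        inband = (f >= cfg.band_low) & (f <= cfg.band_high)
        p_in = p[inband].sum()
        p_out = p[~inband].sum()
        if p_out <= 0:
            snrs[i] = np.inf
        elif p_in <= 0:
            snrs[i] = -np.inf
        else:
            snrs[i] = 10.0 * np.log10(p_in / p_out)
    return snrs


def flag_bad_channels(
    rec: EEGRecording, cfg: PreprocessConfig | None = None
) -> list[int]:
    """Channels whose estimated SNR falls below ``snr_threshold_db``."""
    cfg = cfg or PreprocessConfig()
    snrs = channel_snr_db(rec, cfg)
    return [i for i in range(rec.n_channels) if snrs[i] < cfg.snr_threshold_db]


def interpolate_channels(
    rec: EEGRecording,
    bad: list[int],
    neighbor_map: dict[int, list[int]],
) -> EEGRecording:
    """Replace each bad channel by the arithmetic mean of its good neighbors."""
    bad_set = set(bad)
    out = rec.data.copy()
    for ch in bad:
        good = [n for n in neighbor_map.get(ch, []) if n not in bad_set]
        if not good:
            raise ValueError(f"bad channel {ch} has no good neighbors to interpolate from")
        out[ch] = rec.data[good].mean(axis=0)
    return EEGRecording(out, rec.fs, list(rec.channel_labels), list(rec.events))


def normalize_windows(
    ds: WindowedDataset, mode: str = "per-channel-zscore", var_floor: float = 1e-8
) -> WindowedDataset:
    """Per-window, per-channel z-scoring (mean 0, variance 1).

    Constant channels receive a variance floor and come out all-zero (logged).
    """
    if mode != "per-channel-zscore":
        raise ValueError(f"unknown normalization mode {mode!r}")
    windows = []
    for w in ds.windows:
        mu = w.data.mean(axis=1, keepdims=True)
        var = w.data.var(axis=1, keepdims=True)
        flat = var[:, 0] < var_floor
        if flat.any():
            log.warning(
                "window %s: %d constant channel(s), variance floor applied",
                w.source_recording, int(flat.sum()),
            )
        sd = np.sqrt(np.maximum(var, var_floor))
        windows.append(Window((w.data - mu) / sd, w.source_recording, w.start_sample))
    return WindowedDataset(windows, ds.labels.copy(), ds.K, list(ds.class_names))
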