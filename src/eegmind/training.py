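"""Training protocol, augmentation, stratified evaluation, and the
noise-robustness harness.

Optimization uses Adam with a cosine-annealing learning-rate schedule with
warm restarts (initial period 10 epochs, doubling after each restart) and
early stopping when the validation loss has not improved for a fixed number
of consecutive epochs; the checkpoint with the best validation loss is
returned. Splits and cross-validation folds are stratified by class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import WindowedDataset, Window
from .model import EEGMindModel, one_hot
from .synth import add_noise_at_snr

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "EvalReport",
    "stratified_split",
    "stratified_kfold",
    "augment",
    "cosine_warm_restart_lr",
    "train",
    "evaluate",
    "noise_robustness_suite",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol parameters."""

    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 50
    early_stop_patience: int = 10
    warm_restart_period: int = 10
    warm_restart_mult: int = 2
    folds: int = 5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class AugmentConfig:
    """Label-preserving augmentation probabilities and strengths."""

    p_crop: float = 0.0
    crop_fraction: float = 0.9
    p_noise: float = 0.0
    noise_snr_db: float = 20.0
    p_jitter: float = 0.0
    max_jitter: int = 8
    p_warp: float = 0.0
    max_stretch: float = 0.1


def _stratified_assign(
    labels: np.ndarray, fractions: list[float], rng: np.random.Generator
) -> np.ndarray:
    """Assign indices to len(fractions) groups, per class, largest-remainder."""
    out = np.empty(len(labels), dtype=np.int64)
    for k in np.unique(labels):
        idx = np.where(labels == k)[0]
        rng.shuffle(idx)
        n = len(idx)
        quotas = np.array([f * n for f in fractions])
        counts = np.floor(quotas).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(quotas - counts))
        for g in order[:rem]:
            counts[g] += 1
        start = 0
        for g, cnt in enumerate(counts):
            out[idx[start : start + cnt]] = g
            start += cnt
    return out


def stratified_split(
    ds: WindowedDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Disjoint train/val/test subsets with per-class proportions preserved."""
    labels = ds.labels
    for k in range(1, ds.K + 1):
        if (labels == k).sum() < 3:
            raise ValueError(f"class {k} has fewer than 3 windows")
    groups = _stratified_assign(labels, list(fractions), np.random.default_rng(seed))
    return tuple(ds.subset(np.where(groups == g)[0]) for g in range(3))


def stratified_kfold(
    ds: WindowedDataset, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs (train_idx, val_idx)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = ds.labels
    for c in range(1, ds.K + 1):
        if (labels == c).sum() < k:
            raise ValueError(f"class {c} has fewer than {k} windows")
    groups = _stratified_assign(labels, [1.0 / k] * k, np.random.default_rng(seed))
    all_idx = np.arange(len(ds))
    folds = []
    for g in range(k):
        val = all_idx[groups == g]
        train = all_idx[groups != g]
        folds.append((train, val))
    return folds


# -- augmentation -----------------------------------------------------------


def _resample_linear(x: np.ndarray, new_positions: np.ndarray) -> np.ndarray:
    old = np.arange(x.shape[-1])
    return np.stack([np.interp(new_positions, old, ch) for ch in x])


def augment(
    batch: np.ndarray, cfg: AugmentConfig, seed: int = 0
) -> np.ndarray:
    """Apply random crop+resize, SNR-scaled noise, circular jitter, and
    piecewise-linear time-warp, each per sample with its configured
    probability. Deterministic given seed; label-preserving by design."""
    rng = np.random.default_rng(seed)
    x = np.asarray(batch, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    w = x.shape[-1]
    crop_len = int(round(cfg.crop_fraction * w))
    if crop_len > w:
        raise ValueError("crop longer than window")
    out = x.copy()
    for i in range(out.shape[0]):
        if cfg.p_crop > 0 and rng.random() < cfg.p_crop:
            start = rng.integers(0, w - crop_len + 1)
            cropped = out[i][:, start : start + crop_len]
            pos = np.linspace(0, crop_len - 1, w)
            out[i] = _resample_linear(cropped, pos)
        if cfg.p_jitter > 0 and rng.random() < cfg.p_jitter:
            shift = int(rng.integers(-cfg.max_jitter, cfg.max_jitter + 1))
            out[i] = np.roll(out[i], shift, axis=-1)
        if cfg.p_warp > 0 and rng.random() < cfg.p_warp:
            # piecewise-linear remap through a stretched midpoint
            mid = 0.5 + rng.uniform(-cfg.max_stretch, cfg.max_stretch)
            anchor_src = np.array([0.0, mid * (w - 1), w - 1.0])
            anchor_dst = np.array([0.0, 0.5 * (w - 1), w - 1.0])
            pos = np.interp(np.arange(w), anchor_dst, anchor_src)
            out[i] = _resample_linear(out[i], pos)
        if cfg.p_noise > 0 and rng.random() < cfg.p_noise:
            p_sig = np.mean(out[i] ** 2)
            noise = rng.standard_normal(out[i].shape)
            target = p_sig / 10.0 ** (cfg.noise_snr_db / 10.0)
            noise *= np.sqrt(target / np.mean(noise**2))
            out[i] = out[i] + noise
    return out[0] if single else out


# -- optimization -----------------------------------------------------------


def cosine_warm_restart_lr(
    epoch: int, lr0: float, period: int = 10, mult: int = 2, lr_min: float = 0.0
) -> float:
    """Cosine-annealed learning rate with warm restarts (SGDR schedule)."""
    t, p = epoch, period
    while t >= p:
        t -= p
        p *= mult
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + np.cos(np.pi * t / p))


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.params = params
        self.lr = lr
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _connectivity_targets(x: np.ndarray) -> np.ndarray:
    """Per-window rectified Pearson correlation, the alignment target."""
    out = np.empty((x.shape[0], x.shape[1], x.shape[1]))
    for i, w in enumerate(x):
        sd = w.std(axis=1)
        if (sd == 0).any():
            c = np.eye(w.shape[0])
        else:
            c = np.corrcoef(w)
        out[i] = np.abs(c)
    return out


def train(
    model: EEGMindModel,
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    cfg: TrainConfig | None = None,
    augment_cfg: AugmentConfig | None = None,
) -> tuple[EEGMindModel, pd.DataFrame]:
    """Optimize the model; returns the best-validation checkpoint + history.

    History has one row per epoch: lr, train_loss, val_loss, val_accuracy.
    Stops early when validation loss fails to improve for
    ``early_stop_patience`` consecutive epochs; aborts (keeping the last
    finite checkpoint) if the loss diverges to NaN.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    x_train = train_ds.stack()
    y_train = train_ds.labels
    x_val = val_ds.stack()
    y_val = val_ds.labels
    use_align = model.cfg.align_lambda > 0

    opt = _Adam(model.trainable(), cfg.lr)
    best_state = model.get_state()
    best_val = np.inf
    since_best = 0
    rows = []
    for epoch in range(cfg.max_epochs):
        lr = cosine_warm_restart_lr(
            epoch, cfg.lr, cfg.warm_restart_period, cfg.warm_restart_mult
        )
        opt.lr = lr
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            if augment_cfg is not None:
                xb = augment(xb, augment_cfg, seed=int(rng.integers(2**31)))
            target = _connectivity_targets(xb) if use_align else None
            loss = model.loss(xb, y_train[idx], align_target=target)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        train_loss = float(np.mean(epoch_losses))
        val_target = _connectivity_targets(x_val) if use_align else None
        val_loss = float(model.loss(x_val, y_val, align_target=val_target).data)
        val_acc = float(np.mean(model.predict(x_val) == y_val))
        rows.append(
            {"epoch": epoch, "lr": lr, "train_loss": train_loss,
             "val_loss": val_loss, "val_accuracy": val_acc}
        )
        if not np.isfinite(val_loss) or not np.isfinite(train_loss):
            log.warning("loss diverged at epoch %d; keeping last finite checkpoint",
                        epoch)
            break
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                log.info("early stop at epoch %d (patience %d)",
                         epoch, cfg.early_stop_patience)
                break
    model.set_state(best_state)
    return model, pd.DataFrame(rows)


def early_stop_trace(val_losses: list[float], patience: int) -> int:
    """Index of the epoch after which training stops under the patience rule.

    Returns the (0-based) number of epochs actually run: training halts once
    ``patience`` consecutive epochs fail to improve on the best loss so far.
    """
    best = np.inf
    since = 0
    for i, v in enumerate(val_losses):
        if v < best:
            best = v
            since = 0
        else:
            since += 1
            if since >= patience:
                return i + 1
    return len(val_losses)


# -- evaluation -------------------------------------------------------------


@dataclass
class EvalReport:
    """Classification metrics derived from the confusion matrix."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    auc: float | None
    sensitivity: float
    specificity: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1, "auc": self.auc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "confusion": self.confusion.tolist(),
        }


def report_from_confusion(
    confusion: np.ndarray, auc: float | None = None
) -> EvalReport:
    """Macro-averaged metrics from a K x K count matrix (rows = true)."""
    cm = np.asarray(confusion, dtype=float)
    k = cm.shape[0]
    total = cm.sum()
    acc = float(np.trace(cm) / total)
    recalls, precisions, f1s, specs = [], [], [], []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(f1)
        specs.append(spec)
    if k == 2:
        # binary convention: class 2 ("positive") recall is sensitivity
        sensitivity = recalls[1]
        specificity = recalls[0]
    else:
        sensitivity = float(np.mean(recalls))
        specificity = float(np.mean(specs))
    return EvalReport(
        accuracy=acc, recall=float(np.mean(recalls)),
        precision=float(np.mean(precisions)), f1=float(np.mean(f1s)),
        auc=auc, sensitivity=float(sensitivity), specificity=float(specificity),
        confusion=np.asarray(confusion),
    )


def evaluate(model: EEGMindModel, ds: WindowedDataset) -> EvalReport:
    """Accuracy, macro recall/precision/F1, one-vs-rest macro AUC,
    sensitivity/specificity on a labelled dataset."""
    from sklearn.metrics import roc_auc_score

    x = ds.stack()
    y = ds.labels
    proba = model.predict_proba(x)
    pred = np.argmax(proba, axis=-1) + 1
    k = ds.K
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        cm[t - 1, p - 1] += 1
    auc = None
    if len(np.unique(y)) < 2:
        log.warning("single-class evaluation set: AUC undefined")
    else:
        if k == 2:
            auc = float(roc_auc_score(y == 2, proba[:, 1]))
        else:
            auc = float(
                roc_auc_score(y, proba, multi_class="ovr", average="macro")
            )
    return report_from_confusion(cm, auc)


def noise_robustness_suite(
    model: EEGMindModel,
    ds: WindowedDataset,
    tiers: list[float] = (20.0, 10.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate on noise-injected copies at each SNR tier.

    Returns one row per scenario (clean baseline first) with accuracy and
    macro F1, mirroring a noise-robustness results table.
    """
    rows = []
    clean = evaluate(model, ds)
    rows.append({"scenario": "clean", "snr_db": np.inf,
                 "accuracy": clean.accuracy, "f1": clean.f1})
    for i, snr in enumerate(tiers):
        noisy = add_noise_at_snr(ds, snr, seed=seed + i)
        rep = evaluate(model, noisy)
        rows.append({"scenario": f"snr_{snr:g}dB", "snr_db": snr,
                     "accuracy": rep.accuracy, "f1": rep.f1})
    return pd.DataFrame(rows)
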