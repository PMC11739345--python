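"""Spatial-temporal fusion head and the full window classifier.

The classifier concatenates the temporal feature h_t (from the temporal
graph attention stack) with the spatial feature h_s (from the hierarchical
channel graph), passes the pair through one rectified affine fusion layer,
and classifies with a softmax output layer:

    h_f = ReLU(W_f [h_t ; h_s] + b_f),   y_hat = softmax(W_o h_f + b_o)

trained with mean cross-entropy, optionally plus a weighted alignment term
pulling the learned channel adjacency toward measured functional
connectivity.

Ablated variants keep the interface: without the temporal attention stack,
h_t is the mean-pooled patch embedding; without the hierarchy, h_s comes
from a single-level fully connected graph convolution; without the fusion
layer, the head is a sum of separately projected h_t and h_s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dtgam as _dtgam
from . import hgra as _hgra
from .autodiff import Tensor, concat, softmax
from .containers import Window

__all__ = [
    "ModelConfig",
    "EEGMindModel",
    "fuse",
    "classify",
    "cross_entropy",
    "model_forward",
]

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the window classifier."""

    C: int
    W: int
    K: int
    fs: float = 128.0
    d_model: int = 64
    n_heads: int = 4
    patch_s: float = 0.125
    temporal_connectivity: str = "full"
    temporal_conv_layers: int = 1
    spatial_conv_layers: int = 1
    level_spec: list[dict[int, int]] = field(default_factory=list)
    adjacency_source: str = "learned"
    pool_mode: str = "mean"
    aggregate_mode: str = "mean"
    fusion_width: int = 64
    use_dtgam: bool = True
    use_hgra: bool = True
    use_stfm: bool = True
    use_pad: bool = True
    scorer_width: int = 16
    align_lambda: float = 0.0
    seed: int = 0

    @property
    def patch_len(self) -> int:
        return max(1, int(round(self.patch_s * self.fs)))


def fuse(h_t: Tensor, h_s: Tensor, w_f: Tensor, b_f: Tensor) -> Tensor:
    """h_f = ReLU(W_f [h_t ; h_s] + b_f)."""
    h_st = concat([h_t, h_s], axis=-1)
    if h_st.shape[-1] != w_f.shape[0]:
        raise ValueError(
            f"fusion expects width {w_f.shape[0]}, got {h_st.shape[-1]}"
        )
    return (h_st @ w_f + b_f).relu()


def classify(h_f: Tensor, w_o: Tensor, b_o: Tensor) -> Tensor:
    """Softmax class probabilities from the fused feature vector."""
    return softmax(h_f @ w_o + b_o, axis=-1)


def cross_entropy(y_hat: Tensor, y_onehot: np.ndarray, clamp: float = 1e-12) -> Tensor:
    """Mean cross-entropy -(1/N) sum_i sum_k y_ik log y_hat_ik.

    Predicted probabilities are clamped at ``clamp`` before the log (and the
    clamping is logged) so a zero probability on a true class cannot produce
    an infinite loss.
    """
    y = np.asarray(y_onehot, dtype=float)
    if (y_hat.data[y > 0] < clamp).any():
        log.warning("cross_entropy: clamped zero predicted probability")
    # floor through a data-side shift; gradient of floored entries is kept
    floor = Tensor(np.where(y_hat.data < clamp, clamp - y_hat.data, 0.0))
    y_hat = y_hat + floor
    n = y.shape[0] if y.ndim > 1 else 1
    return (y_hat.log() * y).sum() * (-1.0 / n)


def one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    """Labels in {1..K} to one-hot rows."""
    labels = np.asarray(labels)
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


class EEGMindModel:
    """Full graph-attention window classifier with trainable parameters."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.d_model
        self.params: dict[str, Tensor] = {}
        self.params.update(
            {f"t_{k}": v for k, v in _dtgam.init_dtgam_params(
                rng, cfg.C, cfg.patch_len, d_model=d, n_heads=cfg.n_heads,
                conv_layers=cfg.temporal_conv_layers,
            ).items()}
        )
        n_levels = len(cfg.level_spec) + 1
        self.hierarchy = _hgra.build_hierarchy(cfg.C, cfg.level_spec)
        self.params.update(
            {f"s_{k}": v for k, v in _hgra.init_hgra_params(
                rng, cfg.C, cfg.W, d=d, conv_layers=cfg.spatial_conv_layers,
                n_levels=n_levels, scorer_width=cfg.scorer_width,
            ).items()}
        )

        def glorot(*shape):
            lim = np.sqrt(6.0 / (shape[-2] + shape[-1]))
            return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

        f_in, f_out = 2 * d, cfg.fusion_width
        self.params["w_f"] = glorot(f_in, f_out)
        self.params["b_f"] = Tensor(np.zeros(f_out), requires_grad=True)
        self.params["w_o"] = glorot(f_out, cfg.K)
        self.params["b_o"] = Tensor(np.zeros(cfg.K), requires_grad=True)
        # projected-sum head for the no-fusion ablation
        self.params["w_pt"] = glorot(d, f_out)
        self.params["w_ps"] = glorot(d, f_out)

    # -- forward ------------------------------------------------------------

    def _temporal(self, x: np.ndarray) -> Tensor:
        cfg = self.cfg
        t_params = {k[2:]: v for k, v in self.params.items() if k.startswith("t_")}
        if cfg.use_dtgam:
            return _dtgam.dtgam_forward(
                x, t_params, cfg.patch_len, n_heads=cfg.n_heads,
                connectivity=cfg.temporal_connectivity,
            )
        emb = _dtgam.patch_embed(
            x, cfg.patch_len, t_params["patch_w"], t_params["patch_b"]
        )
        return emb.mean(axis=-2)

    def _spatial(self, x: np.ndarray, return_adjacency: bool = False):
        cfg = self.cfg
        s_params = {k[2:]: v for k, v in self.params.items() if k.startswith("s_")}
        if cfg.use_hgra:
            return _hgra.hgra_forward(
                x, s_params, self.hierarchy,
                adjacency_source=cfg.adjacency_source,
                pool_mode=cfg.pool_mode, aggregate_mode=cfg.aggregate_mode,
                use_pad=cfg.use_pad, return_adjacency=return_adjacency,
            )
        # flat ablation: single fully connected level, no hierarchy/PAD
        flat = _hgra.Hierarchy([_hgra.LevelGraph(1, cfg.C, None, None)])
        emb = Tensor(np.asarray(x, dtype=float)) @ s_params["chan_w"] + s_params["chan_b"]
        flat.levels[0].embeddings = emb
        ws = [s_params[k] for k in sorted(s_params) if k.startswith("lvl0_w")]
        h = _hgra.level_graph_conv(flat.levels[0], ws)
        h_s = h.mean(axis=-2)
        if return_adjacency:
            return h_s, None
        return h_s

    def forward(
        self, windows: np.ndarray, return_adjacency: bool = False
    ):
        """Class probabilities for (batch, C, W) or a single (C, W) window."""
        x = np.asarray(windows, dtype=float)
        if x.ndim == 2:
            x = x[None]
            squeeze = True
        else:
            squeeze = False
        if x.shape[-2] != self.cfg.C or x.shape[-1] != self.cfg.W:
            raise ValueError(
                f"expected windows of shape (C={self.cfg.C}, W={self.cfg.W}), "
                f"got {x.shape[-2:]}"
            )
        h_t = self._temporal(x)
        spat = self._spatial(x, return_adjacency=True)
        h_s, learned_adj = spat
        if self.cfg.use_stfm:
            h_f = fuse(h_t, h_s, self.params["w_f"], self.params["b_f"])
        else:
            h_f = (h_t @ self.params["w_pt"] + h_s @ self.params["w_ps"]).relu()
        y_hat = classify(h_f, self.params["w_o"], self.params["b_o"])
        if squeeze:
            y_hat = y_hat.reshape(self.cfg.K)
            if learned_adj is not None and learned_adj.ndim > 2:
                learned_adj = learned_adj.reshape(*learned_adj.shape[-2:])
        if return_adjacency:
            return y_hat, learned_adj
        return y_hat

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.forward(windows).data

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Hard labels in {1..K}."""
        p = self.predict_proba(windows)
        return np.argmax(p, axis=-1) + 1

    def loss(
        self,
        windows: np.ndarray,
        labels: np.ndarray,
        align_target: np.ndarray | None = None,
    ) -> Tensor:
        """Cross-entropy plus the optional weighted alignment term."""
        y_hat, learned = self.forward(windows, return_adjacency=True)
        loss = cross_entropy(y_hat, one_hot(labels, self.cfg.K))
        if self.cfg.align_lambda > 0 and learned is not None and align_target is not None:
            loss = loss + self.cfg.align_lambda * _hgra.alignment_loss(
                align_target, learned
            )
        return loss

    def learned_adjacency(self, windows: np.ndarray) -> np.ndarray | None:
        """Mean learned channel adjacency over the given windows."""
        _, learned = self.forward(windows, return_adjacency=True)
        if learned is None:
            return None
        w = learned.data
        return w.mean(axis=0) if w.ndim > 2 else w

    # -- parameter plumbing --------------------------------------------------

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    def save(self, path: str | Path) -> Path:
        """Checkpoint: one .npy per parameter plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k, v in self.params.items():
            np.save(path / f"{k}.npy", v.data)
        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.cfg.__dict__.items()
            },
            "parameters": sorted(self.params),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EEGMindModel":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["level_spec"] = [
            {int(k): int(v) for k, v in part.items()}
            for part in cfg_dict.get("level_spec", [])
        ]
        cfg = ModelConfig(**cfg_dict)
        model = cls(cfg)
        for k in manifest["parameters"]:
            model.params[k].data = np.load(path / f"{k}.npy")
        return model


def model_forward(window: Window | np.ndarray, model: EEGMindModel) -> np.ndarray:
    """Probability vector for one window (deterministic in eval mode)."""
    data = window.data if isinstance(window, Window) else np.asarray(window)
    return model.predict_proba(data)
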