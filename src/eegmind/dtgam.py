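"""Dynamic temporal graph attention (DT-GAM).

A window is grouped into non-overlapping temporal patches that become the
nodes of a per-window temporal graph. Scaled dot-product attention over the
graph's edge mask yields a row-stochastic attention matrix A_t (averaged
over heads for propagation); temporal graph convolution
H^(l+1) = sigma(A_t H^(l) W^(l)) then refines the node embeddings, and mean
pooling over nodes gives the window's temporal feature vector h_t.

The "dynamic" structure is realized through A_t itself: the edge mask is
fixed (full or banded), while the attention weights on those edges are
input-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "AttentionParams",
    "TemporalGraph",
    "build_temporal_graph",
    "temporal_attention",
    "temporal_graph_conv",
    "patch_embed",
    "dtgam_forward",
    "init_dtgam_params",
]


@dataclass
class AttentionParams:
    """Projection parameters of the temporal attention block.

    d_t is the per-head key/query width and the softmax scaling divisor.
    """

    d_model: int
    n_heads: int
    w_q: Tensor  # (n_heads, d_model, d_t)
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor  # (n_heads*d_t, d_model)

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def d_t(self) -> int:
        return self.w_q.shape[-1]


@dataclass
class TemporalGraph:
    """Per-window temporal graph over patch-level time steps."""

    n_nodes: int
    edge_mask: np.ndarray  # (n, n) boolean
    embeddings: Tensor  # (..., n, d_model)
    attention: Tensor | None = None  # (..., n_heads, n, n) row-stochastic
    attended: Tensor | None = None  # (..., n, d_model)


def banded_mask(n: int, k: int) -> np.ndarray:
    """Boolean mask allowing edges within +-k steps (self-edges included)."""
    if k < 0:
        raise ValueError("band half-width k must be >= 0")
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :]) <= k


def build_temporal_graph(
    window_embedding: Tensor | np.ndarray, connectivity: str = "full"
) -> TemporalGraph:
    """Build a temporal graph from time-major node embeddings.

    ``connectivity`` is ``"full"`` or ``"banded:k"`` for a band limited to
    +-k time steps.
    """
    emb = window_embedding if isinstance(window_embedding, Tensor) else Tensor(window_embedding)
    n = emb.shape[-2]
    if n < 1:
        raise ValueError("need at least one time-step node")
    if connectivity == "full":
        mask = np.ones((n, n), dtype=bool)
    elif connectivity.startswith("banded"):
        k = int(connectivity.split(":")[1]) if ":" in connectivity else 1
        mask = banded_mask(n, k)
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    return TemporalGraph(n_nodes=n, edge_mask=mask, embeddings=emb)


def temporal_attention(g: TemporalGraph, p: AttentionParams) -> TemporalGraph:
    """Masked scaled dot-product attention; fills ``g.attention``/``g.attended``.

    A_t = softmax(Q K^T / sqrt(d_t)) row-wise over unmasked entries; node
    values are A_t V per head, concatenated and mixed back to d_model.
    """
    if not np.isfinite(g.embeddings.data).all():
        raise ValueError("non-finite values in temporal node embeddings")
    h = g.embeddings  # (..., n, d)
    # add a head axis: (..., 1, n, d) @ (H, d, d_t) -> (..., H, n, d_t)
    hh = h.reshape(*h.shape[:-2], 1, *h.shape[-2:])
    q = hh @ p.w_q
    k = hh @ p.w_k
    v = hh @ p.w_v
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(p.d_t))
    att = softmax(scores, axis=-1, mask=g.edge_mask)
    out = att @ v  # (..., H, n, d_t)
    # concat heads: (..., n, H*d_t)
    out = out.swapaxes(-3, -2)
    out = out.reshape(*out.shape[:-2], p.n_heads * p.d_t)
    g.attention = att
    g.attended = out @ p.w_o
    return g


def temporal_graph_conv(
    g: TemporalGraph,
    weights: list[Tensor],
    nonlinearity: str = "relu",
) -> Tensor:
    """Iterate H^(l+1) = sigma(A_t H^(l) W^(l)); returns mean-pooled h_t.

    Propagation uses the head-averaged attention matrix (row-stochastic).
    """
    if not weights:
        raise ValueError("need at least one conv layer")
    if g.attended is None or g.attention is None:
        raise ValueError("run temporal_attention before temporal_graph_conv")
    a = g.attention.mean(axis=-3)  # average heads -> (..., n, n)
    h = g.attended
    for w in weights:
        h = a @ (h @ w)
        if nonlinearity == "relu":
            h = h.relu()
        elif nonlinearity == "identity":
            pass
        else:
            raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    return h.mean(axis=-2)  # mean over nodes


def _glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    fan_in, fan_out = shape[-2], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


def init_dtgam_params(
    rng: np.random.Generator,
    c: int,
    patch_len: int,
    d_model: int = 16,
    n_heads: int = 4,
    conv_layers: int = 1,
) -> dict[str, Tensor]:
    """Initialize patch embedding + attention + conv parameters."""
    d_t = d_model // n_heads
    params = {
        "patch_w": _glorot(rng, c * patch_len, d_model),
        "patch_b": Tensor(np.zeros(d_model), requires_grad=True),
        "w_q": _glorot(rng, n_heads, d_model, d_t),
        "w_k": _glorot(rng, n_heads, d_model, d_t),
        "w_v": _glorot(rng, n_heads, d_model, d_t),
        "w_o": _glorot(rng, n_heads * d_t, d_model),
    }
    for l in range(conv_layers):
        params[f"conv_w{l}"] = _glorot(rng, d_model, d_model)
    return params


def patch_embed(
    windows: np.ndarray, patch_len: int, w: Tensor, b: Tensor
) -> Tensor:
    """Group samples into non-overlapping patches and embed linearly.

    ``windows`` is (..., C, W); trailing samples that do not fill a patch are
    dropped. Returns (..., n_patches, d_model).
    """
    *lead, c, t = windows.shape
    n = t // patch_len
    if n < 1:
        raise ValueError("window shorter than one patch")
    x = windows[..., : n * patch_len].reshape(*lead, c, n, patch_len)
    x = np.moveaxis(x, -3, -2).reshape(*lead, n, c * patch_len)
    return Tensor(x) @ w + b


def dtgam_forward(
    windows: np.ndarray,
    params: dict[str, Tensor],
    patch_len: int,
    n_heads: int = 4,
    connectivity: str = "full",
    nonlinearity: str = "relu",
) -> Tensor:
    """Full DT-GAM pass: patch-embed -> attention -> conv -> h_t.

    ``windows`` is (batch, C, W) or (C, W); returns (batch, d_model) or
    (d_model,).
    """
    emb = patch_embed(windows, patch_len, params["patch_w"], params["patch_b"])
    g = build_temporal_graph(emb, connectivity)
    d_model = params["patch_w"].shape[-1]
    p = AttentionParams(
        d_model=d_model, n_heads=n_heads,
        w_q=params["w_q"], w_k=params["w_k"], w_v=params["w_v"], w_o=params["w_o"],
    )
    g = temporal_attention(g, p)
    conv_ws = [params[k] for k in sorted(params) if k.startswith("conv_w")]
    return temporal_graph_conv(g, conv_ws, nonlinearity)
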