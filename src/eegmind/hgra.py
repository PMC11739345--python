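"""Hierarchical graph representation over channels and regions (HGRA).

Level 1 has one node per EEG channel; higher levels group channels into
regions via user-supplied partitions. Each level runs graph convolutions
with the symmetric-normalized adjacency D^{-1/2}(A+I)D^{-1/2} (self-loops
added so isolated nodes stay well-defined), embeddings are pooled upward
between levels, and a principal aggregation/distribution (PAD) step forms a
global embedding from all levels and adds a transformed copy back to each
level. The top level's mean-pooled embedding is the spatial feature h_s.

The level-1 adjacency can be fully connected, supplied (e.g. functional
connectivity), or learned from node features with a symmetric nonnegative
scorer; the learned adjacency can be regularized toward a measured
connectivity matrix through a squared-Frobenius alignment loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax

__all__ = [
    "LevelGraph",
    "Hierarchy",
    "PADState",
    "build_hierarchy",
    "sym_normalized",
    "level_graph_conv",
    "pool_to_next_level",
    "pad_aggregate",
    "pad_distribute",
    "learn_adjacency",
    "alignment_loss",
    "hgra_forward",
    "init_hgra_params",
]


@dataclass
class LevelGraph:
    """One level of the hierarchy: adjacency, memberships, embeddings."""

    level: int
    n_nodes: int
    adjacency: np.ndarray | None  # (n, n) symmetric nonnegative; None = full
    memberships: np.ndarray | None  # node -> parent id at the next level
    embeddings: Tensor | None = None

    def degree(self) -> np.ndarray:
        a = self.adjacency
        if a is None:
            a = np.ones((self.n_nodes, self.n_nodes))
        return a.sum(axis=1)


@dataclass
class Hierarchy:
    levels: list[LevelGraph]

    @property
    def L(self) -> int:
        return len(self.levels)


@dataclass
class PADState:
    """Global embedding plus the distribution weight matrix."""

    h_global: Tensor
    w_pad: Tensor
    aggregate_mode: str = "mean"


def build_hierarchy(
    c: int,
    level_spec: list[dict[int, int]] | None = None,
    adjacency: np.ndarray | None = None,
) -> Hierarchy:
    """Build the multi-level graph structure.

    ``level_spec`` is a list of partitions; partition ``l`` maps every node
    of level ``l+1`` to its parent at level ``l+2``. Higher-level adjacency
    is aggregated from the level below (sum of inter-group weights).
    """
    level_spec = level_spec or []
    levels = [LevelGraph(1, c, adjacency, None)]
    for li, part in enumerate(level_spec):
        prev = levels[-1]
        missing = [i for i in range(prev.n_nodes) if i not in part]
        if missing:
            raise ValueError(
                f"partition for level {li + 2} leaves orphan nodes {missing}"
            )
        parents = sorted(set(part.values()))
        if parents != list(range(len(parents))):
            raise ValueError("parent ids must be 0..n_parents-1")
        member = np.array([part[i] for i in range(prev.n_nodes)])
        prev.memberships = member
        n_up = len(parents)
        if prev.adjacency is not None:
            up_adj = np.zeros((n_up, n_up))
            for i in range(prev.n_nodes):
                for j in range(prev.n_nodes):
                    up_adj[member[i], member[j]] += prev.adjacency[i, j]
            np.fill_diagonal(up_adj, 0.0)
        else:
            up_adj = None
        levels.append(LevelGraph(li + 2, n_up, up_adj, None))
    return Hierarchy(levels)


def sym_normalized(a: np.ndarray, self_loops: bool = True) -> np.ndarray:
    """Symmetric normalization D^{-1/2}(A+I)D^{-1/2} of an adjacency."""
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if self_loops:
        a = a + np.eye(a.shape[0])
    d = a.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("isolated node with zero degree; enable self-loops")
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * a * dinv[None, :]


def level_graph_conv(
    g: LevelGraph,
    weights: list[Tensor],
    nonlinearity: str = "relu",
    adjacency_override: Tensor | None = None,
) -> Tensor:
    """Iterate H^(k+1) = sigma(D^{-1/2}(A+I)D^{-1/2} H^(k) W^(k)).

    ``adjacency_override`` substitutes a (differentiable) learned adjacency
    for this level's stored one.
    """
    if g.embeddings is None:
        raise ValueError("level embeddings not initialized")
    if adjacency_override is not None:
        a_hat = _sym_normalized_tensor(adjacency_override)
    else:
        a = g.adjacency
        if a is None:
            a = np.ones((g.n_nodes, g.n_nodes)) - np.eye(g.n_nodes)
        a_hat = Tensor(sym_normalized(a))
    h = g.embeddings
    for w in weights:
        h = a_hat @ (h @ w)
        if nonlinearity == "relu":
            h = h.relu()
        elif nonlinearity == "identity":
            pass
        else:
            raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    g.embeddings = h
    return h


def _sym_normalized_tensor(a: Tensor) -> Tensor:
    """Differentiable D^{-1/2}(A+I)D^{-1/2} for a batched learned adjacency."""
    n = a.shape[-1]
    a = a + Tensor(np.eye(n))
    d = a.sum(axis=-1, keepdims=True)
    dinv = (d.log() * -0.5).exp()  # d^{-1/2}, differentiable
    return a * dinv * dinv.swapaxes(-1, -2)


def pool_to_next_level(
    h: Hierarchy,
    l: int,
    mode: str = "mean",
    attention_scores: np.ndarray | None = None,
) -> Tensor:
    """Aggregate level-l node embeddings into initial parent embeddings.

    ``mode`` is ``max``, ``mean``, or ``attention`` (softmax-weighted mean
    over children using ``attention_scores``; uniform scores reduce to the
    mean).
    """
    g = h.levels[l - 1]
    if g.embeddings is None:
        raise ValueError(f"level {l} embeddings not computed")
    if g.memberships is None:
        raise ValueError(f"level {l} has no partition to pool over")
    n_up = h.levels[l].n_nodes
    parts = []
    for parent in range(n_up):
        idx = np.where(g.memberships == parent)[0]
        child = g.embeddings[..., idx, :]
        if mode == "mean":
            parts.append(child.mean(axis=-2, keepdims=True))
        elif mode == "max":
            parts.append(child.max(axis=-2, keepdims=True))
        elif mode == "attention":
            if attention_scores is None:
                scores = np.zeros(len(idx))
            else:
                scores = np.asarray(attention_scores)[idx]
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            parts.append((child * w[:, None]).sum(axis=-2, keepdims=True))
        else:
            raise ValueError(f"unknown pooling mode {mode!r}")
    from .autodiff import concat

    pooled = concat(parts, axis=-2)
    h.levels[l].embeddings = pooled
    return pooled


def pad_aggregate(h: Hierarchy, w_pad: Tensor, mode: str = "mean") -> PADState:
    """Form the global embedding from all levels' summaries.

    Each level is mean-pooled over nodes to one vector of shared width d,
    then the per-level summaries are combined by sum, mean, or attention.
    """
    summaries = [g.embeddings.mean(axis=-2, keepdims=True) for g in h.levels]
    from .autodiff import concat

    stacked = concat(summaries, axis=-2)  # (..., L, d)
    if mode == "sum":
        h_global = stacked.sum(axis=-2)
    elif mode == "mean":
        h_global = stacked.mean(axis=-2)
    elif mode == "attention":
        # scores from each summary's norm-free mean activation
        scores = stacked.mean(axis=-1, keepdims=True)
        att = softmax(scores, axis=-2)
        h_global = (stacked * att).sum(axis=-2)
    else:
        raise ValueError(f"unknown aggregate mode {mode!r}")
    return PADState(h_global=h_global, w_pad=w_pad, aggregate_mode=mode)


def pad_distribute(h: Hierarchy, s: PADState) -> list[Tensor]:
    """Add W_PAD @ H_global back to every node of every level."""
    shift = s.h_global @ s.w_pad  # (..., d)
    enhanced = []
    for g in h.levels:
        e = g.embeddings + shift.reshape(*shift.shape[:-1], 1, shift.shape[-1])
        g.embeddings = e
        enhanced.append(e)
    return enhanced


def learn_adjacency(
    node_features: Tensor | np.ndarray,
    theta: Tensor,
    a_vec: Tensor,
    bias: Tensor,
    m_bilinear: Tensor | None = None,
    zero_diagonal: bool = False,
) -> Tensor:
    """Symmetric nonnegative learned adjacency W_ij = f(x_i, x_j, theta).

    The default scorer is a symmetrized softplus bilinear form over projected
    features z = theta^T x:

        f = softplus(z_i^T M z_j + a^T [z_i || z_j] + b)

    averaged with its transpose so W is exactly symmetric. The bilinear term
    lets the scorer express pairwise (community) structure; the concatenation
    term alone is node-additive and can only modulate degrees.
    """
    x = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
    if not np.isfinite(x.data).all():
        raise ValueError("non-finite node features")
    z = x @ theta  # (..., n, p)
    p = z.shape[-1]
    a1 = a_vec[:p]
    a2 = a_vec[p:]
    si = z @ a1.reshape(p, 1)  # (..., n, 1)
    sj = z @ a2.reshape(p, 1)
    raw = si + sj.swapaxes(-1, -2) + bias  # (..., n, n)
    if m_bilinear is not None:
        m_sym = (m_bilinear + m_bilinear.transpose()) * 0.5
        raw = raw + z @ m_sym @ z.swapaxes(-1, -2)
    w = _softplus(raw)
    w = (w + w.swapaxes(-1, -2)) * 0.5
    if zero_diagonal:
        n = w.shape[-1]
        w = w * Tensor(1.0 - np.eye(n))
    return w


def _softplus(x: Tensor) -> Tensor:
    # stable softplus: max(x, 0) + log1p(exp(-|x|))
    pos = x.relu()
    absx = x.relu() + (-x).relu()
    return pos + ((absx * -1.0).exp() + 1.0).log()


def alignment_loss(c: np.ndarray | Tensor, w: Tensor) -> Tensor:
    """Squared Frobenius norm ||C - W||_F^2 (summed over batch mean)."""
    c_t = c if isinstance(c, Tensor) else Tensor(c)
    if c_t.shape[-2:] != w.shape[-2:]:
        raise ValueError(f"shape mismatch: C {c_t.shape} vs W {w.shape}")
    diff = c_t - w
    sq = diff * diff
    if sq.ndim > 2:
        return sq.sum(axis=-1).sum(axis=-1).mean()
    return sq.sum()


def init_hgra_params(
    rng: np.random.Generator,
    c: int,
    w_samples: int,
    d: int = 16,
    conv_layers: int = 1,
    n_levels: int = 2,
    scorer_width: int = 4,
) -> dict[str, Tensor]:
    """Initialize channel embedding, per-level conv, PAD, and scorer weights."""

    def glorot(*shape, scale=1.0):
        lim = scale * np.sqrt(6.0 / (shape[-2] + shape[-1]))
        return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)

    params = {
        "chan_w": glorot(w_samples, d),
        "chan_b": Tensor(np.zeros(d), requires_grad=True),
        "w_pad": glorot(d, d),
        # scorer starts near a weak uniform adjacency (softplus(-1) ~ 0.31):
        # small weights keep the softplus out of its saturated region, where
        # gradients vanish and the learned graph cannot recover structure
        "adj_theta": glorot(d, scorer_width, scale=0.3),
        "adj_a": Tensor(rng.uniform(-0.1, 0.1, size=2 * scorer_width),
                        requires_grad=True),
        "adj_m": glorot(scorer_width, scorer_width, scale=0.3),
        "adj_bias": Tensor(np.full(1, -1.0), requires_grad=True),
    }
    for lvl in range(n_levels):
        for k in range(conv_layers):
            params[f"lvl{lvl}_w{k}"] = glorot(d, d)
    return params


def hgra_forward(
    windows: np.ndarray,
    params: dict[str, Tensor],
    hierarchy: Hierarchy,
    adjacency_source: str = "learned",
    pool_mode: str = "mean",
    aggregate_mode: str = "mean",
    nonlinearity: str = "relu",
    use_pad: bool = True,
    return_adjacency: bool = False,
):
    """Full HGRA pass: channel embed -> per-level conv/pool -> PAD -> h_s.

    ``windows`` is (batch, C, W) or (C, W). ``adjacency_source`` selects the
    level-1 adjacency: ``learned`` (scored from channel embeddings),
    ``supplied`` (the hierarchy's stored matrix), or ``full``.
    Returns h_s (top-level readout) and, optionally, the learned adjacency.
    """
    x = np.asarray(windows, dtype=float)
    emb = Tensor(x) @ params["chan_w"] + params["chan_b"]  # (..., C, d)
    levels = hierarchy.levels
    n_levels = len(levels)
    learned = None
    for g in levels:
        g.embeddings = None

    levels[0].embeddings = emb
    adjacency_override = None
    if adjacency_source == "learned":
        learned = learn_adjacency(
            emb, params["adj_theta"], params["adj_a"], params["adj_bias"],
            m_bilinear=params.get("adj_m"),
        )
        adjacency_override = learned
    elif adjacency_source == "full":
        adjacency_override = None
        levels[0].adjacency = None
    elif adjacency_source != "supplied":
        raise ValueError(f"unknown adjacency source {adjacency_source!r}")

    for lvl in range(n_levels):
        ws = [params[k] for k in sorted(params) if k.startswith(f"lvl{lvl}_w")]
        level_graph_conv(
            levels[lvl], ws, nonlinearity,
            adjacency_override=adjacency_override if lvl == 0 else None,
        )
        if lvl < n_levels - 1:
            pool_to_next_level(hierarchy, lvl + 1, mode=pool_mode)

    if use_pad:
        state = pad_aggregate(hierarchy, params["w_pad"], mode=aggregate_mode)
        pad_distribute(hierarchy, state)

    h_s = levels[-1].embeddings.mean(axis=-2)
    if return_adjacency:
        return h_s, learned
    return h_s
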