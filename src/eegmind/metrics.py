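"""Connectivity-validation statistics.

Functional connectivity is the Pearson correlation between channel (or
region) time courses. A learned adjacency is compared against it with a
normalized graph similarity index (cosine similarity over matrix entries),
its community structure is quantified with Newman modularity, group
differences in edge strength are tested with a Welch two-sample t statistic,
and per-node importance is the normalized weighted degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .containers import EEGRecording

__all__ = [
    "ConnectivityPair",
    "functional_connectivity",
    "graph_similarity_index",
    "modularity",
    "connectivity_contrast",
    "node_importance",
]

log = logging.getLogger(__name__)


@dataclass
class ConnectivityPair:
    """A measured connectivity matrix C and a learned adjacency W."""

    C: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.C.shape != self.W.shape:
            raise ValueError(f"shape mismatch: C {self.C.shape}, W {self.W.shape}")
        for name, m in (("C", self.C), ("W", self.W)):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")

    @property
    def n(self) -> int:
        return self.C.shape[0]


def functional_connectivity(data: EEGRecording | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of channel time courses.

    Accepts a recording, one (C, T) array, or a stack of windows (N, C, W)
    whose time axes are concatenated. Constant channels get correlation 0
    with everything (logged); the diagonal is always 1.
    """
    if isinstance(data, EEGRecording):
        x = data.data
    else:
        x = np.asarray(data, dtype=float)
        if x.ndim == 3:
            x = np.concatenate(list(x), axis=1)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        log.warning("%d constant channel(s); their correlations set to 0",
                    int(flat.sum()))
    c = np.zeros((x.shape[0], x.shape[0]))
    ok = ~flat
    if ok.sum() >= 2:
        c[np.ix_(ok, ok)] = np.corrcoef(x[ok])
    elif ok.sum() == 1:
        c[np.ix_(ok, ok)] = 1.0
    np.fill_diagonal(c, 1.0)
    return c


def graph_similarity_index(pair: ConnectivityPair, rectify: bool = True) -> float:
    """Normalized similarity S = <C, W> / (||C||_F ||W||_F) in [0, 1].

    The [0, 1] range requires nonnegative entries; Pearson correlations can
    be negative, so C (and W) are rectified to absolute values by default.
    """
    c, w = pair.C, pair.W
    if rectify:
        c, w = np.abs(c), np.abs(w)
    nc = np.sqrt((c**2).sum())
    nw = np.sqrt((w**2).sum())
    if nc == 0 or nw == 0:
        raise ValueError("similarity undefined for an all-zero matrix")
    return float((c * w).sum() / (nc * nw))


def modularity(w: np.ndarray, memberships: np.ndarray) -> float:
    """Newman modularity Q = (1/2m) sum_ij [W_ij - k_i k_j / 2m] delta(g_i, g_j).

    ``w`` is a symmetric nonnegative (weighted) adjacency; ``memberships``
    assigns each node to a module. 2m is the total edge weight.
    """
    w = np.asarray(w, dtype=float)
    g = np.asarray(memberships)
    if not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric")
    if (w < 0).any():
        raise ValueError("adjacency must be nonnegative")
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("graph has no edges (2m = 0)")
    k = w.sum(axis=1)
    delta = g[:, None] == g[None, :]
    return float(((w - np.outer(k, k) / two_m) * delta).sum() / two_m)


def connectivity_contrast(
    group1: np.ndarray, group2: np.ndarray
) -> tuple[float, float]:
    """Welch two-sample t on edge-strength samples; returns (t, two-sided p).

    t = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2) with the
    Welch-Satterthwaite degrees of freedom for the p-value. Zero variance in
    both groups with equal means gives t = 0, p = 1.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(p)


def edge_samples(
    matrices: np.ndarray, i: int, j: int
) -> np.ndarray:
    """Extract one edge's strength across a stack of (N, C, C) matrices."""
    m = np.asarray(matrices)
    return m[:, i, j]


def node_importance(w: np.ndarray) -> np.ndarray:
    """Normalized weighted degree: score_i = k_i / sum(k); sums to 1."""
    w = np.asarray(w, dtype=float)
    if not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric")
    k = w.sum(axis=1)
    total = k.sum()
    if total == 0:
        return np.full(len(k), 1.0 / len(k))
    return k / total
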