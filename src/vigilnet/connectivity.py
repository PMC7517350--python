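"""Functional connectivity by normalised zero-lag cross-correlation.

The connectivity between channels i and j is

    gamma_ij = | sum_t s_i(t) s_j(t) | / sqrt( sum_t s_i(t)^2  sum_t s_j(t)^2 )

i.e. the absolute normalised cross-correlation at lag zero, computed on the
raw (not mean-centred) samples.  On band-limited, near zero-mean signals
this is numerically close to the absolute Pearson correlation; a centred
variant is available via ``center=True``.  The matrix F collects gamma_ij
with an exactly zero diagonal (self-connections excluded), and the global
connectivity energy sum_ij F(i,j)^2 summarises overall coupling strength.

No correction for volume conduction is attempted: the estimator is kept
mixing-prone deliberately, and the downstream connection-cluster
classification is designed to extract structure despite the resulting
artificial and spurious links.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_montage import Recording, read_matrix, write_matrix

__all__ = [
    "ConnectivityMatrix",
    "zero_lag_correlation",
    "build_matrix",
    "global_connectivity_energy",
    "ZeroLagConnectivity",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N matrix of zero-lag correlation strengths.

    Invariants: exact symmetry, exactly zero diagonal, off-diagonal values
    in [0, 1].
    """

    labels: tuple[str, ...]
    values: np.ndarray
    segment_index: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.array_equal(v, v.T):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("off-diagonal entries must lie in [0, 1]")
        self.labels = tuple(self.labels)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def save(self, path) -> Path:
        return write_matrix(self.labels, self.values, path)

    @classmethod
    def load(cls, path, segment_index: int | None = None) -> "ConnectivityMatrix":
        labels, values = read_matrix(path)
        return cls(labels, values, segment_index)


def zero_lag_correlation(si, sj) -> float:
    """Normalised cross-correlation magnitude at lag zero; in [0, 1]."""
    a = np.asarray(si, dtype=float)
    b = np.asarray(sj, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    ea = float(a @ a)
    eb = float(b @ b)
    if ea == 0.0 or eb == 0.0:
        raise ValueError("zero-energy input sequence")
    gamma = abs(float(a @ b)) / np.sqrt(ea * eb)
    return min(gamma, 1.0)  # guard against rounding slightly above 1


def build_matrix(seg: Recording | np.ndarray,
                 labels: Sequence[str] | None = None,
                 segment_index: int | None = None,
                 center: bool = False) -> ConnectivityMatrix:
    """Connectivity matrix of a (band-limited) multichannel segment.

    The upper triangle is computed and mirrored, so symmetry is exact; the
    diagonal is zero.  A zero-energy channel is an error naming the channel.
    """
    if isinstance(seg, Recording):
        X = seg.data
        labels = seg.channel_labels
        if segment_index is None:
            segment_index = None
    else:
        X = np.atleast_2d(np.asarray(seg, dtype=float))
        if labels is None:
            labels = tuple(f"ch{i + 1}" for i in range(X.shape[0]))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two channels")
    if center:
        X = X - X.mean(axis=1, keepdims=True)
    G = X @ X.T
    energy = np.diag(G).copy()
    for i, e in enumerate(energy):
        if e == 0.0:
            raise ValueError(f"zero-energy channel {labels[i]!r}")
    denom = np.sqrt(np.outer(energy, energy))
    C = np.abs(G) / denom
    np.clip(C, 0.0, 1.0, out=C)
    upper = np.triu(C, k=1)
    return ConnectivityMatrix(tuple(labels), upper + upper.T, segment_index)


def global_connectivity_energy(F: ConnectivityMatrix | np.ndarray) -> float:
    """Total energy sum_ij F(i,j)^2 of the connectivity matrix elements."""
    v = F.values if isinstance(F, ConnectivityMatrix) else np.asarray(F, dtype=float)
    return float(np.sum(v ** 2))


class ZeroLagConnectivity(TransformerMixin, BaseEstimator):
    """Transformer mapping a (channels x samples) array to its N x N matrix.

    ``transform`` is stateless; ``fit`` records the channel count.  With
    ``center=True`` channels are mean-centred first (absolute Pearson).
    """

    def __init__(self, center: bool = False):
        self.center = center

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_channels_ = X.shape[0]
        return self

    def transform(self, X) -> np.ndarray:
        return build_matrix(np.asarray(X, dtype=float), center=self.center).values
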