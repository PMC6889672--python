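"""Gaussian interaction profile kernel (GIPK) similarity.

Each entity is represented by its binary interaction profile — a row of the
association matrix for diseases, a column for miRNAs — and similarity is an
RBF kernel on those profiles:

    K(i, j) = exp(-alpha * ||IP(i) - IP(j)||^2)

with the bandwidth normalized by the mean squared profile norm,
alpha = alpha' / mean_i ||IP(i)||^2, so that the raw bandwidth alpha'
(default 1) is scale-free in the number of known associations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core_io import AdjacencyMatrix, SimilarityMatrix

__all__ = [
    "gipk_bandwidth",
    "gipk_similarity",
    "disease_gipk",
    "mirna_gipk",
]


def _as_profiles(profiles: np.ndarray) -> np.ndarray:
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be a 2-D array (one row per entity)")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("profiles must be binary")
    return x


def gipk_bandwidth(profiles: np.ndarray, alpha_prime: float = 1.0) -> float:
    """Normalized kernel bandwidth alpha' / mean squared profile norm.

    Individual all-zero profiles are fine (a disease stripped of all its
    associations in a hold-out still gets a kernel row); only a fully zero
    profile set is degenerate.
    """
    if alpha_prime <= 0:
        raise ValueError(f"alpha_prime must be positive, got {alpha_prime}")
    x = _as_profiles(profiles)
    mean_sq_norm = float((x * x).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise ValueError("degenerate profiles: every interaction profile is zero")
    return alpha_prime / mean_sq_norm


def gipk_similarity(
    profiles: np.ndarray,
    labels: tuple[str, ...] | list[str],
    alpha_prime: float = 1.0,
) -> SimilarityMatrix:
    """Kernel matrix over a set of binary interaction profiles."""
    x = _as_profiles(profiles)
    if len(labels) != x.shape[0]:
        raise ValueError("label count does not match profile count")
    alpha = gipk_bandwidth(x, alpha_prime)
    sq_dists = squareform(pdist(x, metric="sqeuclidean"))
    values = np.exp(-alpha * sq_dists)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, tuple(labels), "gipk")


def disease_gipk(adj: AdjacencyMatrix, alpha_prime: float = 1.0) -> SimilarityMatrix:
    """Kernel over disease profiles (rows of the association matrix)."""
    return gipk_similarity(adj.values, adj.index.diseases, alpha_prime)


def mirna_gipk(adj: AdjacencyMatrix, alpha_prime: float = 1.0) -> SimilarityMatrix:
    """Kernel over miRNA profiles (columns of the association matrix)."""
    return gipk_similarity(adj.values.T, adj.index.mirnas, alpha_prime)
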