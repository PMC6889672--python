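"""Integrated similarity matrices.

The two information sources per axis are merged entrywise.  For diseases,
when both endpoints have ontology DAGs the entry is the mean of the two
semantic similarity models; otherwise the interaction-profile kernel fills
in.  For miRNAs, the precomputed functional similarity is used as-is when
both endpoints are covered by it, with the kernel as fallback.  Coverage is a
per-entity boolean mask, applied pairwise (both endpoints must be covered).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SimilarityMatrix

__all__ = [
    "CoverageMask",
    "coverage_from_labels",
    "integrate_disease_similarity",
    "integrate_mirna_similarity",
]


@dataclass(frozen=True)
class CoverageMask:
    """Per-entity flags for which similarity source covers each entity."""

    labels: tuple[str, ...]
    covered: np.ndarray  # bool, aligned with labels

    def __post_init__(self) -> None:
        c = np.asarray(self.covered, dtype=bool)
        if c.shape != (len(self.labels),):
            raise ValueError("mask length does not match labels")
        object.__setattr__(self, "covered", c)

    def pairwise(self) -> np.ndarray:
        """True where both entities of a pair are covered."""
        return np.outer(self.covered, self.covered)


def coverage_from_labels(
    labels: tuple[str, ...] | list[str], covered_labels
) -> CoverageMask:
    covered_set = set(covered_labels)
    labels = tuple(labels)
    return CoverageMask(labels, np.array([l in covered_set for l in labels]))


def _check_aligned(*mats: SimilarityMatrix) -> tuple[str, ...]:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("similarity matrices have mismatched labels")
    return labels


def integrate_disease_similarity(
    dss1: SimilarityMatrix,
    dss2: SimilarityMatrix,
    dks: SimilarityMatrix,
    mask: CoverageMask,
) -> SimilarityMatrix:
    """Mean of the two semantic models where both diseases have DAGs, else kernel.

    All matrices must share labels and order; semantic matrices computed on a
    DAG-covered subset should be expanded first (``SimilarityMatrix.reindex``).
    """
    labels = _check_aligned(dss1, dss2, dks)
    if mask.labels != labels:
        raise ValueError("coverage mask labels do not match matrices")
    both = mask.pairwise()
    values = np.where(both, (dss1.values + dss2.values) / 2.0, dks.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, labels, "integrated")


def integrate_mirna_similarity(
    mfsm: SimilarityMatrix,
    mks: SimilarityMatrix,
    mask: CoverageMask,
) -> SimilarityMatrix:
    """Functional similarity where both miRNAs are covered by it, else kernel."""
    labels = _check_aligned(mfsm, mks)
    if mask.labels != labels:
        raise ValueError("coverage mask labels do not match matrices")
    both = mask.pairwise()
    values = np.where(both, mfsm.values, mks.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, labels, "integrated")
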