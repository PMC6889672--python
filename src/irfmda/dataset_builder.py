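"""Labeled training set construction.

Positives are the known associations; negatives are unconfirmed pairs drawn
uniformly without replacement from the zero cells of the association matrix
(rejection sampling, mirroring how a balanced training set is assembled from
an otherwise positive-unlabeled problem).  Each pair (d, m) is represented by
the row of the integrated miRNA similarity matrix for m followed by the row
of the integrated disease similarity matrix for d, so with nm miRNAs and nd
diseases the raw feature vector has nm + nd dimensions (878 at the scale of
the HMDD v2.0 snapshot: 495 + 383).  Features are min-max rescaled per column
over the training samples; the stored statistics are reapplied (with
clipping) to any pair scored later.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import AdjacencyMatrix, EntityIndex, SimilarityMatrix

__all__ = [
    "PairSample",
    "NormalizationStats",
    "LabeledDataset",
    "sample_negatives",
    "build_features",
    "minmax_normalize",
    "apply_normalization",
]


@dataclass(frozen=True)
class PairSample:
    """One (disease, miRNA) pair with a 0/1 label, by index position."""

    disease: int
    mirna: int
    label: int


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature training min/max, reapplied at prediction time."""

    mins: np.ndarray
    maxs: np.ndarray
    feature_names: tuple[str, ...]

    def subset(self, names: list[str]) -> "NormalizationStats":
        pos = {n: i for i, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return NormalizationStats(self.mins[idx], self.maxs[idx], tuple(names))


@dataclass(frozen=True)
class LabeledDataset:
    samples: tuple[PairSample, ...]
    features: np.ndarray
    feature_names: tuple[str, ...]
    stats: NormalizationStats | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.shape != (len(self.samples), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {f.shape} does not match "
                f"{len(self.samples)} samples x {len(self.feature_names)} features"
            )
        keys = {(s.disease, s.mirna) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("duplicate (disease, miRNA) pair in dataset")
        object.__setattr__(self, "features", f)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select_columns(self, names: list[str]) -> "LabeledDataset":
        pos = {n: i for i, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return LabeledDataset(
            self.samples,
            self.features[:, idx],
            tuple(names),
            self.stats.subset(names) if self.stats is not None else None,
        )

    def write_tsv(self, path: str | Path, index: EntityIndex) -> None:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "mirna", [index.mirnas[s.mirna] for s in self.samples])
        df.insert(0, "disease", [index.diseases[s.disease] for s in self.samples])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sample_negatives(
    adj: AdjacencyMatrix, count: int, seed: int
) -> list[PairSample]:
    """Uniform draw of ``count`` distinct unconfirmed pairs, label 0.

    Rejection sampling from random (disease, miRNA) cells, skipping known
    positives and already-drawn cells; deterministic given ``seed``.
    """
    nd, nm = adj.values.shape
    n_zero = nd * nm - adj.n_positive
    if count > n_zero:
        raise ValueError(
            f"requested {count} negatives but only {n_zero} unconfirmed pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: dict[tuple[int, int], None] = {}
    while len(chosen) < count:
        d = int(rng.integers(nd))
        m = int(rng.integers(nm))
        if adj.values[d, m] == 0 and (d, m) not in chosen:
            chosen[(d, m)] = None
    return [PairSample(d, m, 0) for d, m in chosen]


def build_features(
    pairs: list[PairSample],
    idsm: SimilarityMatrix,
    imsm: SimilarityMatrix,
) -> LabeledDataset:
    """Concatenate the miRNA similarity row and the disease similarity row.

    The miRNA block comes first; feature names are ``m:<name>`` then
    ``d:<name>`` so selection results can be traced back to entities.
    """
    nd, nm = idsm.n, imsm.n
    for s in pairs:
        if not (0 <= s.disease < nd and 0 <= s.mirna < nm):
            raise IndexError(
                f"pair ({s.disease}, {s.mirna}) out of range for "
                f"{nd} diseases x {nm} miRNAs"
            )
    features = np.empty((len(pairs), nm + nd), dtype=float)
    for row, s in enumerate(pairs):
        features[row, :nm] = imsm.values[s.mirna]
        features[row, nm:] = idsm.values[s.disease]
    names = tuple(f"m:{n}" for n in imsm.labels) + tuple(f"d:{n}" for n in idsm.labels)
    return LabeledDataset(tuple(pairs), features, names)


def minmax_normalize(dataset: LabeledDataset) -> LabeledDataset:
    """Rescale each feature column to [0, 1] over the training samples.

    Constant columns carry no information and map to 0.  The per-column
    min/max are stored on the dataset for reuse on prediction-time pairs.
    """
    if len(dataset.samples) == 0:
        raise ValueError("cannot normalize an empty dataset")
    mins = dataset.features.min(axis=0)
    maxs = dataset.features.max(axis=0)
    stats = NormalizationStats(mins, maxs, dataset.feature_names)
    return replace(
        dataset, features=apply_normalization(dataset.features, stats), stats=stats
    )


def apply_normalization(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Apply stored min-max statistics, clipping to [0, 1].

    Clipping matters only for prediction-time pairs whose raw values fall
    outside the training range.
    """
    features = np.asarray(features, dtype=float)
    span = stats.maxs - stats.mins
    safe = np.where(span == 0.0, 1.0, span)
    out = (features - stats.mins) / safe
    out[:, span == 0.0] = 0.0
    return np.clip(out, 0.0, 1.0)
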