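"""Random-forest regression scorer for disease-miRNA pairs.

The model is a regression forest fitted on 0/1 labels, so each prediction is
the forest's vote-averaged estimate of the association probability; scores
are clipped to [0, 1].  The trained scorer carries everything needed to
reproduce its feature space at prediction time: the selected feature names in
order and the min-max normalization statistics of the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .core_io import EntityIndex, SimilarityMatrix
from .dataset_builder import LabeledDataset, NormalizationStats, apply_normalization

__all__ = ["RFConfig", "TrainedScorer", "train_rf", "score_pairs", "score_all_pairs"]


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters.

    ``mtry`` (features tried per split) defaults to floor(feature count / 3)
    at fit time — 33 for a 100-feature model — and ``min_leaf`` (terminal
    node size) to 5, the regression defaults of the classical randomForest
    implementation.
    """

    ntree: int = 500
    mtry: int | None = None
    min_leaf: int = 5
    seed: int = 0

    def resolved_mtry(self, n_features: int) -> int:
        mtry = self.mtry if self.mtry is not None else max(1, n_features // 3)
        if not 1 <= mtry <= n_features:
            raise ValueError(
                f"mtry {mtry} outside [1, {n_features}] for {n_features} features"
            )
        return mtry


@dataclass
class TrainedScorer:
    forest: RandomForestRegressor = field(repr=False)
    feature_names: tuple[str, ...]
    stats: NormalizationStats
    config: RFConfig

    def predict(self, raw_features: np.ndarray) -> np.ndarray:
        """Score raw (unnormalized) feature rows in this scorer's feature order."""
        X = apply_normalization(raw_features, self.stats)
        return np.clip(self.forest.predict(X), 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedScorer":
        return joblib.load(path)


def train_rf(dataset: LabeledDataset, config: RFConfig = RFConfig()) -> TrainedScorer:
    """Fit the regression forest on a normalized, feature-selected dataset."""
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both positive and negative samples")
    if dataset.stats is None:
        raise ValueError("dataset must be min-max normalized before training")
    forest = RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=config.resolved_mtry(dataset.n_features),
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(dataset.features, y)
    return TrainedScorer(forest, dataset.feature_names, dataset.stats, config)


def _raw_feature_rows(
    pairs: list[tuple[int, int]],
    feature_names: tuple[str, ...],
    idsm: SimilarityMatrix,
    imsm: SimilarityMatrix,
) -> np.ndarray:
    """Assemble raw feature rows for (disease idx, miRNA idx) pairs.

    Feature ``m:<name>`` reads column <name> of the scored pair's miRNA
    similarity row; ``d:<name>`` the disease analogue — so a scorer trained
    on a selected subset rebuilds exactly those columns.
    """
    m_cols, d_cols, m_slots, d_slots = [], [], [], []
    for slot, name in enumerate(feature_names):
        axis, _, entity = name.partition(":")
        if axis == "m":
            m_slots.append(slot)
            m_cols.append(imsm.labels.index(entity))
        elif axis == "d":
            d_slots.append(slot)
            d_cols.append(idsm.labels.index(entity))
        else:
            raise ValueError(f"unrecognized feature name {name!r}")
    out = np.empty((len(pairs), len(feature_names)), dtype=float)
    for row, (d, m) in enumerate(pairs):
        out[row, m_slots] = imsm.values[m, m_cols]
        out[row, d_slots] = idsm.values[d, d_cols]
    return out


def score_pairs(
    model: TrainedScorer,
    pairs: list[tuple[str, str]],
    idsm: SimilarityMatrix,
    imsm: SimilarityMatrix,
    index: EntityIndex,
) -> pd.DataFrame:
    """Score named (disease, miRNA) pairs; returns a disease/mirna/score table."""
    if not pairs:
        return pd.DataFrame(columns=["disease", "mirna", "score"])
    idx_pairs = [(index.disease_pos(d), index.mirna_pos(m)) for d, m in pairs]
    raw = _raw_feature_rows(idx_pairs, model.feature_names, idsm, imsm)
    scores = model.predict(raw)
    return pd.DataFrame(
        {
            "disease": [d for d, _ in pairs],
            "mirna": [m for _, m in pairs],
            "score": scores,
        }
    )


def score_all_pairs(
    model: TrainedScorer,
    idsm: SimilarityMatrix,
    imsm: SimilarityMatrix,
    index: EntityIndex,
) -> np.ndarray:
    """Score every cell of the nd x nm association grid, returned as a matrix."""
    idx_pairs = [(d, m) for d in range(index.nd) for m in range(index.nm)]
    raw = _raw_feature_rows(idx_pairs, model.feature_names, idsm, imsm)
    return model.predict(raw).reshape(index.nd, index.nm)
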