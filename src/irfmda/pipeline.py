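"""End-to-end orchestration: adjacency -> similarities -> features -> forest.

The four stages are (1) balanced sample selection, (2) similarity-based pair
representation, (3) importance-based feature selection, (4) forest training
and scoring of unknown pairs.  :func:`fit_pipeline` runs them on in-memory
inputs and returns a :class:`FittedPipeline`; :func:`run_full_pipeline` is
the file-to-file variant used by the command line, writing every
intermediate artifact plus a manifest.

All randomness derives from one integer seed: negative sampling, the
importance forests and the final forest get fixed offsets of it, so a run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    AdjacencyMatrix,
    DagCollection,
    EntityIndex,
    SimilarityMatrix,
    build_adjacency,
    load_associations,
    load_dag_collection,
    load_similarity_matrix,
    write_similarity_matrix,
)
from .dataset_builder import (
    LabeledDataset,
    PairSample,
    build_features,
    minmax_normalize,
    sample_negatives,
)
from .disease_semantics import semantic_similarity
from .feature_selection import (
    FeatureRanking,
    ImportanceScores,
    rank_features,
    select_top_k,
    variable_importance,
)
from .gipk import disease_gipk, mirna_gipk
from .integration import (
    coverage_from_labels,
    integrate_disease_similarity,
    integrate_mirna_similarity,
)
from .rf_model import RFConfig, TrainedScorer, score_all_pairs, train_rf

logger = logging.getLogger("irfmda")

__all__ = ["PipelineConfig", "FittedPipeline", "fit_pipeline", "run_full_pipeline"]

# fixed offsets separating the pipeline's independent random streams
_NEGATIVE_SEED_OFFSET = 1_000
_IMPORTANCE_SEED_OFFSET = 2_000
_RF_SEED_OFFSET = 3_000


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, plus the file paths for CLI runs.

    Defaults follow the reference setting of the method: decay 0.5 for the
    semantic contribution, raw kernel bandwidth 1 on both axes, balanced
    negative sampling, 500-tree importance forests averaged over 10 resampled
    runs, top-100 features, and a 500-tree regression forest with mtry =
    floor(features / 3).
    """

    # inputs (CLI runs; fit_pipeline ignores these)
    associations_path: str | None = None
    dags_path: str | None = None
    functional_path: str | None = None
    out_dir: str = "irfmda_out"

    # similarity parameters
    delta: float = 0.5
    alpha_disease: float = 1.0
    alpha_mirna: float = 1.0

    # dataset
    n_negatives: int | None = None  # None -> one per positive

    # feature selection; k=None disables selection
    importance_ntree: int = 500
    importance_folds: int = 10
    importance_repeats: int = 1
    importance_criterion: str = "accuracy"
    k: int | None = 100

    # final forest
    rf_ntree: int = 500
    rf_mtry: int | None = None
    rf_min_leaf: int = 5

    # evaluation
    leakage: str = "strict"  # strict | paper-fast
    grouped_loocv: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.leakage not in ("strict", "paper-fast"):
            raise ValueError(f"leakage must be 'strict' or 'paper-fast', got {self.leakage!r}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be positive or None")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value YAML; explicit keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FittedPipeline:
    """All artifacts of one pipeline fit, sharing one entity index."""

    index: EntityIndex
    adjacency: AdjacencyMatrix
    dss1: SimilarityMatrix | None
    dss2: SimilarityMatrix | None
    dks: SimilarityMatrix
    mks: SimilarityMatrix
    idsm: SimilarityMatrix
    imsm: SimilarityMatrix
    dataset: LabeledDataset = field(repr=False)
    importance: ImportanceScores | None
    ranking: FeatureRanking | None
    scorer: TrainedScorer = field(repr=False)
    config: PipelineConfig
    seed: int

    def score_matrix(self) -> np.ndarray:
        """Predicted association score for every cell of the nd x nm grid."""
        return score_all_pairs(self.scorer, self.idsm, self.imsm, self.index)

    def refit_without(self, held_out: set[tuple[int, int]]) -> "FittedPipeline":
        """Retrain the forest with the given pairs' samples dropped.

        Similarities, normalization and feature selection are kept as fitted
        — this is the cheap hold-out used by the leakage-tolerant mode.
        """
        keep = [
            i
            for i, s in enumerate(self.dataset.samples)
            if (s.disease, s.mirna) not in held_out
        ]
        sub = LabeledDataset(
            tuple(self.dataset.samples[i] for i in keep),
            self.dataset.features[keep],
            self.dataset.feature_names,
            self.dataset.stats,
        )
        scorer = train_rf(
            sub,
            RFConfig(
                self.config.rf_ntree, self.config.rf_mtry,
                self.config.rf_min_leaf, self.seed + _RF_SEED_OFFSET,
            ),
        )
        return replace(self, dataset=sub, scorer=scorer)


def build_similarities(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, SimilarityMatrix | None]:
    """Stage 2 similarities: semantic models, kernels, and their integration."""
    index = adj.index
    dks = disease_gipk(adj, config.alpha_disease)
    mks = mirna_gipk(adj, config.alpha_mirna)

    if dags is not None and len(dags) > 0:
        covered = [d for d in dags.diseases if d in set(index.diseases)]
    else:
        covered = []
    if covered:
        sub = DagCollection({d: dags.dags[d] for d in covered})
        dss1 = semantic_similarity(sub, model=1, delta=config.delta).reindex(index.diseases)
        dss2 = semantic_similarity(sub, model=2).reindex(index.diseases)
    else:
        dss1 = dss2 = None
    d_mask = coverage_from_labels(index.diseases, covered)
    if dss1 is not None:
        idsm = integrate_disease_similarity(dss1, dss2, dks, d_mask)
    else:
        idsm = SimilarityMatrix(dks.values.copy(), dks.labels, "integrated")

    if mfsm is not None:
        m_covered = [m for m in mfsm.labels if m in set(index.mirnas)]
        mfsm_full = mfsm.reindex(index.mirnas)
        m_mask = coverage_from_labels(index.mirnas, m_covered)
        imsm = integrate_mirna_similarity(mfsm_full, mks, m_mask)
    else:
        imsm = SimilarityMatrix(mks.values.copy(), mks.labels, "integrated")
    return {"dss1": dss1, "dss2": dss2, "dks": dks, "mks": mks, "idsm": idsm, "imsm": imsm}


def fit_pipeline(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig = PipelineConfig(),
    seed: int | None = None,
) -> FittedPipeline:
    """Run stages 1-4 on in-memory inputs.

    ``seed`` overrides ``config.seed`` (used by cross-validation to give each
    fold its own stream while keeping one config object).
    """
    seed = config.seed if seed is None else seed
    index = adj.index
    if adj.n_positive == 0:
        raise ValueError("association matrix has no positive entries")

    sims = build_similarities(adj, dags, mfsm, config)
    idsm, imsm = sims["idsm"], sims["imsm"]

    positives = [PairSample(d, m, 1) for d, m in adj.positive_pairs()]
    n_neg = config.n_negatives if config.n_negatives is not None else len(positives)
    negatives = sample_negatives(adj, n_neg, seed + _NEGATIVE_SEED_OFFSET)
    dataset = minmax_normalize(build_features(positives + negatives, idsm, imsm))

    importance = ranking = None
    if config.k is not None:
        if config.k > dataset.n_features:
            raise ValueError(
                f"k={config.k} exceeds the {dataset.n_features} available features"
            )
        importance = variable_importance(
            dataset,
            ntree=config.importance_ntree,
            folds=config.importance_folds,
            seed=seed + _IMPORTANCE_SEED_OFFSET,
            criterion=config.importance_criterion,
            n_repeats=config.importance_repeats,
            min_leaf=config.rf_min_leaf,
        )
        ranking = rank_features(importance)
        dataset = select_top_k(dataset, ranking, config.k)

    scorer = train_rf(
        dataset,
        RFConfig(config.rf_ntree, config.rf_mtry, config.rf_min_leaf, seed + _RF_SEED_OFFSET),
    )
    return FittedPipeline(
        index=index,
        adjacency=adj,
        dss1=sims["dss1"],
        dss2=sims["dss2"],
        dks=sims["dks"],
        mks=sims["mks"],
        idsm=idsm,
        imsm=imsm,
        dataset=dataset,
        importance=importance,
        ranking=ranking,
        scorer=scorer,
        config=config,
        seed=seed,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> Path:
    """File-to-file run writing every artifact; returns the output directory.

    Artifacts: the six similarity matrices, the labeled dataset with its
    normalization sidecar, the importance table, the fitted model, and a
    prediction table over every unconfirmed pair (sorted within disease by
    descending score).  The manifest records the config, seeds, input hashes
    and library versions so a run can be reproduced byte-for-byte.
    """
    if config.associations_path is None:
        raise ValueError("config.associations_path is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.2fs", name, timings[name])

    s = stage("load")
    assoc, index = load_associations(config.associations_path)
    adj = build_adjacency(assoc, index)
    dags = load_dag_collection(config.dags_path) if config.dags_path else None
    mfsm = (
        load_similarity_matrix(config.functional_path)
        if config.functional_path
        else None
    )
    logger.info(
        "loaded %d associations over %d diseases x %d miRNAs",
        len(assoc), index.nd, index.nm,
    )
    done(s)

    s = stage("fit")
    fp = fit_pipeline(adj, dags, mfsm, config)
    done(s)

    s = stage("write")
    for name in ("dss1", "dss2", "dks", "mks", "idsm", "imsm"):
        sim = getattr(fp, name)
        if sim is not None:
            write_similarity_matrix(sim, out / f"{name}.tsv")
    fp.dataset.write_tsv(out / "dataset.tsv", index)
    if fp.dataset.stats is not None:
        stats = fp.dataset.stats
        with open(out / "normalization_stats.tsv", "w") as fh:
            fh.write("feature\tmin\tmax\n")
            for n, lo, hi in zip(stats.feature_names, stats.mins, stats.maxs):
                fh.write(f"{n}\t{lo:.10g}\t{hi:.10g}\n")
    if fp.importance is not None:
        fp.importance.to_frame().to_csv(
            out / "importance.tsv", sep="\t", index=False, float_format="%.10g"
        )
    fp.scorer.save(out / "model.joblib")

    scores = fp.score_matrix()
    rows = []
    for d, m in adj.unlabeled_pairs():
        rows.append((index.diseases[d], index.mirnas[m], scores[d, m]))
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    with open(out / "predictions.tsv", "w") as fh:
        fh.write("disease\tmirna\tscore\n")
        for d, m, sc in rows:
            fh.write(f"{d}\t{m}\t{sc:.10g}\n")
    done(s)

    import sklearn

    manifest = {
        "config": config.to_dict(),
        "counts": {
            "diseases": index.nd,
            "mirnas": index.nm,
            "positives": adj.n_positive,
            "negatives": len(fp.dataset.samples) - adj.n_positive,
            "features_kept": fp.dataset.n_features,
        },
        "input_hashes": {
            name: _sha256(Path(p))
            for name, p in (
                ("associations", config.associations_path),
                ("dags", config.dags_path),
                ("functional", config.functional_path),
            )
            if p
        },
        "versions": {
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
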