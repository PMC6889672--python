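"""Ranking-based validation protocols.

Because the problem is positive-unlabeled, validation is by ranking: a
held-out known association is scored together with every unconfirmed pair
and its position in the descending-score order is recorded.  Protocols:

* **global LOOCV** — each positive is held out in turn and ranked against
  all unconfirmed pairs of the whole matrix;
* **local LOOCV** — the same, but the candidate set is restricted to the
  unconfirmed pairs of the test pair's disease;
* **repeated k-fold CV** — the positives are split evenly into k folds, each
  fold held out once, every held-out positive ranked globally.

Leakage policy: in the default ``strict`` mode the similarities, features,
normalization and feature selection are all rebuilt from the training-only
association matrix of each hold-out, so nothing about a test pair reaches
the model.  The ``paper-fast`` mode builds them once from the full matrix
and only retrains the forest per hold-out — cheaper, and the reading some
published pipelines use, but mildly optimistic.

The ROC/AUC machinery counts ties as half, so the AUC equals the
Mann-Whitney probability that a random positive outscores a random negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AdjacencyMatrix, DagCollection, SimilarityMatrix
from .pipeline import FittedPipeline, PipelineConfig, fit_pipeline

__all__ = [
    "RankResult",
    "RocCurve",
    "roc_auc",
    "auc_from_ranks",
    "global_loocv",
    "local_loocv",
    "kfold_cv",
    "summarize_kfold",
    "novel_disease_holdout",
]


@dataclass(frozen=True)
class RankResult:
    """One held-out positive: its score and rank among the candidates.

    ``rank`` is 1-based with ties assigned the mean rank;
    ``n_candidates`` counts the unlabeled pairs it was ranked against (so
    1 <= rank <= n_candidates + 1).
    """

    disease: str
    mirna: str
    score: float
    rank: float
    n_candidates: int
    protocol: str


@dataclass(frozen=True)
class RocCurve:
    points: pd.DataFrame  # columns fpr, tpr, nondecreasing from (0,0) to (1,1)
    auc: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC from scored positive/negative samples.

    The curve sweeps the decision threshold over the distinct score values,
    computing TPR = TP/(TP+FN) and FPR = FP/(FP+TN) at each; trapezoidal
    integration then counts tied scores as half, making the AUC the
    Mann-Whitney statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep only the last point of each tied-score run: one curve vertex per threshold
    boundary = np.append(sorted_scores[1:] != sorted_scores[:-1], True)
    tpr = np.concatenate(([0.0], tp[boundary] / n_pos))
    fpr = np.concatenate(([0.0], fp[boundary] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc)


def auc_from_ranks(results: list[RankResult]) -> float:
    """AUC implied by hold-out ranks.

    A positive at mean rank r among n unlabeled candidates outscores
    (n + 1 - r) of them (ties already averaged into r), so its per-positive
    AUC contribution is (n + 1 - r) / n; the protocol AUC is the mean.
    """
    if not results:
        raise ValueError("no rank results")
    contribs = [(r.n_candidates + 1 - r.rank) / r.n_candidates for r in results]
    return float(np.mean(contribs))


def _rank_among(score: float, candidates: np.ndarray) -> float:
    """1-based descending rank of ``score`` inside candidates + itself (mean ties)."""
    greater = int((candidates > score).sum())
    ties = int((candidates == score).sum())
    return 1.0 + greater + 0.5 * ties


def _holdout_fit(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig,
    test_pairs: set[tuple[int, int]],
    full_fit: FittedPipeline | None,
    seed: int,
) -> FittedPipeline:
    """One training fit with ``test_pairs`` excluded, per the leakage policy."""
    if config.leakage == "strict":
        return fit_pipeline(adj.mask_pairs(test_pairs), dags, mfsm, config, seed=seed)
    return full_fit.refit_without(test_pairs)


def _loocv(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig,
    scope: str,
) -> list[RankResult]:
    index = adj.index
    positives = adj.positive_pairs()
    if len(positives) < 2:
        raise ValueError("LOOCV requires at least two positives")
    unlabeled = adj.unlabeled_pairs()
    u_rows = np.array([d for d, _ in unlabeled])
    u_cols = np.array([m for _, m in unlabeled])

    full_fit = None
    if config.leakage == "paper-fast":
        full_fit = fit_pipeline(adj, dags, mfsm, config)

    if config.grouped_loocv:
        groups: dict[int, list[tuple[int, int]]] = {}
        for d, m in positives:
            groups.setdefault(d, []).append((d, m))
        batches = list(groups.values())
    else:
        batches = [[p] for p in positives]

    results: list[RankResult] = []
    for i, batch in enumerate(batches):
        fp = _holdout_fit(
            adj, dags, mfsm, config, set(batch), full_fit, seed=config.seed + i
        )
        scores = fp.score_matrix()
        u_scores = scores[u_rows, u_cols]
        for d, m in batch:
            if scope == "local":
                cand = u_scores[u_rows == d]
            else:
                cand = u_scores
            results.append(
                RankResult(
                    disease=index.diseases[d],
                    mirna=index.mirnas[m],
                    score=float(scores[d, m]),
                    rank=_rank_among(scores[d, m], cand),
                    n_candidates=int(cand.size),
                    protocol=f"{scope}-loocv",
                )
            )
    return results


def global_loocv(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig = PipelineConfig(),
) -> list[RankResult]:
    """Each positive held out and ranked against all unconfirmed pairs.

    With ``config.grouped_loocv`` one fit is shared by all positives of a
    disease (they are all masked together) — a desk-scale approximation, not
    the one-fit-per-positive protocol.
    """
    return _loocv(adj, dags, mfsm, config, "global")


def local_loocv(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig = PipelineConfig(),
) -> list[RankResult]:
    """As :func:`global_loocv`, candidates restricted to the test disease.

    A disease whose other miRNAs are all confirmed yields a candidate set of
    just the test pair itself (rank 1 of 1).
    """
    return _loocv(adj, dags, mfsm, config, "local")


def kfold_cv(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    config: PipelineConfig = PipelineConfig(),
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> list[list[RankResult]]:
    """Repeated k-fold CV over the positives; one rank list per repeat."""
    if k < 2:
        raise ValueError("k must be at least 2")
    positives = adj.positive_pairs()
    if len(positives) < k:
        raise ValueError(f"{len(positives)} positives cannot fill {k} folds")
    index = adj.index
    unlabeled = adj.unlabeled_pairs()
    u_rows = np.array([d for d, _ in unlabeled])
    u_cols = np.array([m for _, m in unlabeled])

    full_fit = None
    if config.leakage == "paper-fast":
        full_fit = fit_pipeline(adj, dags, mfsm, config)

    rng = np.random.default_rng(seed)
    all_repeats: list[list[RankResult]] = []
    for rep in range(repeats):
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        results: list[RankResult] = []
        for fold_no, fold in enumerate(folds):
            test = [positives[i] for i in fold]
            fp = _holdout_fit(
                adj, dags, mfsm, config, set(test), full_fit,
                seed=config.seed + rep * k + fold_no,
            )
            scores = fp.score_matrix()
            u_scores = scores[u_rows, u_cols]
            for d, m in test:
                results.append(
                    RankResult(
                        disease=index.diseases[d],
                        mirna=index.mirnas[m],
                        score=float(scores[d, m]),
                        rank=_rank_among(scores[d, m], u_scores),
                        n_candidates=int(u_scores.size),
                        protocol="kfold",
                    )
                )
        all_repeats.append(results)
    return all_repeats


def summarize_kfold(all_repeats: list[list[RankResult]]) -> dict[str, float]:
    """AUC of repeated k-fold CV, both ways of combining repeats.

    ``auc_mean_of_repeats`` averages each repeat's AUC; ``auc_pooled`` pools
    every rank across repeats first.  They coincide for one repeat.
    """
    per_repeat = [auc_from_ranks(r) for r in all_repeats]
    pooled = [r for rep in all_repeats for r in rep]
    return {
        "auc_mean_of_repeats": float(np.mean(per_repeat)),
        "auc_pooled": auc_from_ranks(pooled),
        "n_repeats": len(all_repeats),
    }


def novel_disease_holdout(
    adj: AdjacencyMatrix,
    dags: DagCollection | None,
    mfsm: SimilarityMatrix | None,
    disease: str,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Score all miRNAs for a disease stripped of its known associations.

    Emulates prediction for a disease with no validated partners: every
    association of ``disease`` is removed before similarities, features and
    the model are built, then all nm (disease, miRNA) pairs are scored and
    sorted descending.
    """
    index = adj.index
    d = index.disease_pos(disease)
    masked = adj.mask_pairs([(d, m) for m in range(index.nm)])
    fp = fit_pipeline(masked, dags, mfsm, config)
    scores = fp.score_matrix()[d]
    out = pd.DataFrame({"mirna": list(index.mirnas), "score": scores})
    out.insert(0, "disease", disease)
    return out.sort_values(
        ["score", "mirna"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
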