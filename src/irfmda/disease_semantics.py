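"""Disease semantic similarity from ontology ancestor DAGs.

Two contribution models are implemented.  Model 1 assigns a disease a
contribution of 1 to itself and decays the contribution of each ancestor by a
factor delta per layer, taking the maximum over in-DAG children when an
ancestor has several paths down to the disease.  Model 2 replaces the decay
with an information-content style score: the contribution of a term is
-log(fraction of disease DAGs containing it), so terms shared by every
disease contribute nothing and rare terms contribute most.

Either way, the similarity of two diseases is the contribution mass of their
shared DAG vertices divided by the sum of their total semantic values:

    sim(a, b) = sum_{v in S(a) & S(b)} (C_a(v) + C_b(v)) / (DS(a) + DS(b))

which is 1 on the diagonal for model 1 and lies in [0, 1] for both models.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .core_io import DagCollection, SimilarityMatrix

__all__ = [
    "contributions_model1",
    "contributions_model2",
    "semantic_value",
    "semantic_similarity",
]


def contributions_model1(dag: nx.DiGraph, disease: str, delta: float = 0.5) -> dict[str, float]:
    """Per-vertex decay contributions toward ``disease``.

    ``dag`` is oriented parent -> child with ``disease`` as the unique sink.
    The contribution of the disease to itself is 1; every ancestor gets
    delta times the maximum contribution among its children inside the DAG.

    Parameters
    ----------
    delta:
        Semantic contribution attenuation per layer, in (0, 1).
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    if disease not in dag:
        raise ValueError(f"disease {disease!r} not a vertex of its DAG")
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"DAG of {disease!r} contains a cycle")
    scores: dict[str, float] = {}
    # children must be scored before their parents: reversed topological order
    for v in reversed(list(nx.topological_sort(dag))):
        if v == disease:
            scores[v] = 1.0
            continue
        children = [c for c in dag.successors(v) if c in scores]
        if not children:
            raise ValueError(
                f"vertex {v!r} in DAG of {disease!r} has no path to the disease"
            )
        scores[v] = delta * max(scores[c] for c in children)
    return scores


def contributions_model2(dags: DagCollection) -> dict[str, float]:
    """Frequency-based contributions, shared across all DAGs.

    A vertex present in k of the n disease DAGs contributes -log(k / n),
    regardless of which DAG it is viewed from.  Natural log; the base cancels
    in the similarity ratio.
    """
    if len(dags) == 0:
        raise ValueError("empty DAG collection")
    n = len(dags)
    counts: dict[str, int] = {}
    for g in dags.dags.values():
        for v in g.nodes:
            counts[v] = counts.get(v, 0) + 1
    return {v: -math.log(k / n) for v, k in counts.items()}


def semantic_value(contributions: dict[str, float]) -> float:
    """Total semantic value of a disease: sum of its vertex contributions."""
    return float(sum(contributions.values()))


def semantic_similarity(
    dags: DagCollection, model: int = 1, delta: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity over all diseases of the collection.

    ``model`` selects the contribution scheme (1 decay, 2 frequency).  For
    model 2 a pair of diseases can both have semantic value 0 (every vertex
    shared by all DAGs); the ratio is then defined as 1 on the diagonal and 0
    off it, preserving self-similarity without inventing signal.
    """
    if model not in (1, 2):
        raise ValueError(f"model must be 1 or 2, got {model}")
    diseases = dags.diseases
    if model == 1:
        contribs = {
            d: contributions_model1(dags.dags[d], d, delta) for d in diseases
        }
    else:
        shared = contributions_model2(dags)
        contribs = {
            d: {v: shared[v] for v in dags.dags[d].nodes} for d in diseases
        }
    totals = {d: semantic_value(contribs[d]) for d in diseases}

    n = len(diseases)
    values = [[0.0] * n for _ in range(n)]
    for i, a in enumerate(diseases):
        for j in range(i, n):
            b = diseases[j]
            ca, cb = contribs[a], contribs[b]
            denom = totals[a] + totals[b]
            if denom == 0.0:
                sim = 1.0 if i == j else 0.0
            else:
                num = sum(ca[v] + cb[v] for v in ca.keys() & cb.keys())
                sim = num / denom
            values[i][j] = values[j][i] = sim
        if model == 1:
            values[i][i] = 1.0  # exact, avoids round-off in the ratio
    return SimilarityMatrix(
        np.asarray(values, dtype=float), diseases, f"semantic{model}"
    )
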