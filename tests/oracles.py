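"""Independent brute-force oracles and random-input generators for tests.

These deliberately re-derive quantities by explicit enumeration (recursive
definitions over explicit vertex sets, double loops, closed forms) so they
share no code path with the library implementations they check.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from irfmda.core_io import DagCollection


def random_dag_collection(
    rng: np.random.Generator,
    n_diseases: int = 4,
    max_ancestors: int = 6,
    n_shared_terms: int = 5,
) -> DagCollection:
    """Random forest of ancestor DAGs with <= 8 vertices each.

    Ancestor names are drawn from a shared pool so vertex sets of different
    diseases overlap.  Every ancestor is wired to at least one vertex closer
    to the disease, keeping the disease the unique sink.
    """
    terms = [f"T{i}" for i in range(n_shared_terms)]
    dags: dict[str, nx.DiGraph] = {}
    for k in range(n_diseases):
        disease = f"D{k}"
        n_anc = int(rng.integers(0, max_ancestors + 1))
        ancestors = list(rng.choice(terms, size=min(n_anc, len(terms)), replace=False))
        g = nx.DiGraph()
        g.add_node(disease)
        # order[i] may only point at later vertices -> acyclic, all reach sink
        order = ancestors + [disease]
        for i in range(len(ancestors)):
            targets = order[i + 1 :]
            n_edges = int(rng.integers(1, len(targets) + 1))
            for t in rng.choice(targets, size=n_edges, replace=False):
                g.add_edge(order[i], t)
        dags[disease] = g
    return DagCollection(dags)


def oracle_cs1(dag: nx.DiGraph, disease: str, delta: float) -> dict[str, float]:
    """Recursive evaluation of the decay contribution, memoized."""
    memo: dict[str, float] = {}

    def rec(v: str) -> float:
        if v in memo:
            return memo[v]
        if v == disease:
            memo[v] = 1.0
        else:
            memo[v] = delta * max(rec(c) for c in dag.successors(v))
        return memo[v]

    return {v: rec(v) for v in dag.nodes}


def oracle_semantic_matrix(
    dags: DagCollection, model: int, delta: float = 0.5, log_base: float = math.e
) -> np.ndarray:
    """Explicit-enumeration semantic similarity over sorted diseases.

    ``log_base`` lets the model-2 invariance to the logarithm base be
    checked directly.
    """
    diseases = sorted(dags.dags)
    n_total = len(diseases)
    vertex_sets = {d: set(dags.dags[d].nodes) for d in diseases}
    if model == 1:
        contribs = {d: oracle_cs1(dags.dags[d], d, delta) for d in diseases}
    else:
        def cs2(v: str) -> float:
            count = sum(1 for d in diseases if v in vertex_sets[d])
            return -math.log(count / n_total, log_base)

        contribs = {d: {v: cs2(v) for v in vertex_sets[d]} for d in diseases}
    out = np.zeros((len(diseases), len(diseases)))
    for i, a in enumerate(diseases):
        for j, b in enumerate(diseases):
            shared = vertex_sets[a] & vertex_sets[b]
            num = sum(contribs[a][v] + contribs[b][v] for v in shared)
            den = sum(contribs[a].values()) + sum(contribs[b].values())
            if den == 0:
                out[i, j] = 1.0 if i == j else 0.0
            else:
                out[i, j] = num / den
    if model == 1:
        np.fill_diagonal(out, 1.0)
    return out


def oracle_gipk(profiles: np.ndarray, alpha_prime: float = 1.0) -> np.ndarray:
    """Double-loop kernel evaluation."""
    x = np.asarray(profiles, dtype=float)
    n = x.shape[0]
    alpha = alpha_prime / np.mean([np.dot(r, r) for r in x])
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = x[i] - x[j]
            out[i, j] = math.exp(-alpha * float(np.dot(diff, diff)))
    return out


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Closed-form AUC: fraction of (positive, negative) pairs won, ties half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
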