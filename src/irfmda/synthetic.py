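"""Synthetic planted-world generator and hand-checkable micro-fixtures.

The generator builds a desk-scale bipartite world with the statistical
structure the predictor assumes: diseases and miRNAs fall into latent
groups, associations are Bernoulli draws that are denser within a group
(p_in) than across (p_out), same-group diseases share ontology ancestors so
their semantic similarity is high, and the functional similarity of miRNAs
is inflated within a group.  A configurable fraction of diseases lacks a
DAG and a fraction of miRNAs is absent from the functional matrix,
mirroring real inputs where ontology descriptors and precomputed functional
scores never cover every entity — those entities exercise the kernel
fallback of the integration step.

Real data differ in ways the generator does not emulate: ontology DAGs are
deep multi-parent hierarchies rather than short shared chains, association
degrees are heavy-tailed, and group structure is soft.  Passing end-to-end
tests on this world therefore shows the machinery recovers planted block
signal, not that any particular real-data AUC is attainable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import (
    AdjacencyMatrix,
    AssociationTable,
    DagCollection,
    EntityIndex,
    SimilarityMatrix,
    build_adjacency,
    write_associations,
    write_dag_collection,
    write_similarity_matrix,
)

__all__ = ["PlantedWorld", "make_planted_world", "write_world", "make_toy_paper_instances", "ToyFixture"]


@dataclass(frozen=True)
class PlantedWorld:
    index: EntityIndex
    disease_groups: np.ndarray
    mirna_groups: np.ndarray
    prob_matrix: np.ndarray
    associations: AssociationTable
    adjacency: AdjacencyMatrix
    dags: DagCollection
    functional: SimilarityMatrix
    seed: int
    params: dict


def _group_assignment(n: int, groups: int) -> np.ndarray:
    """Contiguous, near-even group labels 0..groups-1."""
    return np.array([i * groups // n for i in range(n)])


def make_planted_world(
    nd: int = 40,
    nm: int = 60,
    groups: int = 4,
    p_in: float = 0.35,
    p_out: float = 0.02,
    seed: int = 0,
    dag_coverage: float = 0.9,
    functional_coverage: float = 1.0,
    functional_boost: float = 0.6,
    functional_noise: float = 0.2,
) -> PlantedWorld:
    """Sample a planted bipartite world, reproducible from ``seed``.

    Parameters
    ----------
    nd, nm, groups:
        Entity counts and number of latent groups shared by both axes.
    p_in, p_out:
        Association probability within / across groups; the planted signal
        strength is their gap (p_in = p_out gives a null world).
    dag_coverage, functional_coverage:
        Fraction of diseases given an ontology DAG and of miRNAs present in
        the functional matrix; the rest fall through to the kernel branch of
        the integration rule.  Defaults mirror typical real inputs: the
        precomputed functional matrix covers every miRNA, while some disease
        names have no ontology descriptor.
    functional_boost, functional_noise:
        Within-group additive boost and uniform noise scale of the generated
        functional similarity.
    """
    if not (nd >= groups >= 1 and nm >= groups):
        raise ValueError("need nd, nm >= groups >= 1")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    if not (0.0 <= dag_coverage <= 1.0 and 0.0 <= functional_coverage <= 1.0):
        raise ValueError("coverage fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    diseases = tuple(f"disease_{i:03d}" for i in range(nd))
    mirnas = tuple(f"mirna_{i:03d}" for i in range(nm))
    index = EntityIndex(diseases, mirnas)
    d_groups = _group_assignment(nd, groups)
    m_groups = _group_assignment(nm, groups)

    same = d_groups[:, None] == m_groups[None, :]
    probs = np.where(same, p_in, p_out)
    draw = (rng.random((nd, nm)) < probs).astype(np.int8)
    if draw.sum() == 0:  # degenerate draw at tiny sizes: plant one pair
        draw[0, 0] = 1
    pairs = frozenset(
        (diseases[d], mirnas[m]) for d, m in zip(*np.nonzero(draw))
    )
    assoc = AssociationTable(pairs)
    adj = build_adjacency(assoc, index)

    # one ancestor chain per group under a global root: same-group diseases
    # share two ancestors, cross-group diseases only the root
    dag_mask = rng.random(nd) < dag_coverage
    dags: dict[str, nx.DiGraph] = {}
    for i, name in enumerate(diseases):
        if not dag_mask[i]:
            continue
        g = nx.DiGraph()
        anc = f"ancestor_g{d_groups[i]}"
        g.add_edge("ancestor_root", anc)
        g.add_edge(anc, name)
        dags[name] = g
    dag_collection = DagCollection(dags)

    fn_mask = rng.random(nm) < functional_coverage
    covered = [m for i, m in enumerate(mirnas) if fn_mask[i]]
    kk = len(covered)
    cg = m_groups[fn_mask]
    base = rng.uniform(0.0, functional_noise, (kk, kk))
    base += np.where(cg[:, None] == cg[None, :], functional_boost, 0.0)
    base = np.clip((base + base.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(base, 1.0)
    functional = SimilarityMatrix(base, tuple(covered), "functional")

    params = {
        "nd": nd, "nm": nm, "groups": groups, "p_in": p_in, "p_out": p_out,
        "dag_coverage": dag_coverage, "functional_coverage": functional_coverage,
        "functional_boost": functional_boost, "functional_noise": functional_noise,
    }
    return PlantedWorld(
        index, d_groups, m_groups, probs, assoc, adj, dag_collection,
        functional, seed, params,
    )


def write_world(world: PlantedWorld, out_dir: str | Path) -> Path:
    """Write associations.tsv, dags.tsv, similarity.tsv and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_associations(world.associations, out / "associations.tsv")
    write_dag_collection(world.dags, out / "dags.tsv")
    write_similarity_matrix(world.functional, out / "similarity.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": world.seed, "params": world.params}, fh, indent=2, sort_keys=True)
    return out


@dataclass(frozen=True)
class ToyFixture:
    """A micro input with hand-computed expected values as a sidecar."""

    name: str
    inputs: dict
    expected: dict[str, float]


def make_toy_paper_instances() -> dict[str, ToyFixture]:
    """Hand-checkable fixtures used throughout the test suite.

    Expected values were evaluated by hand from the defining formulas:

    * parent/child DAG chain (decay 0.5): sim(D, P) = (0.5 + 1) / (1.5 + 1) = 0.6
    * sibling pair under one root: model-1 sim = (0.5 + 0.5) / 3 = 1/3; the
      only shared vertex of the siblings appears in all three DAGs, so its
      frequency contribution is -log(1) = 0 and model-2 sim = 0
    * kernel toy, profiles (1,0,1) and (1,1,0): mean squared norm 2 gives
      bandwidth 1/2, squared distance 2, off-diagonal exp(-1)
    * min-max column (0.2, 0.5, 0.8) -> (0, 0.5, 1)
    * scores pos {0.9, 0.7} vs neg {0.8, 0.1}: 3 of 4 positive-negative
      comparisons won -> AUC 0.75
    """
    parent_child = nx.DiGraph()
    parent_child.add_edge("P", "D")
    root_p = nx.DiGraph()
    root_p.add_node("P")
    pc = DagCollection({"D": parent_child, "P": root_p})

    d1 = nx.DiGraph(); d1.add_edge("R", "D1")
    d2 = nx.DiGraph(); d2.add_edge("R", "D2")
    r = nx.DiGraph(); r.add_node("R")
    siblings = DagCollection({"D1": d1, "D2": d2, "R": r})

    return {
        "parent_child": ToyFixture(
            "parent_child", {"dags": pc}, {"dss1_D_P": 0.6},
        ),
        "sibling": ToyFixture(
            "sibling", {"dags": siblings},
            {"dss1_D1_D2": 1.0 / 3.0, "dss2_D1_D2": 0.0, "dss2_D1_D1": 1.0},
        ),
        "gipk": ToyFixture(
            "gipk",
            {"profiles": np.array([[1, 0, 1], [1, 1, 0]]), "labels": ("a", "b")},
            {"alpha": 0.5, "offdiag": float(np.exp(-1.0))},
        ),
        "normalize": ToyFixture(
            "normalize",
            {"column": np.array([0.2, 0.5, 0.8])},
            {"lo": 0.0, "mid": 0.5, "hi": 1.0},
        ),
        "roc": ToyFixture(
            "roc",
            {
                "scores": np.array([0.9, 0.7, 0.8, 0.1]),
                "labels": np.array([1, 1, 0, 0]),
            },
            {"auc": 0.75, "tpr_top2": 0.5, "fpr_top2": 0.5},
        ),
    }
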