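"""File formats and indexed containers for the association data.

The pipeline works on three external inputs: a two-column table of
experiment-supported disease-miRNA associations, a per-disease edge list of
ontology ancestor DAGs, and an optional precomputed miRNA functional
similarity matrix.  Everything downstream is keyed by the :class:`EntityIndex`
built from the association table, so name handling (trimming, case,
uniqueness) is concentrated here.

All tabular formats are TSV.  Similarity matrices are written with a header
row and a first label column, values at 10 significant digits, which
round-trips exactly through :func:`load_similarity_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EntityIndex",
    "AssociationTable",
    "AdjacencyMatrix",
    "SimilarityMatrix",
    "DagCollection",
    "load_associations",
    "write_associations",
    "build_adjacency",
    "load_dag_collection",
    "write_dag_collection",
    "load_similarity_matrix",
    "write_similarity_matrix",
]

#: tolerance for symmetry of similarity matrices read from disk
SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered disease and miRNA name lists defining all matrix axes."""

    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]
    _disease_pos: Mapping[str, int] = field(repr=False, compare=False, default=None)
    _mirna_pos: Mapping[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease names in index")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValueError("duplicate miRNA names in index")
        object.__setattr__(
            self, "_disease_pos", {n: i for i, n in enumerate(self.diseases)}
        )
        object.__setattr__(
            self, "_mirna_pos", {n: i for i, n in enumerate(self.mirnas)}
        )

    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def nm(self) -> int:
        return len(self.mirnas)

    def disease_pos(self, name: str) -> int:
        try:
            return self._disease_pos[name]
        except KeyError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def mirna_pos(self, name: str) -> int:
        try:
            return self._mirna_pos[name]
        except KeyError:
            raise KeyError(f"unknown miRNA: {name!r}") from None


@dataclass(frozen=True)
class AssociationTable:
    """Set of experiment-supported (disease, miRNA) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def entity_index(self) -> EntityIndex:
        """Index over the names occurring in the table, sorted for determinism."""
        diseases = tuple(sorted({d for d, _ in self.pairs}))
        mirnas = tuple(sorted({m for _, m in self.pairs}))
        return EntityIndex(diseases, mirnas)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary nd x nm association matrix.

    Rows are disease interaction profiles, columns are miRNA interaction
    profiles; both views feed the Gaussian interaction profile kernel.
    """

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (self.index.nd, self.index.nm):
            raise ValueError(
                f"adjacency shape {v.shape} does not match index "
                f"({self.index.nd}, {self.index.nm})"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """(disease index, miRNA index) of every known association, row-major."""
        di, mi = np.nonzero(self.values)
        return list(zip(di.tolist(), mi.tolist()))

    def unlabeled_pairs(self) -> list[tuple[int, int]]:
        """All zero cells — the unconfirmed pairs scored by the model."""
        di, mi = np.nonzero(self.values == 0)
        return list(zip(di.tolist(), mi.tolist()))

    def mask_pairs(self, pairs: Iterable[tuple[int, int]]) -> "AdjacencyMatrix":
        """Copy with the given cells zeroed (hold-out construction)."""
        v = self.values.copy()
        for d, m in pairs:
            v[d, m] = 0
        return AdjacencyMatrix(v, self.index)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labeled symmetric matrix of pairwise scores.

    ``kind`` tags the provenance: semantic1 | semantic2 | gipk | functional |
    integrated.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    kind: str = "functional"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValueError("similarity matrix is not symmetric")
        if (v < -1e-12).any():
            raise ValueError("similarity entries must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def reindex(self, labels: Iterable[str], fill: float | np.ndarray = 0.0,
                kind: str | None = None) -> "SimilarityMatrix":
        """Embed into a (possibly larger) label set; missing entries get ``fill``.

        ``fill`` may be a full matrix over the new labels (used when a kernel
        matrix backs the uncovered entries); own entries always win.
        """
        labels = tuple(labels)
        n = len(labels)
        if isinstance(fill, np.ndarray):
            out = fill.astype(float).copy()
            if out.shape != (n, n):
                raise ValueError("fill matrix shape does not match labels")
        else:
            out = np.full((n, n), float(fill))
        pos = {l: i for i, l in enumerate(labels)}
        own = [pos[l] for l in self.labels if l in pos]
        keep = [i for i, l in enumerate(self.labels) if l in pos]
        out[np.ix_(own, own)] = self.values[np.ix_(keep, keep)]
        return SimilarityMatrix(out, labels, kind or self.kind)


@dataclass(frozen=True)
class DagCollection:
    """Per-disease ancestor DAGs.

    Each graph is directed parent -> child and contains the disease itself
    plus all of its ancestral terms; the disease is the unique sink.  The
    collection size doubles as the disease universe for the frequency-based
    contribution model.
    """

    dags: Mapping[str, nx.DiGraph]

    def __len__(self) -> int:
        return len(self.dags)

    def __contains__(self, disease: str) -> bool:
        return disease in self.dags

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.dags))

    def vertex_set(self, disease: str) -> frozenset[str]:
        return frozenset(self.dags[disease].nodes)

    def dag_count(self, vertex: str) -> int:
        """Number of DAGs whose vertex set contains ``vertex``."""
        return sum(1 for g in self.dags.values() if vertex in g)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path, n_cols: int) -> list[tuple[str, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < n_cols:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, found {len(parts)}"
                )
            rows.append(tuple(parts[:n_cols]))
    return rows


def load_associations(path: str | Path) -> tuple[AssociationTable, EntityIndex]:
    """Read a ``disease<TAB>mirna`` table; duplicates collapse to one pair.

    An optional literal ``disease / mirna`` header row is skipped.  Names are
    whitespace-trimmed but matched case-sensitively: silent case folding would
    hide curation errors in the source database.
    """
    rows = _read_tsv_rows(path, 2)
    if rows and tuple(s.lower() for s in rows[0]) == ("disease", "mirna"):
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{Path(path).name}: no associations")
    pairs = frozenset(rows)
    table = AssociationTable(pairs)
    return table, table.entity_index()


def write_associations(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, m in sorted(table.pairs):
            fh.write(f"{d}\t{m}\n")


def build_adjacency(assoc: AssociationTable, index: EntityIndex) -> AdjacencyMatrix:
    """Binary matrix with a 1 wherever the table confirms the pair."""
    values = np.zeros((index.nd, index.nm), dtype=np.int8)
    for d, m in assoc.pairs:
        values[index.disease_pos(d), index.mirna_pos(m)] = 1
    return AdjacencyMatrix(values, index)


#: sentinel parent marking a root-only disease in the DAG edge list
ROOT_SENTINEL = "-"


def load_dag_collection(path: str | Path) -> DagCollection:
    """Read a ``disease<TAB>child<TAB>parent`` ancestor edge list.

    A row ``D<TAB>D<TAB>-`` declares a root disease whose DAG is the single
    vertex ``D``.  Every graph must be acyclic, contain its own disease, and
    have every vertex on a path down to the disease (the DAG holds only the
    disease and its ancestors, so anything else is malformed).
    """
    rows = _read_tsv_rows(path, 3)
    if not rows:
        raise FormatError(f"{Path(path).name}: no DAG edges")
    dags: dict[str, nx.DiGraph] = {}
    for disease, child, parent in rows:
        g = dags.setdefault(disease, nx.DiGraph())
        g.add_node(disease)
        if parent == ROOT_SENTINEL:
            g.add_node(child)
            continue
        g.add_edge(parent, child)
    for disease, g in dags.items():
        if disease not in g:
            raise FormatError(f"disease {disease!r} absent from its own DAG")
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError(f"cycle detected in DAG of disease {disease!r}")
        reaches = nx.ancestors(g, disease) | {disease}
        stray = set(g.nodes) - reaches
        if stray:
            raise FormatError(
                f"DAG of disease {disease!r} has vertices with no path to it: "
                f"{sorted(stray)}"
            )
    return DagCollection(dags)


def write_dag_collection(dags: DagCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for disease in dags.diseases:
            g = dags.dags[disease]
            if g.number_of_edges() == 0:
                fh.write(f"{disease}\t{disease}\t{ROOT_SENTINEL}\n")
                continue
            for parent, child in sorted(g.edges):
                fh.write(f"{disease}\t{child}\t{parent}\n")


def load_similarity_matrix(path: str | Path, kind: str = "functional") -> SimilarityMatrix:
    """Read a square labeled TSV; symmetry is enforced within 1e-8."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path.name}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path.name}: row labels differ from column labels")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path.name}: non-numeric or missing cell")
    if not np.allclose(values, values.T, atol=SYMMETRY_TOL, rtol=0.0):
        worst = float(np.abs(values - values.T).max())
        raise FormatError(
            f"{path.name}: asymmetric beyond tolerance (max deviation {worst:.3g})"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, tuple(str(l) for l in df.index), kind)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """TSV with header row + first label column, 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(sim.labels) + "\n")
        for i, label in enumerate(sim.labels):
            cells = "\t".join(f"{x:.10g}" for x in sim.values[i])
            fh.write(f"{label}\t{cells}\n")
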