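import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irfmda.core_io import (
    AssociationTable,
    EntityIndex,
    FormatError,
    SimilarityMatrix,
    build_adjacency,
    load_associations,
    load_dag_collection,
    load_similarity_matrix,
    write_dag_collection,
    write_similarity_matrix,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadAssociations:
    def test_duplicates_collapse_and_names_trim(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "d1\tm1\nd1\tm1\n d2 \tm2\n")
        table, index = load_associations(p)
        assert table.pairs == {("d1", "m1"), ("d2", "m2")}
        assert index.diseases == ("d1", "d2")

    def test_optional_header_skipped_case_preserved(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "disease\tmirna\nLung Cancer\thsa-mir-21\n")
        table, index = load_associations(p)
        assert table.pairs == {("Lung Cancer", "hsa-mir-21")}

    def test_empty_file_errors(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "\n\n")
        with pytest.raises(FormatError, match="no associations"):
            load_associations(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "d1\tm1\nonly-one-column\n")
        with pytest.raises(FormatError, match=":2"):
            load_associations(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_associations(tmp_path / "nope.tsv")


class TestBuildAdjacency:
    def test_single_pair(self):
        index = EntityIndex(("d1", "d2"), ("m1", "m2"))
        adj = build_adjacency(AssociationTable(frozenset({("d1", "m1")})), index)
        assert adj.values.tolist() == [[1, 0], [0, 0]]

    def test_empty_table_all_zero(self):
        index = EntityIndex(("d1", "d2"), ("m1", "m2"))
        adj = build_adjacency(AssociationTable(frozenset()), index)
        assert adj.values.sum() == 0

    def test_row_sums_of_hand_enumerated_pairs(self):
        # d1 pairs with m1 and m3; d2 with m2 -> row sums (2, 1)
        index = EntityIndex(("d1", "d2"), ("m1", "m2", "m3"))
        pairs = frozenset({("d1", "m1"), ("d1", "m3"), ("d2", "m2")})
        adj = build_adjacency(AssociationTable(pairs), index)
        assert adj.values.sum(axis=1).tolist() == [2, 1]

    def test_unknown_name_reported(self):
        index = EntityIndex(("d1",), ("m1",))
        with pytest.raises(KeyError, match="dX"):
            build_adjacency(AssociationTable(frozenset({("dX", "m1")})), index)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.sets(st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=1, max_size=20))
    def test_total_equals_pair_count(self, cells):
        pairs = frozenset((f"d{i}", f"m{j}") for i, j in cells)
        table = AssociationTable(pairs)
        adj = build_adjacency(table, table.entity_index())
        assert adj.values.sum() == len(pairs)


class TestDagCollection:
    def test_single_edge(self, tmp_path):
        p = _write(tmp_path, "dags.tsv", "D\tD\tP\n")
        dags = load_dag_collection(p)
        assert dags.vertex_set("D") == {"D", "P"}
        assert list(dags.dags["D"].edges) == [("P", "D")]

    def test_cycle_rejected_naming_disease(self, tmp_path):
        p = _write(tmp_path, "dags.tsv", "D\tD\tP\nD\tP\tD\n")
        with pytest.raises(FormatError, match="'D'"):
            load_dag_collection(p)

    def test_sibling_forest(self, tmp_path):
        p = _write(tmp_path, "dags.tsv", "D1\tD1\tR\nD2\tD2\tR\nR\tR\t-\n")
        dags = load_dag_collection(p)
        assert dags.vertex_set("D1") == {"D1", "R"}
        assert dags.vertex_set("D2") == {"D2", "R"}
        assert dags.vertex_set("R") == {"R"}
        assert dags.dag_count("R") == 3

    def test_stray_vertex_rejected(self, tmp_path):
        # X -> Y is disconnected from D: neither is an ancestor of D
        p = _write(tmp_path, "dags.tsv", "D\tD\tP\nD\tY\tX\n")
        with pytest.raises(FormatError, match="no path"):
            load_dag_collection(p)

    def test_vertex_sets_closed_under_parent_relation(self, tmp_path):
        p = _write(tmp_path, "dags.tsv", "D\tD\tP\nD\tP\tG\nE\tE\tG\n")
        dags = load_dag_collection(p)
        for disease, g in dags.dags.items():
            s = dags.vertex_set(disease)
            assert all(u in s and v in s for u, v in g.edges)

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, "dags.tsv", "D\tD\tP\nD\tP\tG\nR\tR\t-\n")
        dags = load_dag_collection(p)
        out = tmp_path / "out.tsv"
        write_dag_collection(dags, out)
        again = load_dag_collection(out)
        assert {d: set(g.edges) for d, g in dags.dags.items()} == {
            d: set(g.edges) for d, g in again.dags.items()
        }


class TestSimilarityMatrixIO:
    def test_valid_2x2(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "\ta\tb\na\t1\t0.4\nb\t0.4\t1\n")
        sim = load_similarity_matrix(p)
        assert sim.loc("a", "b") == pytest.approx(0.4)
        assert sim.kind == "functional"

    def test_identity_3x3(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "\ta\tb\tc\na\t1\t0\t0\nb\t0\t1\t0\nc\t0\t0\t1\n")
        sim = load_similarity_matrix(p)
        assert np.array_equal(sim.values, np.eye(3))

    def test_asymmetry_rejected(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "\ta\tb\na\t1\t0.4\nb\t0.5\t1\n")
        with pytest.raises(FormatError, match="asymmetric"):
            load_similarity_matrix(p)

    def test_non_square_rejected(self, tmp_path):
        p = _write(tmp_path, "s.tsv", "\ta\tb\na\t1\t0.4\n")
        with pytest.raises(FormatError):
            load_similarity_matrix(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        base = np.round(rng.uniform(0, 1, (5, 5)), 4)
        values = (base + base.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values, tuple("abcde"), "gipk")
        path = tmp_path / "s.tsv"
        write_similarity_matrix(sim, path)
        again = load_similarity_matrix(path, kind="gipk")
        assert again.labels == sim.labels
        np.testing.assert_allclose(again.values, sim.values, rtol=1e-9, atol=0)
        # a second write of the re-read matrix is byte-stable
        path2 = tmp_path / "s2.tsv"
        write_similarity_matrix(again, path2)
        assert path.read_bytes() == path2.read_bytes()
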