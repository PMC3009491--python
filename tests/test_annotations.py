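import math

import hypothesis.strategies as st
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings

from generank import (
    AnnotationTable,
    build_knn_graph,
    compute_information_content,
    gene_similarity,
    load_annotations,
    rank_with_rwr,
)


def table_from(entries):
    return AnnotationTable(ontology_label="BP", entries=entries)


@st.composite
def annotation_tables(draw):
    n_genes = draw(st.integers(min_value=2, max_value=12))
    term_pool = [f"T{i}" for i in range(draw(st.integers(3, 10)))]
    entries = {}
    for i in range(n_genes):
        terms = draw(st.sets(st.sampled_from(term_pool), min_size=1))
        entries[f"g{i:02d}"] = terms
    return table_from(entries)


class TestInformationContent:
    def test_ubiquitous_term_has_zero_ic(self):
        table = table_from({f"g{i}": {"T", f"U{i}"} for i in range(100)})
        ic = compute_information_content(table)
        assert ic["T"] == 0.0

    def test_natural_log_value(self):
        # 8 genes, term annotating 2 of them: IC = ln(8/2) = ln 4
        entries = {f"g{i}": {"T"} if i < 2 else {f"U{i}"} for i in range(8)}
        ic = compute_information_content(table_from(entries))
        assert ic["T"] == pytest.approx(math.log(4), abs=1e-12)

    @given(annotation_tables())
    @settings(max_examples=50, deadline=None)
    def test_singleton_terms_are_maximal_and_ic_monotone(self, table):
        ic = compute_information_content(table)
        counts = {}
        for terms in table.entries.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        top = max(ic.values())
        for t, n_t in counts.items():
            assert ic[t] >= 0
            if n_t == 1:
                assert ic[t] == pytest.approx(top)
        # monotone non-increasing in n_t
        for t1, c1 in counts.items():
            for t2, c2 in counts.items():
                if c1 < c2:
                    assert ic[t1] >= ic[t2]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no annotations"):
            compute_information_content(table_from({}))


class TestGeneSimilarity:
    def test_disjoint_term_sets_score_zero(self, small_table):
        ic = compute_information_content(small_table)
        assert gene_similarity("g1", "g4", small_table, ic) == 0.0

    def test_identical_term_sets_sum_squared_ic(self):
        table = table_from({"a": {"T1", "T2"}, "b": {"T1", "T2"}})
        ic = {"T1": 1.0, "T2": 2.0}
        assert gene_similarity("a", "b", table, ic) == pytest.approx(5.0)

    def test_self_similarity_is_squared_norm(self, small_table):
        ic = compute_information_content(small_table)
        expected = sum(ic[t] ** 2 for t in small_table.entries["g2"])
        assert gene_similarity("g2", "g2", small_table, ic) == pytest.approx(expected)

    def test_missing_gene_named_in_error(self, small_table):
        ic = compute_information_content(small_table)
        with pytest.raises(KeyError, match="nope"):
            gene_similarity("g1", "nope", small_table, ic)

    @given(annotation_tables())
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force_and_symmetry(self, table):
        ic = compute_information_content(table)
        genes = table.genes
        for g1 in genes[:4]:
            for g2 in genes[:4]:
                brute = sum(
                    ic[t] ** 2
                    for t in table.entries[g1] | table.entries[g2]
                    if t in table.entries[g1] and t in table.entries[g2]
                )
                s = gene_similarity(g1, g2, table, ic)
                assert s == pytest.approx(brute)
                assert s == pytest.approx(gene_similarity(g2, g1, table, ic))


class TestKnnGraph:
    def test_k_covering_all_gives_complete_graph(self):
        # each pair shares one non-ubiquitous term, so all similarities > 0
        table = table_from({"a": {"T1", "T2"}, "b": {"T1", "T3"}, "c": {"T2", "T3"}})
        ic = compute_information_content(table)
        g = build_knn_graph(table, ic, k=2)
        assert set(g.edges) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_zero_similarity_gene_stays_isolated(self):
        table = table_from(
            {"g1": {"T1"}, "g2": {"T1"}, "g3": {"T1", "T2"}, "g4": {"X"}}
        )
        ic = compute_information_content(table)
        g = build_knn_graph(table, ic, k=1)
        assert g.degree("g4") == 0
        assert "g4" in g.nodes

    def test_edge_weights_equal_similarity(self, small_table):
        ic = compute_information_content(small_table)
        g = build_knn_graph(small_table, ic, k=2)
        for a, b, data in g.edges(data=True):
            assert data["weight"] == pytest.approx(
                gene_similarity(a, b, small_table, ic)
            )

    def test_k_too_large_rejected(self, small_table):
        ic = compute_information_content(small_table)
        with pytest.raises(ValueError):
            build_knn_graph(small_table, ic, k=4)

    @given(annotation_tables())
    @settings(max_examples=30, deadline=None)
    def test_degree_lower_bound(self, table):
        ic = compute_information_content(table)
        k = 2
        if len(table) <= k:
            return
        g = build_knn_graph(table, ic, k=k)
        for gene in table.genes:
            n_pos = sum(
                1
                for other in table.genes
                if other != gene and gene_similarity(gene, other, table, ic) > 0
            )
            assert g.degree(gene) >= min(k, n_pos)


def test_ic_log_base_does_not_change_downstream_ranks(rng):
    """Rescaling all IC values by a constant leaves KNN edges and RWR
    rankings unchanged: the transition matrix is column-normalized."""
    genes = [f"g{i:02d}" for i in range(20)]
    pool = [f"T{i}" for i in range(15)]
    entries = {
        g: set(rng.choice(pool, size=rng.integers(2, 6), replace=False))
        for g in genes
    }
    table = AnnotationTable(ontology_label="BP", entries=entries)
    ranks = {}
    for base in (math.e, 2):
        ic = compute_information_content(table, base=None if base is math.e else base)
        net = build_knn_graph(table, ic, k=3)
        rl = rank_with_rwr(net, set(genes[:3]), genes[3:], gamma=0.7)
        ranks[base] = rl.ranks
    assert ranks[math.e] == ranks[2]


def test_load_annotations_roundtrip(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("# comment\ng1\tT1\tP\ng1\tT2\tP\ng2\tT1\tP\n")
    table = load_annotations(str(p))
    assert table.ontology_label == "BP"
    assert table.entries == {"g1": {"T1", "T2"}, "g2": {"T1"}}
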