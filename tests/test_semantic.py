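"""Information content, Resnik distance against a brute-force ancestor
oracle, bubble expansion, pruning and centrality ranking."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from methylsift.semantic import (
    AnnotationCorpus,
    GeneCentralityRanking,
    SemanticConfig,
    SemanticIndex,
    bubble_cliques,
    genes_to_probes,
    propagate_annotations,
    prune_gene_terms,
    rank_gene_centrality,
)
from methylsift.preselect import union_preselect
from methylsift.simulate import ProbeAnnotation
import pandas as pd


def build_dag(edges):
    g = nx.DiGraph()
    for child, parent in edges:
        g.add_edge(child, parent, relation="is_a")
    return g


@pytest.fixture
def toy_dag():
    #        root
    #       /    \
    #      A      B
    #     / \      \
    #    C   D      E
    g = build_dag([("A", "root"), ("B", "root"), ("C", "A"), ("D", "A"), ("E", "B")])
    corpus = AnnotationCorpus.from_gene2terms(
        {
            "g1": {"C"},
            "g2": {"C", "D"},
            "g3": {"D"},
            "g4": {"E"},
            "g5": {"E"},
            "g6": {"B"},
            "g7": {"A"},
            "g8": {"root"},
        }
    )
    return g, corpus


def brute_force_resnik_distance(graph, prop_corpus, t1, t2):
    """Oracle: enumerate ALL common ancestors explicitly and take the
    best IC by direct counting."""
    n_total = len(prop_corpus.gene2terms)

    def ancestors(t):
        out = {t}
        frontier = [t]
        while frontier:
            node = frontier.pop()
            for parent in graph.successors(node):
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out

    common = ancestors(t1) & ancestors(t2)
    ics = [
        -math.log(len(prop_corpus.term2genes[t]) / n_total)
        for t in common
        if t in prop_corpus.term2genes
    ]
    all_ics = [
        -math.log(len(g) / n_total) for g in prop_corpus.term2genes.values()
    ]
    return 1.0 - max(ics) / max(all_ics)


class TestPropagation:
    def test_leaf_gene_counted_at_root(self, toy_dag):
        g, corpus = toy_dag
        prop = propagate_annotations(g, corpus)
        assert "g1" in prop.term2genes["root"]
        assert prop.term2genes["root"] == frozenset(corpus.gene2terms)

    def test_idempotent(self, toy_dag):
        g, corpus = toy_dag
        once = propagate_annotations(g, corpus)
        twice = propagate_annotations(g, once)
        assert once.gene2terms == twice.gene2terms

    def test_counts_monotone_child_to_parent(self, toy_dag):
        g, corpus = toy_dag
        prop = propagate_annotations(g, corpus)
        for child, parent in g.edges():
            if child in prop.term2genes and parent in prop.term2genes:
                assert len(prop.term2genes[child]) <= len(prop.term2genes[parent])

    def test_unknown_term_dropped_with_warning(self, toy_dag):
        g, _ = toy_dag
        corpus = AnnotationCorpus.from_gene2terms({"g1": {"C", "NOPE"}})
        with pytest.warns(UserWarning, match="unknown"):
            prop = propagate_annotations(g, corpus)
        assert "NOPE" not in prop.gene2terms["g1"]


class TestInformationContent:
    def test_root_is_zero(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        assert index.information_content("root") == pytest.approx(0.0)

    def test_half_corpus_term(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        # A covers g1,g2,g3,g7 = 4 of 8 genes
        assert index.information_content("A") == pytest.approx(math.log(2))

    def test_one_of_eight(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        assert index.information_content("C") == pytest.approx(math.log(8 / 2))  # C: g1,g2
        corpus2 = AnnotationCorpus.from_gene2terms(
            {**{f"x{i}": {"E"} for i in range(7)}, "solo": {"C"}}
        )
        index2 = SemanticIndex(g, corpus2)
        assert index2.information_content("C") == pytest.approx(math.log(8))

    def test_unannotated_term_query_raises(self):
        g = build_dag([("A", "root")])
        corpus = AnnotationCorpus.from_gene2terms({"g1": {"A"}})
        index = SemanticIndex(g, corpus)
        with pytest.raises(KeyError):
            index.information_content("Z")


class TestResnikDistance:
    def test_matches_brute_force_on_all_pairs(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        prop = index.propagated
        terms = sorted(prop.term2genes)
        for t1, t2 in itertools.combinations_with_replacement(terms, 2):
            expected = brute_force_resnik_distance(g, prop, t1, t2)
            assert index.resnik_distance(t1, t2) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_generated_ontology(self, toy_ontology):
        g, corpus, _ = toy_ontology
        index = SemanticIndex(g, corpus)
        terms = sorted(index.propagated.term2genes)[:15]
        for t1, t2 in itertools.combinations(terms, 2):
            expected = brute_force_resnik_distance(g, index.propagated, t1, t2)
            assert index.resnik_distance(t1, t2) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_self_minimal(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        assert index.resnik_distance("C", "E") == index.resnik_distance("E", "C")
        terms = sorted(index.propagated.term2genes)
        for t in terms:
            d_self = index.resnik_distance(t, t)
            for other in terms:
                assert d_self <= index.resnik_distance(t, other) + 1e-12

    def test_root_only_common_ancestor_is_maximal(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        assert index.resnik_distance("C", "E") == pytest.approx(1.0)


class TestBubbleCliques:
    def test_enumerated_neighbor_walk(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        cliques = bubble_cliques(["g1"], index)
        # g1 -> C; neighborhood {C, A} (root excluded, C has no children)
        # genes of C: g1,g2; genes of A: g7
        assert cliques["g1"] == {"g1", "g2", "g7"}

    def test_empty_input(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        assert bubble_cliques([], index) == {}

    def test_unannotated_gene_skipped_with_warning(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        with pytest.warns(UserWarning, match="no annotations"):
            out = bubble_cliques(["ghost"], index)
        assert out == {}


class TestPruning:
    def test_zero_relaxation_keeps_everything(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        cfg = SemanticConfig(relaxation=0.0)
        assert prune_gene_terms("g2", index, cfg) == {"C", "D"}

    def test_close_pair_drops_lower_ic_member(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        # C (IC ln4) and A (IC ln2) are ancestor-related: d(C,A)=1-IC(A)/ICmax
        corpus2 = AnnotationCorpus.from_gene2terms(
            {**{k: set(v) for k, v in corpus.gene2terms.items()}, "gx": {"C", "A"}}
        )
        index2 = SemanticIndex(g, corpus2)
        d = index2.resnik_distance("C", "A")
        cfg = SemanticConfig(relaxation=min(1.0, d + 0.05))
        retained = prune_gene_terms("gx", index2, cfg)
        assert retained == {"C"}  # A is more generic (lower IC)

    def test_pruned_set_respects_relaxation_exhaustively(self, toy_ontology):
        g, corpus, _ = toy_ontology
        index = SemanticIndex(g, corpus)
        cfg = SemanticConfig(relaxation=0.3)
        for gene in sorted(corpus.gene2terms):
            retained = sorted(prune_gene_terms(gene, index, cfg))
            for a, b in itertools.combinations(retained, 2):
                assert index.resnik_distance(a, b) >= cfg.relaxation


class TestRanking:
    def test_hub_gene_ranks_first(self, toy_ontology):
        g, corpus, _ = toy_ontology
        index = SemanticIndex(g, corpus)
        ranking = rank_gene_centrality(sorted(corpus.gene2terms), index, SemanticConfig())
        assert ranking.rows[0][0] == "gHUB"
        assert ranking.rows[0][1] >= 5

    def test_all_single_term_genes_tie_break_lexicographic(self, toy_dag):
        g, corpus = toy_dag
        index = SemanticIndex(g, corpus)
        genes = ["g1", "g3", "g4"]
        ranking = rank_gene_centrality(genes, index, SemanticConfig())
        assert ranking.genes() == ["g1", "g3", "g4"]
        assert all(s == 1 for _, s, _ in ranking.rows)

    def test_relaxation_zero_scores_dominate(self, toy_ontology):
        g, corpus, _ = toy_ontology
        index = SemanticIndex(g, corpus)
        genes = sorted(corpus.gene2terms)
        strict = rank_gene_centrality(genes, index, SemanticConfig(relaxation=0.0))
        relaxed = rank_gene_centrality(genes, index, SemanticConfig(relaxation=0.15))
        for gene in genes:
            assert strict.score_of(gene) >= relaxed.score_of(gene)

    def test_input_order_invariance(self, toy_ontology):
        g, corpus, _ = toy_ontology
        index = SemanticIndex(g, corpus)
        genes = sorted(corpus.gene2terms)
        r1 = rank_gene_centrality(genes, index, SemanticConfig())
        r2 = rank_gene_centrality(genes[::-1], index, SemanticConfig())
        assert r1.rows == r2.rows


class TestGenesToProbes:
    @pytest.fixture
    def annot(self):
        return ProbeAnnotation(
            pd.DataFrame(
                {
                    "probe": ["cg1", "cg2", "cg3"],
                    "genes": [("gA",), ("gA", "gB"), ("gC",)],
                    "region": ["TSS200", "Body", "3'UTR"],
                }
            )
        )

    def test_probe_count_bound(self, annot):
        out = genes_to_probes(["gA", "gB"], annot)
        assert out["all"] == {"cg1", "cg2"}

    def test_disjoint_preselection_empty_intersection(self, annot):
        pre = union_preselect({"e1": frozenset({"cg3"})})
        out = genes_to_probes(["gA"], annot, pre)
        assert out["e1"] == frozenset()

    def test_experiment_intersections_subset_of_all(self, annot):
        pre = union_preselect({"e1": frozenset({"cg1"}), "e2": frozenset({"cg2", "cg3"})})
        out = genes_to_probes(["gA", "gB", "gC"], annot, pre)
        assert out["e1"] | out["e2"] <= out["all"]

    def test_gene_without_probes_warns(self, annot):
        with pytest.warns(UserWarning, match="without probes"):
            out = genes_to_probes(["gZ"], annot)
        assert out["all"] == frozenset()
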