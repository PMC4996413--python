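"""GO-semantic centrality selection.

Genes are ranked by how many distinct, mutually non-redundant ontology
terms annotate them.  Term specificity is measured by information
content IC(t) = −ln(n_t/n_root) over the annotation corpus closed under
the true-path rule; the Resnik-style distance between two terms is
d = 1 − IC(MICA)/IC_max, where MICA is their most informative common
ancestor.  A gene's term list is pruned iteratively: while any pair of
retained terms lies closer than the relaxation threshold (default
0.15), the more generic (lower-IC) member of the closest pair is
dropped, so the retained terms describe distinct, highly non-
overlapping processes.  The retained-term count is the gene's
centrality score; genes with many such terms sit at the crossroads of
several functional mechanisms.  A companion "bubble" expansion collects
the genes of each term's parent/child neighborhood, and a mapping layer
translates ranked genes back to CpG probes and intersects them with the
statistical pre-selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .simulate import ProbeAnnotation


@dataclass(frozen=True)
class SemanticConfig:
    aspect: str = "BP"
    relaxation: float = 0.15
    metric: str = "resnik"

    def __post_init__(self) -> None:
        if not 0.0 <= self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in [0, 1]")
        if self.aspect not in ("BP", "MF", "CC"):
            raise ValueError(f"unknown aspect {self.aspect!r}")
        if self.metric != "resnik":
            raise ValueError("only the Resnik metric is supported")


@dataclass(frozen=True)
class AnnotationCorpus:
    """Bidirectional gene↔term maps (direct or propagated annotations)."""

    gene2terms: dict[str, frozenset[str]]
    term2genes: dict[str, frozenset[str]]
    propagated: bool = False

    @classmethod
    def from_gene2terms(cls, gene2terms, propagated: bool = False) -> "AnnotationCorpus":
        g2t = {g: frozenset(ts) for g, ts in gene2terms.items() if ts}
        t2g: dict[str, set[str]] = {}
        for g, ts in g2t.items():
            for t in ts:
                t2g.setdefault(t, set()).add(g)
        return cls(
            gene2terms=g2t,
            term2genes={t: frozenset(gs) for t, gs in t2g.items()},
            propagated=propagated,
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene2terms)


def validate_dag(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology graph contains a cycle: {cycle}")


def roots(graph: nx.DiGraph) -> list[str]:
    """Terms with no parent (edges point child→parent)."""
    return sorted(t for t in graph.nodes if graph.out_degree(t) == 0)


def ancestors_of(graph: nx.DiGraph, term: str) -> frozenset[str]:
    """Term plus all its ancestors (following child→parent edges)."""
    return frozenset(nx.descendants(graph, term)) | {term}


def propagate_annotations(graph: nx.DiGraph, corpus: AnnotationCorpus) -> AnnotationCorpus:
    """Close every gene's annotations under ancestors (true-path rule).
    Annotations to terms absent from the graph are dropped with a warning."""
    validate_dag(graph)
    anc_cache: dict[str, frozenset[str]] = {}
    dropped = 0
    g2t: dict[str, set[str]] = {}
    for gene, terms in corpus.gene2terms.items():
        closed: set[str] = set()
        for t in terms:
            if t not in graph:
                dropped += 1
                continue
            if t not in anc_cache:
                anc_cache[t] = ancestors_of(graph, t)
            closed.update(anc_cache[t])
        if closed:
            g2t[gene] = closed
    if dropped:
        warnings.warn(f"dropped {dropped} annotation(s) to unknown terms", stacklevel=2)
    return AnnotationCorpus.from_gene2terms(g2t, propagated=True)


class SemanticIndex:
    """Precomputed IC, ancestor sets and IC_max over a propagated corpus."""

    def __init__(self, graph: nx.DiGraph, corpus: AnnotationCorpus):
        validate_dag(graph)
        self.graph = graph
        self.direct = corpus
        self.propagated = corpus if corpus.propagated else propagate_annotations(graph, corpus)
        self.n_total = self.propagated.n_genes
        self.ic: dict[str, float] = {}
        for term, genes in self.propagated.term2genes.items():
            self.ic[term] = -math.log(len(genes) / self.n_total)
        self.ic_max = max(self.ic.values()) if self.ic else 0.0
        self._anc: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        if term not in self._anc:
            self._anc[term] = ancestors_of(self.graph, term)
        return self._anc[term]

    def information_content(self, term: str) -> float:
        if term not in self.ic:
            raise KeyError(f"term {term!r} has no annotated genes")
        return self.ic[term]

    def mica(self, t1: str, t2: str) -> str:
        common = self.ancestors(t1) & self.ancestors(t2)
        common = [t for t in common if t in self.ic]
        if not common:
            raise ValueError(f"terms {t1!r} and {t2!r} share no annotated common ancestor")
        return max(common, key=lambda t: (self.ic[t], t))

    def resnik_distance(self, t1: str, t2: str) -> float:
        """d = 1 − IC(MICA)/IC_max ∈ [0, 1]; 0 ⇔ the pair shares a
        maximally informative ancestor, 1 ⇔ only the root."""
        if self.ic_max == 0:
            return 0.0
        return 1.0 - self.ic[self.mica(t1, t2)] / self.ic_max


@dataclass(frozen=True)
class GeneCentralityRanking:
    """(gene, retained-term count, retained terms), sorted by count
    descending with lexicographic gene-id tie-break."""

    rows: tuple[tuple[str, int, tuple[str, ...]], ...]

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.rows]

    def top(self, n: int) -> list[str]:
        return self.genes()[:n]

    def score_of(self, gene: str) -> int:
        for g, s, _ in self.rows:
            if g == gene:
                return s
        raise KeyError(gene)


def bubble_cliques(genes, index: SemanticIndex) -> dict[str, frozenset[str]]:
    """Functional clique of each gene: the union, over its direct terms
    t, of the genes directly annotated to t, to t's parents and to t's
    children; ontology roots are excluded from the expansion."""
    root_set = set(roots(index.graph))
    t2g = index.direct.term2genes
    out: dict[str, frozenset[str]] = {}
    for gene in genes:
        terms = index.direct.gene2terms.get(gene)
        if not terms:
            warnings.warn(f"gene {gene!r} has no annotations; skipped", stacklevel=2)
            continue
        clique: set[str] = set()
        for t in terms:
            if t not in index.graph:
                continue
            neighborhood = {t} | set(index.graph.successors(t)) | set(index.graph.predecessors(t))
            neighborhood -= root_set
            for nt in neighborhood:
                clique.update(t2g.get(nt, frozenset()))
        out[gene] = frozenset(clique)
    return out


def prune_gene_terms(gene: str, index: SemanticIndex, cfg: SemanticConfig) -> frozenset[str]:
    """Iteratively drop the lower-IC member of the closest pair of the
    gene's (direct) terms while any pairwise Resnik distance falls below
    the relaxation threshold.  Deterministic: the closest pair is the
    (distance, term-id) minimum; equal-IC ties drop the
    lexicographically larger term."""
    terms = sorted(t for t in index.direct.gene2terms.get(gene, frozenset()) if t in index.ic)
    if cfg.relaxation == 0.0:
        return frozenset(terms)
    retained = list(terms)
    while len(retained) > 1:
        best = None
        for i in range(len(retained)):
            for j in range(i + 1, len(retained)):
                d = index.resnik_distance(retained[i], retained[j])
                key = (d, retained[i], retained[j])
                if best is None or key < best:
                    best = key
        if best is None or best[0] >= cfg.relaxation:
            break
        _, t1, t2 = best
        ic1, ic2 = index.ic[t1], index.ic[t2]
        if ic1 == ic2:
            drop = max(t1, t2)
        elif ic1 < ic2:
            drop = t1
        else:
            drop = t2
        retained.remove(drop)
    return frozenset(retained)


def rank_gene_centrality(
    genes, index: SemanticIndex, cfg: SemanticConfig
) -> GeneCentralityRanking:
    """Score each input gene by its retained-term count after pruning
    and sort descending; the output is restricted to the input list."""
    rows = []
    for gene in sorted(set(genes)):
        retained = prune_gene_terms(gene, index, cfg)
        rows.append((gene, len(retained), tuple(sorted(retained))))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return GeneCentralityRanking(rows=tuple(rows))


def genes_to_probes(
    genes,
    annotation: ProbeAnnotation,
    preselection=None,
) -> dict[str, frozenset[str]]:
    """Map a gene list to its full probe set and, when a pre-selection
    result is supplied, to the intersection with each experiment's
    pre-selected probes."""
    genes = list(genes)
    covered = annotation.gene_universe()
    missing = [g for g in genes if g not in covered]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) without probes skipped", stacklevel=2)
    probes = frozenset(annotation.probes_of_genes([g for g in genes if g in covered]))
    out = {"all": probes}
    if preselection is not None:
        for exp, sel in preselection.per_experiment.items():
            out[exp] = probes & sel
        out["preselected"] = probes & preselection.union
    return out
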