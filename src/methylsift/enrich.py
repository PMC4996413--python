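"""Hypergeometric gene-set enrichment and genomic-region distribution.

For a selected gene list of size n drawn from a background universe of
N genes, a term annotating K universe genes of which a appear in the
list is scored by the upper-tail hypergeometric probability
P(X ≥ a).  The background universe is the set of genes on the probe
annotation (the chip universe), not the genome, because selection
operated on chip probes.  Raw p-values are reported by default;
Benjamini–Hochberg adjustment and an empirical resampling null
(random same-size gene lists) are available as options.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .simulate import PROMOTER_GROUPS, REGION_GROUPS, ProbeAnnotation


def hypergeom_tail(a: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X ≥ a) for X ~ Hypergeom(N population, K successes,
    n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent counts: need K, n <= N")
    if not 0 <= a <= min(K, n):
        raise ValueError("inconsistent counts: need 0 <= a <= min(K, n)")
    return float(sps.hypergeom.sf(a - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    description: str
    p_value: float
    hits: int
    term_size: int
    p_adjusted: float | None = None

    @property
    def enrichment(self) -> str:
        """The a/K notation: list hits over term size."""
        return f"{self.hits}/{self.term_size}"


@dataclass(frozen=True)
class EnrichmentQuery:
    gene_list: frozenset[str]
    universe: frozenset[str]
    term_sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    adjust: str = "none"  # none | bh | resample
    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_list <= self.universe:
            extra = sorted(self.gene_list - self.universe)[:5]
            raise ValueError(f"gene list not contained in universe (e.g. {extra})")
        if self.adjust not in ("none", "bh", "resample"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


def enrich_term_sets(query: EnrichmentQuery) -> list[EnrichmentRow]:
    """One row per term with ≥ 1 hit (terms with K < 2 skipped), sorted
    by p ascending, ties by term id."""
    lst = query.gene_list & query.universe
    if not lst:
        raise ValueError("gene list and universe do not intersect")
    N = len(query.universe)
    n = len(lst)
    raw: list[tuple[str, int, int, float]] = []
    for term in sorted(query.term_sets):
        members = query.term_sets[term] & query.universe
        K = len(members)
        if K < 2:
            continue
        a = len(members & lst)
        if a < 1:
            continue
        raw.append((term, a, K, hypergeom_tail(a, K, n, N)))

    adjusted: list[float | None] = [None] * len(raw)
    if query.adjust == "bh" and raw:
        adjusted = list(sps.false_discovery_control([r[3] for r in raw], method="bh"))
    elif query.adjust == "resample" and raw:
        adjusted = _resampling_null([r for r in raw], query)

    rows = [
        EnrichmentRow(
            term=term,
            description=query.descriptions.get(term, ""),
            p_value=p,
            hits=a,
            term_size=K,
            p_adjusted=adj,
        )
        for (term, a, K, p), adj in zip(raw, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows


def _resampling_null(raw, query: EnrichmentQuery) -> list[float]:
    """Empirical p: fraction of random same-size gene lists whose hit
    count for the term is at least the observed one."""
    rng = np.random.default_rng(np.random.SeedSequence([int(query.seed), 41]))
    universe = sorted(query.universe)
    n = len(query.gene_list & query.universe)
    draws = np.array(
        [rng.choice(len(universe), size=n, replace=False) for _ in range(query.n_resamples)]
    )
    member_idx = {
        term: np.isin(
            np.arange(len(universe)),
            [universe.index(g) for g in (query.term_sets[term] & query.universe)],
        )
        for term, _, _, _ in raw
    }
    out = []
    for term, a, _, _ in raw:
        hits = member_idx[term][draws].sum(axis=1)
        out.append(float((1 + (hits >= a).sum()) / (query.n_resamples + 1)))
    return out


@dataclass(frozen=True)
class RegionDistribution:
    """Probe counts per genomic-region group, with the promoter rollup."""

    counts: dict[str, int]
    unknown: int = 0

    @property
    def promoter_total(self) -> int:
        return sum(self.counts[g] for g in PROMOTER_GROUPS)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def region_distribution(probes, annotation: ProbeAnnotation) -> RegionDistribution:
    """Count the probes of a selection in each of the seven region
    groups; probes with an unrecognized region are tallied separately
    with a warning."""
    probes = set(probes)
    counts = {g: 0 for g in REGION_GROUPS}
    unknown = 0
    frame = annotation.frame
    sub = frame[frame["probe"].isin(probes)]
    for region in sub["region"]:
        if region in counts:
            counts[region] += 1
        else:
            unknown += 1
    if unknown:
        warnings.warn(f"{unknown} probe(s) with unknown region group", stacklevel=2)
    return RegionDistribution(counts=counts, unknown=unknown)
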