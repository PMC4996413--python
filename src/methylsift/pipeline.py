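"""End-to-end orchestration of the biomarker-discovery pipeline.

``run_all`` chains every stage on a synthetic cohort: generation →
two-step QC normalization → per-experiment pre-selection (top-1% of
bootstrap-corrected paired-t p-values ∧ ScaledCV > 1, unioned) → GA
wrapper selection on the union → GO-semantic centrality selection of
the pre-selected genes → classifier suite on the independent test
split → enrichment and region-distribution reporting.  All randomness
derives from one seed and outputs are written deterministically, so two
invocations with the same config produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import default_suite, holdout_evaluate
from .enrich import EnrichmentQuery, enrich_term_sets, region_distribution
from .ga import GAConfig, evolve
from .normalize import normalize_dataset
from .preselect import (
    BootstrapConfig,
    compute_probe_statistics,
    preselect_experiment,
    union_preselect,
)
from .semantic import (
    SemanticConfig,
    SemanticIndex,
    genes_to_probes,
    rank_gene_centrality,
)
from .simulate import DISEASES, SimulationConfig, simulate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters of one full run."""

    simulation: SimulationConfig = SimulationConfig()
    n_bins: int = 100
    bootstrap_B: int = 1000
    top_frac: float = 0.01
    cv_min: float = 1.0
    ga_population: int = 60
    ga_generations: int = 12
    ga_dmax: int = 40
    semantic_relaxation: float = 0.15
    semantic_top_genes: int = 20
    seed: int = 0

    def reseeded(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, simulation=replace(self.simulation, seed=seed))


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage, write all artifacts under ``outdir``, and
    return the summary report (also written as ``report.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- cohort ---------------------------------------------------------
    truth, sheet, raw, graph, corpus, annot = simulate_cohort(config.simulation)
    io.write_sample_sheet(sheet, outdir / "sample_sheet.csv")
    io.write_truth(truth, outdir / "planted_truth.json")
    io.write_probe_annotation(annot, outdir / "probe_annotation.tsv")
    io.write_obo_subset(graph, outdir / "ontology.obo")
    io.write_gene_annotation(corpus, outdir / "gene_annotation.tsv")

    # --- normalization --------------------------------------------------
    ds, qc_stats, norm_report = normalize_dataset(raw, n_bins=config.n_bins)
    io.write_m_matrix(ds, outdir / "m_values.tsv")
    io.write_report(norm_report, outdir / "normalization_report.json")

    # --- pre-selection --------------------------------------------------
    boot = BootstrapConfig(B=config.bootstrap_B, seed=seed)
    selected = {}
    for disease in DISEASES:
        stats = compute_probe_statistics(ds, qc_stats, disease, boot)
        stats.frame.to_csv(outdir / f"stats_{disease}.tsv", sep="\t", index=False)
        selected[stats.experiment] = preselect_experiment(
            stats, top_frac=config.top_frac, cv_min=config.cv_min
        )
    pre = union_preselect(selected, {"top_frac": config.top_frac, "cv_min": config.cv_min})
    io.write_report(
        {
            "per_experiment": {k: sorted(v) for k, v in pre.per_experiment.items()},
            "union": sorted(pre.union),
            "provenance": {k: list(v) for k, v in pre.provenance.items()},
        },
        outdir / "preselection.json",
    )

    union_probes = sorted(pre.union)
    probe_pos = {p: i for i, p in enumerate(ds.probes)}
    train_ids = sheet.split_ids("train")
    test_ids = sheet.split_ids("test")
    class_of = sheet.class_of()
    y_train = np.array([class_of[s] for s in train_ids])
    y_test = np.array([class_of[s] for s in test_ids])
    feat_rows = np.array([probe_pos[p] for p in union_probes], dtype=int)
    X_train = ds.M[np.ix_(feat_rows, ds.columns(train_ids))].T
    X_test = ds.M[np.ix_(feat_rows, ds.columns(test_ids))].T

    # --- evolutionary selection -----------------------------------------
    ga_cfg = GAConfig(
        population_size=config.ga_population,
        d_max=min(config.ga_dmax, len(union_probes)),
        max_generations=config.ga_generations,
        seed=seed,
    )
    ga_mask, ga_log = evolve(X_train, y_train, ga_cfg)
    ga_probes = [p for p, keep in zip(union_probes, ga_mask) if keep]
    pd.DataFrame({"probe": ga_probes}).to_csv(outdir / "ga_selected.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "generation": g.generation,
                "best_fitness": g.best_fitness,
                "mean_fitness": g.mean_fitness,
                "best_cardinality": g.best_cardinality,
            }
            for g in ga_log
        ]
    ).to_csv(outdir / "ga_log.tsv", sep="\t", index=False)

    # --- semantic selection ---------------------------------------------
    index = SemanticIndex(graph, corpus)
    sem_cfg = SemanticConfig(relaxation=config.semantic_relaxation)
    pre_genes = sorted(annot.genes_for_probes(pre.union) & set(corpus.gene2terms))
    ranking = rank_gene_centrality(pre_genes, index, sem_cfg)
    pd.DataFrame(
        [{"gene": g, "score": s, "terms": ";".join(t)} for g, s, t in ranking.rows]
    ).to_csv(outdir / "semantic_ranking.tsv", sep="\t", index=False)
    top_genes = ranking.top(config.semantic_top_genes)
    sem_probesets = genes_to_probes(top_genes, annot, pre)
    io.write_report(
        {k: sorted(v) for k, v in sem_probesets.items()}, outdir / "semantic_probes.json"
    )
    sem_probes = sorted(sem_probesets["preselected"])
    sem_mask = np.isin(np.array(union_probes), sem_probes)

    # --- classification on the independent split ------------------------
    reports = []
    feature_sets = {"ga": ga_mask}
    if sem_mask.sum() >= 1:
        feature_sets["semantic"] = sem_mask
    for name, mask in feature_sets.items():
        for spec in default_suite(seed=seed):
            rep = holdout_evaluate(
                X_train,
                y_train,
                X_test,
                y_test,
                spec,
                mask=mask,
                train_ids=train_ids,
                test_ids=test_ids,
                feature_set=name,
            )
            reports.append(rep)
    io.write_report({"reports": [r.to_dict() for r in reports]}, outdir / "performance.json")
    table = pd.DataFrame(
        [
            {
                "feature_set": r.feature_set,
                "classifier": r.classifier,
                "total_accuracy": round(r.total_accuracy, 4),
                **{f"sens_{c}": round(v, 4) for c, v in r.sensitivities.items()},
            }
            for r in reports
        ]
    )
    table.to_csv(outdir / "performance.tsv", sep="\t", index=False)

    # --- enrichment ------------------------------------------------------
    universe = frozenset(annot.gene_universe() & set(corpus.gene2terms))
    enrichment_rows = []
    ga_genes = frozenset(annot.genes_for_probes(ga_probes) & universe)
    if ga_genes:
        query = EnrichmentQuery(
            gene_list=ga_genes,
            universe=universe,
            term_sets=dict(index.propagated.term2genes),
            descriptions={t: graph.nodes[t].get("name", t) for t in graph.nodes},
            seed=seed,
        )
        enrichment_rows = enrich_term_sets(query)
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "term": r.term,
                    "description": r.description,
                    "p_value": r.p_value,
                    "enrichment": r.enrichment,
                }
                for i, r in enumerate(enrichment_rows)
            ]
        ).to_csv(outdir / "enrichment_ga.tsv", sep="\t", index=False)

    regions = region_distribution(sem_probesets["all"], annot)
    pd.DataFrame(
        [{"region": g, "count": c} for g, c in regions.counts.items()]
        + [{"region": "Promoter(total)", "count": regions.promoter_total}]
    ).to_csv(outdir / "region_distribution.tsv", sep="\t", index=False)

    # --- summary ---------------------------------------------------------
    planted = truth.planted_union()
    ann_reports = [r for r in reports if r.classifier == "ann" and r.feature_set == "ga"]
    summary = {
        "seed": seed,
        "config": {
            "n_probes": config.simulation.n_probes,
            "n_pairs_per_disease": config.simulation.n_pairs_per_disease,
            "effect_delta": config.simulation.effect_delta,
            "bootstrap_B": config.bootstrap_B,
            "top_frac": config.top_frac,
            "ga_population": config.ga_population,
            "ga_generations": config.ga_generations,
        },
        "n_preselected": len(pre.union),
        "n_planted": len(planted),
        "n_planted_recovered": len(pre.union & planted),
        "n_ga_selected": len(ga_probes),
        "n_semantic_probes": len(sem_probesets["all"]),
        "qc_variance_reduction": norm_report["qc_variance_reduction"],
        "ann_holdout_accuracy": ann_reports[0].total_accuracy if ann_reports else None,
        "n_enrichment_terms": len(enrichment_rows),
    }
    io.write_report(summary, outdir / "report.json")
    return summary
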