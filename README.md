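# methylsift

Biomarker discovery for array-based DNA methylation in matched
case–control studies. The package implements, as a tested and fully
seeded pipeline, the analysis chain used to screen Infinium-450K-style
two-channel methylation data for small panels of candidate CpG
biomarkers:

1. **Signal normalization** — per-probe β = I_Meth/(I_Meth+I_UnMeth),
   M = log₂(I_Meth/I_UnMeth) and average intensity
   I = ½·log₂(I_Meth·I_UnMeth); technical bias is corrected in two
   steps using the replicated technical quality-control (QC) sample on
   every chip: (i) within chip, per-intensity-percentile QC residual
   errors are subtracted, and (ii) across probes, the per-probe QC
   standard deviation σ_QC is subtracted.
2. **Statistical pre-selection** — per probe, a scaled coefficient of
   variation (CV of the study pool over the CV of the QC replicates;
   ScaledCV > 1 means variability beyond technical noise) and a paired
   t-test whose p-values are corrected by a sign-flip bootstrap null
   (p_boot = (1+#{|t*| ≥ |t|})/(B+1)). Each experiment keeps the top 1%
   of bootstrap-corrected p-values intersected with ScaledCV > 1;
   experiments are unioned.
3. **Evolutionary feature selection** — a genetic algorithm over binary
   CpG-inclusion masks (population 500, roulette selection, uniform
   crossover with P_c = 0.5, bit mutation with P_m = 1/N, cardinality
   bounds, elitism), with the distance-weighted 12-nn classifier under
   stratified 3-fold cross-validation as the fitness.
4. **Semantic (GO-centrality) selection** — genes are ranked by how
   many mutually non-redundant ontology terms annotate them: term
   specificity is the information content IC(t) = −ln(n_t/n_root),
   the Resnik-style distance is d = 1 − IC(MICA)/IC_max, and a gene's
   term list is pruned while any pair lies closer than a relaxation
   threshold (default 0.15). Ranked genes are mapped back to CpG probes
   via the chip annotation.
5. **Classification** — distance-weighted k-nn (k = 1, 6, 12), a
   Gini-index CART tree, and a one-hidden-layer feed-forward network
   (⌊(F+C)/2⌋+1 sigmoid units, per-sample backprop, learning rate 0.3,
   momentum 0.2, 1000 epochs), evaluated by leave-one-out resampling
   and on an independent held-out split, reporting total accuracy and
   per-class sensitivity.
6. **Enrichment reporting** — upper-tail hypergeometric gene-set
   enrichment (rows "term, p, a/K") and genomic-region distribution
   over the seven region groups (TSS200, TSS1500, 5′UTR, 1stExon,
   Body, 3′UTR, Intergenic).

Because real cohorts of this kind are large and access-controlled, the
package ships a first-class synthetic-cohort generator
(`methylsift.simulate`) producing two-channel intensities for two
matched case–control cohorts with chip-level intensity-dependent bias,
QC replicates, planted differentially methylated probes, and a toy
ontology with a designated high-centrality hub gene — so every stage
can be verified against a known ground truth.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from methylsift import RunConfig, SimulationConfig, run_all

config = RunConfig(
    simulation=SimulationConfig(
        n_probes=2000, n_pairs_per_disease=30, n_planted=50,
        effect_delta=1.5, seed=7,
    ),
    seed=7,
)
summary = run_all(config, "out/demo")
for key in ("n_preselected", "n_planted_recovered", "n_ga_selected",
            "n_semantic_probes", "qc_variance_reduction", "ann_holdout_accuracy"):
    print(f"{key}: {summary[key]}")
```

prints

```
n_preselected: 40
n_planted_recovered: 40
n_ga_selected: 2
n_semantic_probes: 38
qc_variance_reduction: 0.9949275472969433
ann_holdout_accuracy: 100.0
```

The cohort has 2000 probes with 50 planted differentially methylated
probes per disease (shift 1.5 M-units). Pre-selection keeps 40 probes
(the top-1% rank budget is 20 per experiment), all of which are truly
planted; the QC-based normalization removes 99.5% of the technical
replicate variance injected as chip bias; the GA distills a 2-probe
panel sufficient for its cross-validated fitness; and the neural
network classifies the independent test split perfectly — unsurprising
at this planted effect size. `out/demo/` contains every intermediate
artifact (M-value matrix, per-probe statistics, selected panels,
performance tables, enrichment and region tables), written
deterministically: re-running the same config yields byte-identical
files.

A command-line interface mirrors the stages
(`methylsift simulate|normalize|preselect|select-semantic|enrich|run-all`).

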