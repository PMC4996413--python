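"""Seeded synthetic methylation cohorts with known planted truth.

Emulates a matched case–control 450K-style study: two disease cohorts
(breast cancer, BCCA; B-cell lymphoma, LYCA) each matched 1:1 with
controls, samples distributed over chips that carry replicates of one
technical quality-control (QC) sample, per-chip intensity-dependent
technical bias, and a configurable number of planted differentially
methylated probes per disease.  A toy gene-ontology corpus with a
designated high-centrality hub gene supports the semantic-selection
stage.  Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

DISEASES = ("BCCA", "LYCA")
QC_LABEL = "QC"
CONTROL_LABEL = "control"

#: The seven genomic-region groups used by the probe annotation
#: (four TSS200/TSS1500/5'UTR/1stExon promoter subgroups, gene body,
#: 3'UTR, and intergenic).
REGION_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic")
PROMOTER_GROUPS = ("TSS200", "TSS1500", "5'UTR", "1stExon")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``effect_delta`` is the planted case-vs-control shift on the M-value
    (logit-beta) scale.  ``bias_slope``/``bias_offset`` are *scales*: each
    chip draws its own coefficients uniformly from ±scale, so that chips
    genuinely disagree (a bias identical on every chip would be invisible
    to a replicate-based correction).  ``noise_sd`` is the standard
    deviation of multiplicative log-normal channel noise.
    """

    n_probes: int = 2000
    n_genes: int = 200
    n_pairs_per_disease: int = 30
    chip_size: int = 12
    qc_per_chip: int = 1
    n_planted: int = 50
    effect_delta: float = 1.5
    bias_slope: float = 0.5
    bias_offset: float = 0.3
    noise_sd: float = 0.1
    test_fraction: float = 1.0 / 3.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_probes": self.n_probes,
            "n_genes": self.n_genes,
            "n_pairs_per_disease": self.n_pairs_per_disease,
            "chip_size": self.chip_size,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if self.qc_per_chip < 1:
            raise ValueError("qc_per_chip must be >= 1")
        if self.n_planted > self.n_probes:
            raise ValueError("n_planted cannot exceed n_probes")
        if self.chip_size <= self.qc_per_chip:
            raise ValueError("chip_size must exceed qc_per_chip")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    @property
    def n_study_samples(self) -> int:
        return 4 * self.n_pairs_per_disease

    @property
    def n_chips(self) -> int:
        per_chip = self.chip_size - self.qc_per_chip
        return math.ceil(self.n_study_samples / per_chip)

    def chip_ids(self) -> list[str]:
        return [f"chip{i + 1:02d}" for i in range(self.n_chips)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic cohort: which probes are differentially
    methylated per disease, the baseline methylation fraction of every
    probe, and each chip's technical-bias coefficients."""

    dm_probes: dict[str, frozenset[str]]
    true_beta: pd.Series  # index: probe id, values in (0, 1)
    chip_bias: dict[str, tuple[float, float]]  # chip -> (slope, offset)

    def planted_union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for probes in self.dm_probes.values():
            out = out | probes
        return out


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: class label, chip, matched pair, cohort, split."""

    frame: pd.DataFrame  # columns: sample_id, class_label, chip_id, pair_id, cohort, split

    REQUIRED = ("sample_id", "class_label", "chip_id", "pair_id", "cohort", "split")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        qc = self.frame["class_label"] == QC_LABEL
        if (qc & self.frame["pair_id"].notna() & (self.frame["pair_id"] != "")).any():
            raise ValueError("QC rows must not carry a pair_id")
        study = self.frame[~qc]
        for pair_id, grp in study.groupby("pair_id"):
            labels = list(grp["class_label"])
            n_ctrl = labels.count(CONTROL_LABEL)
            if len(grp) != 2 or n_ctrl != 1:
                raise ValueError(
                    f"pair {pair_id!r} must contain exactly one control and one case, got {labels}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def is_qc(self) -> pd.Series:
        return (self.frame["class_label"] == QC_LABEL).set_axis(self.frame["sample_id"])

    def qc_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["class_label"] == QC_LABEL, "sample_id"])

    def study_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["class_label"] != QC_LABEL, "sample_id"])

    def chip_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["chip_id"]))

    def class_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["class_label"]))

    def pairs(self, disease: str) -> list[tuple[str, str]]:
        """(control_id, case_id) tuples of one disease cohort, ordered by pair id."""
        sub = self.frame[(self.frame["cohort"] == disease) & (self.frame["class_label"] != QC_LABEL)]
        out = []
        for pair_id, grp in sorted(sub.groupby("pair_id"), key=lambda kv: kv[0]):
            ctrl = grp.loc[grp["class_label"] == CONTROL_LABEL, "sample_id"].iloc[0]
            case = grp.loc[grp["class_label"] != CONTROL_LABEL, "sample_id"].iloc[0]
            out.append((ctrl, case))
        return out

    def split_ids(self, split: str) -> list[str]:
        sub = self.frame[(self.frame["split"] == split) & (self.frame["class_label"] != QC_LABEL)]
        return list(sub["sample_id"])


@dataclass(frozen=True)
class IntensityDataset:
    """Paired methylated/unmethylated channel intensities (probes × samples)."""

    probes: list[str]
    samples: list[str]
    meth: np.ndarray
    unmeth: np.ndarray
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth and unmeth shapes differ")
        if self.meth.shape != (len(self.probes), len(self.samples)):
            raise ValueError("intensity matrix shape does not match probe/sample ids")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValueError("negative intensity encountered")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def probe_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(n)]


def generate_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw the planted ground truth for a cohort.

    Baseline methylation β is drawn from the bimodal mixture typical of
    array data: equal-weight Beta(2,10) and Beta(10,2) components plus a
    10% intermediate Beta(2,2) component.  Planted differentially
    methylated probe sets are disjoint between the two diseases.
    """
    config.validate()
    if config.n_planted * len(DISEASES) > config.n_probes:
        raise ValueError("cannot plant disjoint sets: n_planted * 2 > n_probes")
    rng = _rng(config.seed, 1)
    probes = probe_ids(config.n_probes)

    comp = rng.choice(3, size=config.n_probes, p=[0.45, 0.45, 0.10])
    beta = np.empty(config.n_probes)
    beta[comp == 0] = rng.beta(2, 10, size=int((comp == 0).sum()))
    beta[comp == 1] = rng.beta(10, 2, size=int((comp == 1).sum()))
    beta[comp == 2] = rng.beta(2, 2, size=int((comp == 2).sum()))
    # clip keeps both channels above the intensity floor at typical T
    beta = np.clip(beta, 5e-3, 1 - 5e-3)

    perm = rng.permutation(config.n_probes)
    dm: dict[str, frozenset[str]] = {}
    for i, disease in enumerate(DISEASES):
        idx = perm[i * config.n_planted : (i + 1) * config.n_planted]
        dm[disease] = frozenset(probes[j] for j in idx)

    chip_bias = {}
    for chip in config.chip_ids():
        slope = config.bias_slope * rng.uniform(-1.0, 1.0)
        offset = config.bias_offset * rng.uniform(-1.0, 1.0)
        chip_bias[chip] = (float(slope), float(offset))

    return PlantedTruth(
        dm_probes=dm,
        true_beta=pd.Series(beta, index=probes, name="true_beta"),
        chip_bias=chip_bias,
    )


def generate_pairs_and_chips(config: SimulationConfig) -> SampleSheet:
    """Lay out matched pairs, chip assignment, QC replicates and the
    stratified train/test split.

    The split is assigned at the pair level so both members of a matched
    pair land on the same side, which keeps class balance exact.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    rows = []
    for disease in DISEASES:
        n = config.n_pairs_per_disease
        n_test = int(round(config.test_fraction * n))
        test_pairs = set(rng.permutation(n)[:n_test])
        for i in range(n):
            pair = f"{disease}-pair{i + 1:03d}"
            split = "test" if i in test_pairs else "train"
            rows.append((f"ctrl-{disease}-{i + 1:03d}", CONTROL_LABEL, pair, disease, split))
            rows.append((f"case-{disease}-{i + 1:03d}", disease, pair, disease, split))

    order = rng.permutation(len(rows))
    study = [rows[i] for i in order]
    per_chip = config.chip_size - config.qc_per_chip
    chips = config.chip_ids()
    out = []
    for j, (sid, label, pair, cohort, split) in enumerate(study):
        out.append(
            {
                "sample_id": sid,
                "class_label": label,
                "chip_id": chips[j // per_chip],
                "pair_id": pair,
                "cohort": cohort,
                "split": split,
            }
        )
    for chip in chips:
        for r in range(config.qc_per_chip):
            out.append(
                {
                    "sample_id": f"QC-{chip}-{r + 1}",
                    "class_label": QC_LABEL,
                    "chip_id": chip,
                    "pair_id": "",
                    "cohort": "QC",
                    "split": "none",
                }
            )
    frame = pd.DataFrame(out, columns=list(SampleSheet.REQUIRED))
    return SampleSheet(frame)


def generate_intensities(
    config: SimulationConfig,
    truth: PlantedTruth,
    sheet: SampleSheet | None = None,
) -> IntensityDataset:
    """Draw two-channel intensities for every sample.

    The channel model inverts the β definition: an effective methylation
    fraction β′ per probe and sample (baseline β shifted by
    ``effect_delta`` on the logit scale for planted probes of that
    sample's disease) is combined with a log-normal total intensity T so
    that I_Meth = T·β′·ε₁ and I_UnMeth = T·(1−β′)·ε₂, with ε multiplicative
    log-normal noise.  All QC replicates share the single baseline β
    profile — they are replicates of one technical sample, with no
    biological variation.  Chip bias is NOT applied here; see
    :func:`inject_chip_bias`.
    """
    config.validate()
    if sheet is None:
        sheet = generate_pairs_and_chips(config)
    rng = _rng(config.seed, 3)
    probes = list(truth.true_beta.index)
    if len(probes) != config.n_probes:
        raise ValueError("truth inconsistent with config: probe count mismatch")
    samples = sheet.sample_ids
    P, S = len(probes), len(samples)
    probe_pos = {p: i for i, p in enumerate(probes)}

    logit = np.log(truth.true_beta.values) - np.log1p(-truth.true_beta.values)
    shift = np.zeros((P, S))
    class_of = sheet.class_of()
    for disease in DISEASES:
        rows = np.array([probe_pos[p] for p in sorted(truth.dm_probes[disease])], dtype=int)
        if rows.size == 0:
            continue
        cols = np.array([j for j, s in enumerate(samples) if class_of[s] == disease], dtype=int)
        if cols.size:
            shift[np.ix_(rows, cols)] = config.effect_delta
    beta_eff = 1.0 / (1.0 + np.exp(-(logit[:, None] + shift)))

    total = np.exp2(rng.normal(11.0, 0.7, size=(P, S)))
    eps1 = np.exp(rng.normal(0.0, config.noise_sd, size=(P, S))) if config.noise_sd > 0 else 1.0
    eps2 = np.exp(rng.normal(0.0, config.noise_sd, size=(P, S))) if config.noise_sd > 0 else 1.0
    meth = total * beta_eff * eps1
    unmeth = total * (1.0 - beta_eff) * eps2
    return IntensityDataset(probes=probes, samples=samples, meth=meth, unmeth=unmeth, sheet=sheet)


def inject_chip_bias(ds: IntensityDataset, truth: PlantedTruth) -> IntensityDataset:
    """Distort each chip's M-values by slope·I + offset, exactly on the M
    scale, preserving average intensity I.

    Since M = log2(meth/unmeth) and I = 0.5·log2(meth·unmeth), the
    channels decompose as meth = 2^(I + M/2), unmeth = 2^(I − M/2); the
    bias is applied by recomposing the channels from (I, M + slope·I + offset).
    """
    chips = ds.sheet.chip_of()
    for sid in ds.samples:
        if chips[sid] not in truth.chip_bias:
            raise ValueError(f"unknown chip id {chips[sid]!r}: no bias coefficients")
    with np.errstate(divide="ignore"):
        m = np.log2(ds.meth) - np.log2(ds.unmeth)
        i = 0.5 * (np.log2(ds.meth) + np.log2(ds.unmeth))
    slope = np.array([truth.chip_bias[chips[s]][0] for s in ds.samples])
    offset = np.array([truth.chip_bias[chips[s]][1] for s in ds.samples])
    m_biased = m + slope[None, :] * i + offset[None, :]
    meth = np.exp2(i + 0.5 * m_biased)
    unmeth = np.exp2(i - 0.5 * m_biased)
    return replace(ds, meth=meth, unmeth=unmeth)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe → gene(s) and genomic-region-group mapping."""

    frame: pd.DataFrame  # columns: probe, genes (tuple of str), region

    def genes_of(self, probe: str) -> tuple[str, ...]:
        row = self.frame.loc[self.frame["probe"] == probe]
        return tuple(row["genes"].iloc[0]) if len(row) else ()

    def probes_of_genes(self, genes) -> set[str]:
        genes = set(genes)
        mask = self.frame["genes"].map(lambda gs: bool(genes.intersection(gs)))
        return set(self.frame.loc[mask, "probe"])

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for gs in self.frame["genes"]:
            out.update(gs)
        return out

    def genes_for_probes(self, probes) -> set[str]:
        probes = set(probes)
        out: set[str] = set()
        for _, row in self.frame.iterrows():
            if row["probe"] in probes:
                out.update(row["genes"])
        return out


def generate_ontology_corpus(
    n_genes: int,
    seed: int,
    probes: list[str] | None = None,
):
    """Build a toy single-aspect ontology DAG, gene annotations, and a
    probe annotation.

    The DAG is rooted, roughly four levels deep, with several mutually
    distant branches.  One "hub" gene is annotated to a leaf in each of
    five different branches (their only common ancestor is the root), so
    its terms are pairwise maximally distant — the configuration a
    semantic-centrality ranking must place first.  Every gene maps to 1–5
    probes, each probe carrying one of the seven region groups.

    Returns ``(graph, corpus, probe_annotation)`` where ``graph`` is a
    :class:`networkx.DiGraph` with child→parent ``is_a`` edges and
    ``corpus`` an :class:`methylsift.semantic.AnnotationCorpus` of direct
    annotations.
    """
    from .semantic import AnnotationCorpus  # local import: avoid cycle

    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    g = nx.DiGraph()
    root = "T:0000"
    g.add_node(root, name="biological_process", aspect="BP")
    n_branches = 5
    leaves_by_branch: list[list[str]] = []
    tid = 1
    for b in range(n_branches):
        a = f"T:{tid:04d}"
        tid += 1
        g.add_node(a, name=f"branch_{b}", aspect="BP")
        g.add_edge(a, root, relation="is_a")
        branch_leaves = []
        for m in range(2):
            mid = f"T:{tid:04d}"
            tid += 1
            g.add_node(mid, name=f"branch_{b}_mid_{m}", aspect="BP")
            g.add_edge(mid, a, relation="is_a")
            for l in range(2):
                leaf = f"T:{tid:04d}"
                tid += 1
                g.add_node(leaf, name=f"branch_{b}_leaf_{m}_{l}", aspect="BP")
                g.add_edge(leaf, mid, relation="is_a")
                branch_leaves.append(leaf)
        leaves_by_branch.append(branch_leaves)

    genes = [f"g{i:04d}" for i in range(n_genes - 1)] + ["gHUB"]
    all_leaves = [l for br in leaves_by_branch for l in br]
    gene2terms: dict[str, set[str]] = {}
    for gene in genes[:-1]:
        k = int(rng.integers(1, 4))
        # ordinary genes stay within one branch so their terms overlap
        branch = leaves_by_branch[int(rng.integers(n_branches))]
        gene2terms[gene] = set(rng.choice(branch, size=min(k, len(branch)), replace=False))
    hub_terms = {str(rng.choice(br)) for br in leaves_by_branch}
    gene2terms["gHUB"] = hub_terms
    corpus = AnnotationCorpus.from_gene2terms(gene2terms)

    if probes is None:
        probes = [f"cg{900000 + i:06d}" for i in range(5 * n_genes)]
    probe_genes: dict[str, set[str]] = {}
    for gene in genes:
        k = int(rng.integers(1, 6))
        chosen = rng.choice(len(probes), size=min(k, len(probes)), replace=False)
        for c in chosen:
            probe_genes.setdefault(probes[int(c)], set()).add(gene)
    rows = []
    for probe in probes:
        if probe not in probe_genes:
            continue
        region = REGION_GROUPS[int(rng.integers(len(REGION_GROUPS)))]
        rows.append({"probe": probe, "genes": tuple(sorted(probe_genes[probe])), "region": region})
    annot = ProbeAnnotation(pd.DataFrame(rows, columns=["probe", "genes", "region"]))
    return g, corpus, annot


def simulate_cohort(config: SimulationConfig):
    """End-to-end generation: truth, sheet, biased intensities, ontology.

    Returns ``(truth, sheet, dataset, graph, corpus, probe_annotation)``.
    """
    truth = generate_truth(config)
    sheet = generate_pairs_and_chips(config)
    clean = generate_intensities(config, truth, sheet)
    biased = inject_chip_bias(clean, truth)
    graph, corpus, annot = generate_ontology_corpus(
        config.n_genes, config.seed, probes=clean.probes
    )
    return truth, sheet, biased, graph, corpus, annot
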