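"""Per-probe pre-selection statistics: scaled CV, paired t-test, and
sign-flip bootstrap p-value correction, combined by the top-1% ∧
ScaledCV>1 rule and unioned across experiments.

The scaled CV compares a probe's coefficient of variation in the study
pool (controls ∪ cases of one experiment) to its CV across the QC
replicates, which see only technical variation; a ratio above 1 flags
variability beyond technical noise.  The paired t-test exploits the
matched case–control design, and its p-values are corrected against
multiple-hypothesis bias by a sign-flip resampling null: pair
differences are symmetric under the null, so randomly flipping their
signs regenerates the null distribution of the t statistic while
preserving the correlation structure across probes (one shared flip
matrix per replicate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .normalize import MethylationDataset, ProbeQCStats

MEAN_GUARD = 1e-8


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    seed: int = 0
    scheme: str = "signflip"

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if self.scheme not in ("signflip",):
            raise ValueError(f"unknown null scheme {self.scheme!r}")


@dataclass(frozen=True)
class PreselectionResult:
    """Selected probe sets per experiment, their union, and provenance."""

    per_experiment: dict[str, frozenset[str]]
    union: frozenset[str]
    provenance: dict[str, tuple[str, ...]]  # probe -> experiments that selected it
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        expect = frozenset().union(*self.per_experiment.values()) if self.per_experiment else frozenset()
        if self.union != expect:
            raise ValueError("union field inconsistent with per-experiment sets")


def experiment_pool(ds: MethylationDataset, disease: str) -> np.ndarray:
    """Column indices of the controls ∪ cases of one experiment's cohort."""
    frame = ds.sheet.frame
    ids = frame.loc[
        (frame["cohort"] == disease) & (frame["class_label"] != "QC"), "sample_id"
    ]
    return ds.columns(list(ids))


def scaled_cv(
    ds: MethylationDataset, qc: ProbeQCStats, disease: str, pool_cols: np.ndarray | None = None
) -> np.ndarray:
    """ScaledCV(p) = CV_pool(p) / CV_QC(p) with CV = sd/|mean| of M.

    Guards: when |mean| < 1e-8 on either side the ratio falls back to the
    plain sd ratio sd_pool/sd_QC for that probe (M-values cross zero and
    a raw CV explodes there); σ_QC = 0 yields +inf, which passes the
    ScaledCV > 1 criterion by construction.
    """
    cols = experiment_pool(ds, disease) if pool_cols is None else pool_cols
    if cols.size < 3:
        raise ValueError("scaled CV needs a pool of at least 3 samples")
    pool = ds.M[:, cols]
    sd_pool = pool.std(axis=1, ddof=1)
    mean_pool = pool.mean(axis=1)
    sd_qc = qc.sigma_qc
    mean_qc = qc.qc_mean

    with np.errstate(divide="ignore", invalid="ignore"):
        cv_pool = sd_pool / np.abs(mean_pool)
        cv_qc = sd_qc / np.abs(mean_qc)
        ratio = cv_pool / cv_qc
        sd_ratio = sd_pool / sd_qc
    degenerate = (np.abs(mean_pool) < MEAN_GUARD) | (np.abs(mean_qc) < MEAN_GUARD)
    out = np.where(degenerate, sd_ratio, ratio)
    out = np.where(sd_qc == 0, np.inf, out)
    out = np.where((sd_qc == 0) & (sd_pool == 0), 0.0, out)
    return out


def paired_differences(ds: MethylationDataset, disease: str) -> np.ndarray:
    """Per-probe case − control M differences, one column per matched pair."""
    pairs = ds.sheet.pairs(disease)
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    ctrl = ds.columns([c for c, _ in pairs])
    case = ds.columns([c for _, c in pairs])
    return ds.M[:, case] - ds.M[:, ctrl]


def _t_from_diffs(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = diffs.shape[-1]
    mean = diffs.mean(axis=-1)
    sd = diffs.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t, sd


def paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired t statistic and two-sided p, df = n−1, from a (probes ×
    pairs) difference matrix.  Degenerate probes (zero-variance, nonzero
    mean differences) get the smallest positive p with a warning."""
    n = diffs.shape[-1]
    if n < 2:
        raise ValueError("need >= 2 pairs")
    t, sd = _t_from_diffs(diffs)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    degen = np.isinf(t)
    if degen.any():
        warnings.warn(
            f"{int(degen.sum())} probe(s) with zero-variance nonzero differences; "
            "p set to smallest representable",
            stacklevel=2,
        )
        p = np.where(degen, np.finfo(float).tiny, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p


def signflip_bootstrap_correct(
    diffs: np.ndarray, t_raw: np.ndarray, cfg: BootstrapConfig
) -> np.ndarray:
    """Bootstrap-corrected p: p_boot = (1 + #{b : |t*_b| ≥ |t_raw|})/(B+1).

    Null replicates flip the sign of each pair's difference (one shared
    Rademacher vector per replicate across all probes).  Because sign
    flips leave Σd² unchanged, the replicate t* follows from the flipped
    mean alone, so the whole null ensemble is two matrix products.
    Comparing |t*| with |t_raw| is equivalent to comparing the
    corresponding p-values at equal degrees of freedom.
    """
    P, n = diffs.shape
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))
    flips = rng.choice([-1.0, 1.0], size=(cfg.B, n))
    m_star = diffs @ flips.T / n  # (P, B)
    ss = (diffs**2).sum(axis=1)  # flip-invariant
    with np.errstate(divide="ignore", invalid="ignore"):
        var_star = (ss[:, None] - n * m_star**2) / (n - 1)
        t_star = m_star / np.sqrt(var_star / n)
    t_star = np.where(
        var_star <= 0, np.where(m_star == 0, 0.0, np.inf), np.abs(t_star)
    )
    count = (t_star >= np.abs(t_raw)[:, None]).sum(axis=1)
    return (1.0 + count) / (cfg.B + 1.0)


@dataclass(frozen=True)
class ProbeStatistics:
    """Per-probe statistics of one experiment, as a tidy frame."""

    experiment: str
    frame: pd.DataFrame  # columns: probe, scaled_cv, t_stat, p_raw, p_boot


def compute_probe_statistics(
    ds: MethylationDataset,
    qc: ProbeQCStats,
    disease: str,
    boot: BootstrapConfig,
) -> ProbeStatistics:
    diffs = paired_differences(ds, disease)
    t, p_raw = paired_t(diffs)
    p_boot = signflip_bootstrap_correct(diffs, t, boot)
    cv = scaled_cv(ds, qc, disease)
    frame = pd.DataFrame(
        {
            "probe": ds.probes,
            "scaled_cv": cv,
            "t_stat": t,
            "p_raw": p_raw,
            "p_boot": p_boot,
        }
    )
    return ProbeStatistics(experiment=f"controls-vs-{disease}", frame=frame)


def preselect_experiment(
    stats: ProbeStatistics, top_frac: float = 0.01, cv_min: float = 1.0
) -> frozenset[str]:
    """Keep the ⌈top_frac·P⌉ probes with smallest bootstrap-corrected p
    (ties broken by raw p, then probe id) that also have ScaledCV > cv_min."""
    frame = stats.frame
    n_top = math.ceil(top_frac * len(frame))
    ranked = frame.sort_values(["p_boot", "p_raw", "probe"], kind="mergesort")
    top = ranked.head(n_top)
    selected = frozenset(top.loc[top["scaled_cv"] > cv_min, "probe"])
    if not selected:
        warnings.warn(f"{stats.experiment}: empty pre-selection", stacklevel=2)
    return selected


def union_preselect(
    sets: dict[str, frozenset[str]], thresholds: dict[str, float] | None = None
) -> PreselectionResult:
    if not sets:
        raise ValueError("need at least one per-experiment set")
    union = frozenset().union(*sets.values())
    provenance = {
        probe: tuple(sorted(exp for exp, s in sets.items() if probe in s)) for probe in sorted(union)
    }
    return PreselectionResult(
        per_experiment=dict(sets),
        union=union,
        provenance=provenance,
        thresholds=dict(thresholds or {}),
    )
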