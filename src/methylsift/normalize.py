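"""β/M/average-intensity computation and two-step QC-based normalization.

The signal model works on M-values, M = log2(I_Meth/I_UnMeth), which are
approximately homoscedastic and therefore preferred over β for
statistics.  Technical bias is corrected in two successive steps using
the replicated technical QC sample carried on every chip:

(i)  *within chip* — for each chip, the QC replicates' M residuals
     against the cross-chip QC consensus are binned along the average
     intensity axis I = 0.5·log2(I_Meth·I_UnMeth) into percentile bins;
     the per-bin mean residual is the chip's intensity-dependent error
     and is subtracted from every measurement on the chip falling in
     that bin;

(ii) *across probes* — the per-probe standard deviation of QC M-values,
     σ_QC, is subtracted from every study sample's M for that probe.
     This step shifts each probe by a constant, so it never alters any
     between-sample contrast; σ_QC is retained because it is also the
     denominator of the downstream scaled-CV statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .simulate import IntensityDataset, SampleSheet

CHANNEL_FLOOR = 1.0


def beta_value(i_meth, i_unmeth):
    """Fraction methylated, β = I_Meth/(I_Meth + I_UnMeth) ∈ [0, 1]."""
    i_meth = np.asarray(i_meth, dtype=float)
    i_unmeth = np.asarray(i_unmeth, dtype=float)
    if (i_meth < 0).any() or (i_unmeth < 0).any():
        raise ValueError("negative channel intensity")
    total = i_meth + i_unmeth
    if (total <= 0).any():
        raise ValueError("uninformative probe: both channels zero")
    return i_meth / total


def _floored(x):
    return np.maximum(np.asarray(x, dtype=float), CHANNEL_FLOOR)


def m_value(i_meth, i_unmeth):
    """M = log2(I_Meth/I_UnMeth); channels below 1 are floored to 1."""
    return np.log2(_floored(i_meth)) - np.log2(_floored(i_unmeth))


def avg_intensity(i_meth, i_unmeth):
    """I = 0.5·log2(I_Meth·I_UnMeth); channels below 1 are floored to 1."""
    return 0.5 * (np.log2(_floored(i_meth)) + np.log2(_floored(i_unmeth)))


@dataclass(frozen=True)
class MethylationDataset:
    """M-value and average-intensity matrices with sample metadata."""

    probes: list[str]
    samples: list[str]
    M: np.ndarray
    I: np.ndarray
    sheet: SampleSheet

    def __post_init__(self) -> None:
        shape = (len(self.probes), len(self.samples))
        if self.M.shape != shape or self.I.shape != shape:
            raise ValueError("matrix shape does not match probe/sample ids")
        if not np.isfinite(self.M).all() or not np.isfinite(self.I).all():
            raise ValueError("non-finite M or I values")

    def columns(self, sample_ids) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.samples)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def qc_columns(self) -> np.ndarray:
        return self.columns(self.sheet.qc_ids())

    def study_columns(self) -> np.ndarray:
        return self.columns(self.sheet.study_ids())


def compute_m_dataset(ds: IntensityDataset) -> MethylationDataset:
    """Convert a two-channel intensity dataset to M/I matrices."""
    return MethylationDataset(
        probes=list(ds.probes),
        samples=list(ds.samples),
        M=m_value(ds.meth, ds.unmeth),
        I=avg_intensity(ds.meth, ds.unmeth),
        sheet=ds.sheet,
    )


@dataclass(frozen=True)
class ProbeQCStats:
    """QC-derived statistics: per-probe consensus mean and σ_QC of M, and
    the per-chip intensity-bin error estimates of the within-chip step."""

    consensus: np.ndarray  # per-probe mean of QC M across all replicates
    qc_mean: np.ndarray  # alias of consensus (kept for the scaled-CV denominator)
    sigma_qc: np.ndarray  # per-probe n-1 sd of QC M
    bin_edges: np.ndarray  # shared I-percentile edges (len n_eff_bins + 1)
    bin_errors: dict[str, np.ndarray]  # chip -> per-bin mean QC residual

    def __post_init__(self) -> None:
        if (self.sigma_qc < 0).any():
            raise ValueError("sigma_qc must be non-negative")
        for chip, err in self.bin_errors.items():
            if not np.isfinite(err).all():
                raise ValueError(f"non-finite bin error on chip {chip}")


MIN_QC_PER_BIN = 3


def _qc_consensus(ds: MethylationDataset):
    qc_cols = ds.qc_columns()
    if qc_cols.size == 0:
        raise ValueError("dataset has no QC replicates")
    qc_m = ds.M[:, qc_cols]
    consensus = qc_m.mean(axis=1)
    if qc_cols.size == 1:
        warnings.warn("single QC replicate overall: sigma_qc set to 0", stacklevel=3)
        sigma = np.zeros(len(ds.probes))
    else:
        sigma = qc_m.std(axis=1, ddof=1)
    return qc_cols, qc_m, consensus, sigma


def _percentile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(values, qs)
    edges = np.unique(edges)
    if len(edges) < 2:  # constant intensities: single all-covering bin
        return np.array([-np.inf, np.inf])
    edges[0] = -np.inf
    edges[-1] = np.inf
    return edges


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)


def _merge_thin_bins(counts: np.ndarray) -> np.ndarray:
    """Map raw bin index -> merged group index so every group has at
    least MIN_QC_PER_BIN QC measurements (thin bins absorb into the
    previous group; a thin trailing group merges backwards)."""
    groups = np.zeros(len(counts), dtype=int)
    g = 0
    acc = 0
    for k in range(len(counts)):
        if acc >= MIN_QC_PER_BIN:
            g += 1
            acc = 0
        groups[k] = g
        acc += counts[k]
    if acc < MIN_QC_PER_BIN and g > 0:
        groups[groups == g] = g - 1
    return groups


def within_chip_correct(
    ds: MethylationDataset, n_bins: int = 100
) -> tuple[MethylationDataset, ProbeQCStats]:
    """Within-chip intensity-binned error correction.

    Bin edges are the percentiles of the pooled QC average intensities
    (shared across chips); each chip's bin error is the mean residual of
    its own QC measurements (QC M minus the cross-chip QC consensus for
    that probe) within the bin.  Bins with fewer than three QC
    measurements on a chip merge with their neighbors.  The bin error is
    subtracted from every measurement (study and QC) on the chip.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    qc_cols, qc_m, consensus, sigma = _qc_consensus(ds)
    chips = ds.sheet.chip_of()
    sample_chip = np.array([chips[s] for s in ds.samples])
    qc_chips = sample_chip[qc_cols]
    for chip in sorted(set(sample_chip)):
        if chip not in set(qc_chips):
            raise ValueError(f"chip {chip!r} has no QC replicate")

    edges = _percentile_edges(ds.I[:, qc_cols].ravel(), n_bins)
    n_raw_bins = len(edges) - 1

    M_new = ds.M.copy()
    bin_errors: dict[str, np.ndarray] = {}
    residuals = qc_m - consensus[:, None]
    for chip in sorted(set(sample_chip)):
        chip_qc_local = np.flatnonzero(qc_chips == chip)
        chip_qc_bins = _bin_index(ds.I[:, qc_cols[chip_qc_local]].ravel(), edges)
        chip_res = residuals[:, chip_qc_local].ravel()
        counts = np.bincount(chip_qc_bins, minlength=n_raw_bins)
        groups = _merge_thin_bins(counts)
        n_groups = groups.max() + 1
        sums = np.bincount(groups[chip_qc_bins], weights=chip_res, minlength=n_groups)
        gcounts = np.bincount(groups[chip_qc_bins], minlength=n_groups)
        errors = np.where(gcounts > 0, sums / np.maximum(gcounts, 1), 0.0)
        per_bin_error = errors[groups]
        bin_errors[chip] = per_bin_error

        chip_cols = np.flatnonzero(sample_chip == chip)
        bins = _bin_index(ds.I[:, chip_cols], edges)
        M_new[:, chip_cols] -= per_bin_error[bins]

    corrected = replace(ds, M=M_new)
    # sigma recomputed on the corrected data: it feeds the across-probe
    # step and the scaled CV, both of which should see post-correction
    # technical spread
    _, _, consensus_c, sigma_c = _qc_consensus(corrected)
    stats = ProbeQCStats(
        consensus=consensus_c,
        qc_mean=consensus_c,
        sigma_qc=sigma_c,
        bin_edges=edges,
        bin_errors=bin_errors,
    )
    return corrected, stats


def across_probe_correct(ds: MethylationDataset, qc: ProbeQCStats) -> MethylationDataset:
    """Subtract the per-probe QC error estimate σ_QC from every study
    sample.  A constant per-probe shift: paired differences and all
    between-sample contrasts are exactly preserved."""
    if qc.sigma_qc.shape[0] != len(ds.probes):
        raise ValueError("sigma_qc not available for every probe")
    M_new = ds.M.copy()
    study = ds.study_columns()
    M_new[:, study] -= qc.sigma_qc[:, None]
    return replace(ds, M=M_new)


def qc_replicate_variance(ds: MethylationDataset) -> float:
    """Mean over probes of the replicate variance of QC M-values."""
    qc_cols = ds.qc_columns()
    if qc_cols.size < 2:
        raise ValueError("need >= 2 QC replicates to measure variance")
    return float(ds.M[:, qc_cols].var(axis=1, ddof=1).mean())


def normalize_dataset(
    raw: IntensityDataset, n_bins: int = 100
) -> tuple[MethylationDataset, ProbeQCStats, dict]:
    """Full pipeline: M/I computation → within-chip → across-probe.

    Returns the corrected dataset, the QC statistics, and a small report
    with the QC replicate variance before and after correction.
    """
    ds = compute_m_dataset(raw)
    var_before = qc_replicate_variance(ds) if len(ds.qc_columns()) >= 2 else float("nan")
    corrected, stats = within_chip_correct(ds, n_bins=n_bins)
    var_after = qc_replicate_variance(corrected) if len(ds.qc_columns()) >= 2 else float("nan")
    final = across_probe_correct(corrected, stats)
    report = {
        "n_bins": n_bins,
        "qc_variance_before": var_before,
        "qc_variance_after": var_after,
        "qc_variance_reduction": (
            1.0 - var_after / var_before if var_before and var_before > 0 else float("nan")
        ),
    }
    return final, stats, report
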