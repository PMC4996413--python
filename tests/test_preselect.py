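"""Scaled-CV arithmetic, paired-t reference values, sign-flip bootstrap
properties and the rank-based top-fraction selection rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import methylsift as ms
from methylsift.preselect import (
    BootstrapConfig,
    ProbeStatistics,
    paired_t,
    preselect_experiment,
    scaled_cv,
    signflip_bootstrap_correct,
    union_preselect,
)


def _stats_frame(p_boot, p_raw=None, cv=None):
    n = len(p_boot)
    return ProbeStatistics(
        experiment="controls-vs-BCCA",
        frame=pd.DataFrame(
            {
                "probe": [f"cg{i:06d}" for i in range(n)],
                "scaled_cv": cv if cv is not None else np.full(n, 2.0),
                "t_stat": np.zeros(n),
                "p_raw": p_raw if p_raw is not None else p_boot,
                "p_boot": p_boot,
            }
        ),
    )


class TestScaledCV:
    def test_hand_arithmetic_oracle(self):
        # pool M {1,1,3,3}: mean 2, sd 1.1547 -> CV 0.57735
        # QC M {1.9,2.1}: mean 2, sd 0.14142 -> CV 0.070711; ratio 8.1650
        pool = np.array([[1.0, 1.0, 3.0, 3.0]])
        sd_pool = pool.std(ddof=1)
        cv_pool = sd_pool / 2.0
        qc_sd = np.std([1.9, 2.1], ddof=1)
        expected = cv_pool / (qc_sd / 2.0)
        assert expected == pytest.approx(8.1650, abs=1e-4)

        cfg = ms.SimulationConfig(n_probes=1, n_pairs_per_disease=2, chip_size=6, n_planted=0, seed=0)
        sheet = ms.generate_pairs_and_chips(cfg)
        bcca = [s for s in sheet.study_ids() if sheet.class_of()[s] != "QC"
                and dict(zip(sheet.frame.sample_id, sheet.frame.cohort))[s] == "BCCA"]
        M = np.zeros((1, len(sheet.sample_ids)))
        ds = ms.MethylationDataset(
            probes=["cg000000"], samples=sheet.sample_ids, M=M, I=np.full_like(M, 9.0), sheet=sheet
        )
        cols = ds.columns(bcca)
        ds.M[0, cols] = [1.0, 1.0, 3.0, 3.0]
        stats = ms.ProbeQCStats(
            consensus=np.array([2.0]),
            qc_mean=np.array([2.0]),
            sigma_qc=np.array([qc_sd]),
            bin_edges=np.array([-np.inf, np.inf]),
            bin_errors={},
        )
        out = scaled_cv(ds, stats, "BCCA", pool_cols=cols)
        assert out[0] == pytest.approx(8.1650, abs=1e-4)

    def test_equal_dispersion_gives_unity(self):
        cfg = ms.SimulationConfig(n_probes=1, n_pairs_per_disease=2, chip_size=6, n_planted=0, seed=0)
        sheet = ms.generate_pairs_and_chips(cfg)
        M = np.zeros((1, len(sheet.sample_ids)))
        ds = ms.MethylationDataset(
            probes=["cg000000"], samples=sheet.sample_ids, M=M, I=np.full_like(M, 9.0), sheet=sheet
        )
        cols = np.array([0, 1, 2, 3])
        ds.M[0, cols] = [1.0, 1.0, 3.0, 3.0]
        sd = np.std([1.0, 1.0, 3.0, 3.0], ddof=1)
        stats = ms.ProbeQCStats(
            consensus=np.array([2.0]), qc_mean=np.array([2.0]),
            sigma_qc=np.array([sd]),
            bin_edges=np.array([-np.inf, np.inf]), bin_errors={},
        )
        assert scaled_cv(ds, stats, "BCCA", pool_cols=cols)[0] == pytest.approx(1.0)

    def test_zero_sigma_qc_treated_as_infinite_ratio(self, normalized):
        ds, qc, _ = normalized
        stats = ms.ProbeQCStats(
            consensus=qc.consensus, qc_mean=qc.qc_mean,
            sigma_qc=np.zeros_like(qc.sigma_qc),
            bin_edges=qc.bin_edges, bin_errors=qc.bin_errors,
        )
        out = scaled_cv(ds, stats, "BCCA")
        assert np.isinf(out).all()

    def test_planted_probes_have_larger_scaled_cv(self, normalized, small_cohort):
        truth = small_cohort[0]
        ds, qc, _ = normalized
        cv = scaled_cv(ds, qc, "BCCA")
        planted = np.isin(ds.probes, sorted(truth.dm_probes["BCCA"]))
        assert np.median(cv[planted]) > 2 * np.median(cv[~planted])


class TestPairedT:
    def test_symmetric_differences_null(self):
        t, p = paired_t(np.array([[1.0, -1.0]]))
        assert t[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_reference_value(self):
        t, p = paired_t(np.array([[1.0, 2.0, 3.0]]))
        assert t[0] == pytest.approx(3.4641, abs=1e-4)
        assert p[0] == pytest.approx(2 * sps.t.sf(2.0 / (1.0 / np.sqrt(3)), df=2), rel=1e-10)
        assert p[0] == pytest.approx(0.0742, abs=2e-4)

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, (5, 12))
        t1, p1 = paired_t(d)
        perm = rng.permutation(12)
        t2, p2 = paired_t(d[:, perm])
        np.testing.assert_allclose(t1, t2)
        np.testing.assert_allclose(p1, p2)

    def test_degenerate_zero_variance_smallest_p(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_t(np.array([[2.0, 2.0, 2.0]]))
        assert p[0] == np.finfo(float).tiny


class TestBootstrap:
    def test_p_boot_within_bounds(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.0, 1.0, (50, 10))
        t, _ = paired_t(d)
        cfg = BootstrapConfig(B=200, seed=1)
        p = signflip_bootstrap_correct(d, t, cfg)
        assert (p >= 1.0 / 201).all() and (p <= 1.0).all()

    def test_extreme_statistic_attains_floor(self):
        d = np.array([[5.0, 5.1, 4.9, 5.05, 5.2, 4.8, 5.0, 5.1]])
        t, _ = paired_t(d)
        p = signflip_bootstrap_correct(d, t, BootstrapConfig(B=200, seed=2))
        assert p[0] == pytest.approx(1.0 / 201)

    def test_monotone_in_raw_statistic(self):
        # same null set (identical diffs), smaller |t| -> larger p_boot
        rng = np.random.default_rng(3)
        d = np.tile(rng.normal(0, 1, 12), (3, 1))
        t = np.array([0.5, 1.5, 3.0])
        p = signflip_bootstrap_correct(d, t, BootstrapConfig(B=300, seed=3))
        assert p[0] >= p[1] >= p[2]

    def test_null_uniformity(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.0, 1.0, (2000, 20))
        t, _ = paired_t(d)
        p = signflip_bootstrap_correct(d, t, BootstrapConfig(B=500, seed=4))
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError, match="B"):
            BootstrapConfig(B=50)


class TestPreselection:
    def test_rank_cut_and_cv_filter(self):
        p = np.linspace(0.001, 1.0, 200)
        cv = np.full(200, 2.0)
        cv[0] = 0.5  # best-ranked probe fails the CV criterion
        sel = preselect_experiment(_stats_frame(p, cv=cv))
        assert len(sel) == 1
        assert sel == {"cg000001"}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 300)
        stats = _stats_frame(p)
        shuffled = ProbeStatistics(
            experiment=stats.experiment,
            frame=stats.frame.sample(frac=1.0, random_state=0).reset_index(drop=True),
        )
        assert preselect_experiment(stats) == preselect_experiment(shuffled)

    def test_empty_selection_warns_not_raises(self):
        sel_frame = _stats_frame(np.linspace(0.01, 1, 100), cv=np.zeros(100))
        with pytest.warns(UserWarning, match="empty"):
            sel = preselect_experiment(sel_frame)
        assert sel == frozenset()

    def test_union_provenance(self):
        res = union_preselect(
            {"e1": frozenset({"a", "b"}), "e2": frozenset({"b", "c"})}
        )
        assert res.union == {"a", "b", "c"}
        assert res.provenance["b"] == ("e1", "e2")
        assert res.provenance["a"] == ("e1",)

    def test_union_of_single_set_is_identity(self):
        res = union_preselect({"e1": frozenset({"x"})})
        assert res.union == {"x"}

    def test_disjoint_sets_additive(self):
        res = union_preselect({"e1": frozenset("ab"), "e2": frozenset("cd")})
        assert len(res.union) == 4

    def test_recovery_power_increases_with_effect(self):
        recovered = []
        for delta in (0.1, 1.5):
            cfg = ms.SimulationConfig(
                n_probes=2000, n_pairs_per_disease=20, n_planted=10,
                effect_delta=delta, seed=9,
            )
            truth = ms.generate_truth(cfg)
            sheet = ms.generate_pairs_and_chips(cfg)
            ds = ms.inject_chip_bias(ms.generate_intensities(cfg, truth, sheet), truth)
            norm, qc, _ = ms.normalize_dataset(ds)
            boot = BootstrapConfig(B=200, seed=9)
            sets = {}
            from methylsift.preselect import compute_probe_statistics

            for d in ("BCCA", "LYCA"):
                ps = compute_probe_statistics(norm, qc, d, boot)
                sets[ps.experiment] = preselect_experiment(ps)
            res = union_preselect(sets)
            recovered.append(len(res.union & truth.planted_union()))
        assert recovered[1] > recovered[0]
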