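import numpy as np
import pytest

from rnatrends.aggregate import cv_filter, group_age_series
from rnatrends.catalog import HG, INTG
from rnatrends.simulate import (
    SimulationConfig,
    calibration_run,
    generate,
    null_config,
    slope_recovery,
)
from rnatrends.trends import fit_line, segment_fits


class TestConfig:
    def test_group_means_are_piecewise_linear(self):
        cfg = SimulationConfig(hg_start=100, hg_slope=-2, breakpoint=9, late_slope_factor=0.5)
        m = cfg.group_means(HG)
        ages = np.asarray(cfg.ages)
        expect = np.where(ages <= 9, 100 - 2 * (ages - 1), 84 - 1.0 * (ages - 9))
        assert np.allclose(m, expect)

    def test_trend_underflow_raises(self):
        cfg = SimulationConfig(intg_start=10.0, intg_slope=-2.0)
        with pytest.raises(ValueError, match="trend underflow"):
            cfg.group_means(INTG)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_genes=1),
            dict(hg_fraction=1.5),
            dict(ages=(3.0, 1.0)),
            dict(replicates_per_cell=4),
            dict(replicate_cv=-0.1),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestGenerate:
    def test_same_seed_identical_datasets(self):
        cfg = SimulationConfig(n_genes=30, n_tissues=2, seed=5)
        a, _ = generate(cfg)
        b, _ = generate(cfg)
        assert a.matrix.equals(b.matrix)
        assert a.samples.equals(b.samples)

    def test_different_seeds_differ(self):
        a, _ = generate(SimulationConfig(n_genes=30, n_tissues=2, seed=5))
        b, _ = generate(SimulationConfig(n_genes=30, n_tissues=2, seed=6))
        assert not a.matrix.equals(b.matrix)

    def test_structure_matches_config(self):
        cfg = SimulationConfig(n_genes=40, n_tissues=3, replicates_per_cell=5, seed=0)
        ds, truth = generate(cfg)
        assert ds.matrix.shape == (40, 3 * 10 * 5)
        assert len(truth.hg_genes) == cfg.n_hg
        assert set(ds.samples["sex"]) == {"M", "F"}
        # 3M+2F per cell
        one_cell = ds.samples[(ds.samples.tissue == "T01") & (ds.samples.age_months == 1.0)]
        assert list(one_cell["sex"]).count("M") == 3

    def test_noiseless_replicates_equal_expectation(self):
        cfg = SimulationConfig(
            n_genes=50, n_tissues=2, replicate_cv=0.0, tissue_effect_sd=0.0,
            high_var_fraction=0.0, seed=3,
        )
        ds, truth = generate(cfg)
        hg = group_age_series(ds, truth.hg_genes)
        assert np.allclose(hg.mean, truth.expected_group_means[HG], atol=1e-9)
        early, late = segment_fits(hg, cfg.breakpoint)
        assert early.slope == pytest.approx(cfg.hg_slope, abs=1e-9)
        assert late.slope == pytest.approx(cfg.hg_slope * cfg.late_slope_factor, abs=1e-9)

    def test_replicate_cv_is_calibrated(self):
        """Empirical within-cell CV of ordinary genes tracks replicate_cv."""
        cfg = SimulationConfig(
            n_genes=1000, n_tissues=2, replicate_cv=0.3, high_var_fraction=0.0, seed=9,
        )
        ds, _ = generate(cfg)
        cvs = []
        for (tissue, age), cols in _cells(ds).items():
            sub = ds.matrix[cols]
            cvs.append((sub.std(axis=1, ddof=1) / sub.mean(axis=1)).to_numpy())
        emp = float(np.mean(np.concatenate(cvs)))
        assert emp == pytest.approx(0.3, rel=0.10)

    def test_cv_filter_separates_high_variance_subset(self):
        """The CV<1 filter hits high-variance genes, and essentially only them.

        With log-normal replicate noise and 6 animals, the sample CV of a
        true-CV-1.5 gene exceeds 1 in ~38% of cells (the sample CV of a
        right-skewed distribution is biased far below its true value at
        n=6), while ordinary CV-0.3 genes are virtually never caught; the
        filter's job is this separation, not complete removal.
        """
        hv_removed, ord_removed = [], []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(
                n_genes=200, n_tissues=2, replicates_per_cell=6,
                high_var_fraction=0.25, high_var_cv=1.5, seed=seed,
            )
            ds, truth = generate(cfg)
            filtered, _ = cv_filter(ds, 1.0)
            hv = list(truth.high_var_genes)
            ordinary = [g for g in ds.genes if g not in set(hv)]
            hv_removed.append(1.0 - filtered.mask.loc[hv].to_numpy().mean())
            ord_removed.append(1.0 - filtered.mask.loc[ordinary].to_numpy().mean())
        assert np.mean(hv_removed) > 0.25
        assert np.mean(ord_removed) < 0.01
        assert np.mean(hv_removed) > 20 * max(np.mean(ord_removed), 1e-4)

    def test_truth_record_expected_series(self):
        cfg = SimulationConfig(n_genes=20, n_tissues=2, seed=0)
        _, truth = generate(cfg)
        s = truth.expected_series(HG)
        assert np.allclose(s.mean, cfg.group_means(HG))


def _cells(ds):
    cells = {}
    for sample, row in ds.samples.iterrows():
        cells.setdefault((row["tissue"], row["age_months"]), []).append(sample)
    return cells


class TestHarnesses:
    def test_alpha_one_rejects_always(self):
        with pytest.warns(UserWarning, match="coarse"):
            res = calibration_run(null_config(seed=1, n_genes=20), 5, alpha=1.0)
        assert res.rate == 1.0 and res.mode == "type_i"

    def test_large_effect_gives_full_power(self):
        cfg = null_config(seed=2, n_genes=40, hg_slope=-8.0, intg_slope=0.0, replicate_cv=0.05)
        with pytest.warns(UserWarning, match="coarse"):
            res = calibration_run(cfg, 10)
        assert res.mode == "power" and res.rate == 1.0

    def test_noiseless_config_rejected(self):
        cfg = null_config(seed=0, replicate_cv=0.0, tissue_effect_sd=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            calibration_run(cfg, 100)

    def test_recovery_truth_matches_configured_early_slope(self):
        cfg = SimulationConfig(n_genes=40, n_tissues=2, seed=4)
        rec = slope_recovery(cfg, 3, interval=(1, 9))
        assert rec[HG].truth == pytest.approx(cfg.hg_slope)
        assert rec[INTG].truth == pytest.approx(cfg.intg_slope)
        assert len(rec[HG].estimates) == 3
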