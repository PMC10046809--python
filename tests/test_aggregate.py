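import numpy as np
import pandas as pd
import pytest

from rnatrends.aggregate import (
    cv_filter,
    group_age_series,
    load_dataset,
    production_coverage,
    write_dataset,
)
from rnatrends.catalog import partition
from rnatrends.simulate import SimulationConfig, generate

from conftest import make_dataset


class TestLoadDataset:
    def test_toy_files(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "gene\ts1\ts2\nActb\t1.0\t2.0\nGapdh\t3.0\t4.0\n"
        )
        (tmp_path / "meta.tsv").write_text(
            "sample\ttissue\tage_months\tsex\ns1\tBrain\t1\tM\ns2\tBrain\t3\tF\n"
        )
        ds = load_dataset(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert ds.matrix.shape == (2, 2)
        assert list(ds.ages) == [1.0, 3.0]
        assert ds.mask.all().all()

    def test_missing_metadata_column_named(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts2\nActb\t1\t2\n")
        (tmp_path / "meta.tsv").write_text(
            "sample\ttissue\tage_months\tsex\ns1\tBrain\t1\tM\n"
        )
        with pytest.raises(ValueError, match="s2"):
            load_dataset(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_bad_age_names_sample(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\nActb\t1\n")
        (tmp_path / "meta.tsv").write_text(
            "sample\ttissue\tage_months\tsex\ns1\tBrain\told\tM\n"
        )
        with pytest.raises(ValueError, match="s1"):
            load_dataset(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_duplicate_sample_id_fatal(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene\ts1\ts1.1\nActb\t1\t2\n")
        (tmp_path / "meta.tsv").write_text(
            "sample\ttissue\tage_months\tsex\ns1\tBrain\t1\tM\ns1\tBrain\t3\tF\n"
        )
        with pytest.raises(ValueError, match="duplicated sample"):
            load_dataset(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_simulated_cohort_round_trips(self, tmp_path):
        ds, _ = generate(SimulationConfig(n_genes=20, n_tissues=2, seed=1))
        write_dataset(ds, tmp_path / "m.tsv", tmp_path / "meta.tsv")
        back = load_dataset(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        pd.testing.assert_frame_equal(back.matrix, ds.matrix)
        pd.testing.assert_frame_equal(back.samples, ds.samples)


class TestCvFilter:
    def test_zero_cv_is_valid(self):
        ds = make_dataset({"A": 10.0}, reps=3)
        ds, rep = cv_filter(ds)
        assert rep.n_invalidated == 0

    def test_high_cv_cell_invalidated(self):
        # replicates (1, 100, 1): mean 34, sample sd 57.16 -> CV 1.68 >= 1
        ds = make_dataset({"A": 1.0}, ages=(1.0,), reps=3)
        ds.matrix.loc["A"] = [1.0, 100.0, 1.0]
        ds, rep = cv_filter(ds)
        assert rep.n_invalidated == 1
        assert not ds.mask.loc["A", ("T1", 1.0)]

    def test_zero_mean_cell_invalidated(self):
        ds = make_dataset({"A": 0.0}, ages=(1.0,), reps=3)
        _, rep = cv_filter(ds)
        assert rep.n_invalidated == 1

    def test_huge_threshold_is_vacuous(self, small_cohort):
        ds, _ = small_cohort
        _, rep = cv_filter(ds, threshold=1e12)
        assert rep.n_invalidated == 0

    def test_threshold_must_be_positive(self, toy_dataset):
        with pytest.raises(ValueError, match="positive"):
            cv_filter(toy_dataset, threshold=0.0)

    def test_single_replicate_cell_rejected(self):
        ds = make_dataset({"A": 1.0}, ages=(1.0,), reps=1)
        with pytest.raises(ValueError, match="replicate"):
            cv_filter(ds)

    @pytest.mark.parametrize("t_low,t_high", [(0.5, 1.0), (1.0, 2.0)])
    def test_monotone_in_threshold(self, small_cohort, t_low, t_high):
        """Raising the threshold never invalidates additional cells."""
        ds, _ = small_cohort
        m_low = cv_filter(ds, t_low)[0].mask
        m_high = cv_filter(ds, t_high)[0].mask
        assert (m_high | ~m_low).all().all()  # invalid@high => invalid@low


class TestGroupAgeSeries:
    def test_constant_gene_degenerate_ci(self):
        ds = make_dataset({"A": 7.0})
        s = group_age_series(ds, ["A"])
        assert np.allclose(s.mean, 7.0)
        assert np.allclose(s.ci_low, 7.0) and np.allclose(s.ci_high, 7.0)

    def test_group_mean_is_mean_of_gene_means(self):
        ds = make_dataset({"A": 10.0, "B": 20.0})
        s = group_age_series(ds, ["A", "B"])
        assert np.allclose(s.mean, 15.0)
        assert list(s.n_genes) == [2, 2, 2]

    def test_invalid_cells_excluded_from_gene_mean(self):
        ds = make_dataset({"A": 5.0}, tissues=("T1", "T2"), ages=(1.0,), reps=3)
        ds.matrix.loc["A", ["T2_1_0", "T2_1_1", "T2_1_2"]] = [1.0, 100.0, 1.0]
        ds, _ = cv_filter(ds)
        s = group_age_series(ds, ["A"])
        assert s.mean[0] == pytest.approx(5.0)  # noisy T2 cell masked out

    def test_empty_group_raises(self, toy_dataset):
        with pytest.raises(ValueError, match="empty gene group"):
            group_age_series(toy_dataset, ["NotThere"])

    def test_aggregation_linearity(self, small_cohort):
        """Scaling the matrix by c scales every mean and CI bound by c."""
        ds, truth = small_cohort
        s1 = group_age_series(ds, truth.hg_genes)
        ds2 = make_scaled(ds, 3.0)
        s2 = group_age_series(ds2, truth.hg_genes)
        assert np.allclose(s2.mean, 3.0 * s1.mean)
        assert np.allclose(s2.ci_low, 3.0 * s1.ci_low)
        assert np.allclose(s2.ci_high, 3.0 * s1.ci_high)

    def test_hg_intg_series_use_disjoint_exhaustive_gene_sets(self, small_cohort):
        ds, truth = small_cohort
        cat = partition(list(ds.genes), list(truth.hg_genes))
        hg, ig = set(cat.hg_genes), set(cat.intg_genes)
        assert hg.isdisjoint(ig)
        assert hg | ig | set(cat.removed) == set(ds.genes)

    def test_tissue_subset_restricts_samples(self):
        ds = make_dataset({"A": 1.0}, tissues=("T1", "T2"))
        ds.matrix.loc["A", [c for c in ds.matrix.columns if c.startswith("T2")]] = 9.0
        s = group_age_series(ds, ["A"], tissues=["T1"])
        assert np.allclose(s.mean, 1.0)

    def test_pooled_mode_weights_samples_not_genes(self):
        ds = make_dataset({"A": 10.0, "B": 20.0})
        s = group_age_series(ds, ["A", "B"], gene_first=False)
        assert np.allclose(s.mean, 15.0)  # balanced design: same mean, wider basis


def make_scaled(ds, c):
    import dataclasses

    return dataclasses.replace(ds, matrix=ds.matrix * c, mask=ds.mask)


class TestProductionCoverage:
    @staticmethod
    def dataset(prods):
        ds = make_dataset({g: 1.0 for g in prods}, ages=(1.0,), reps=2)
        for g, p in prods.items():
            ds.matrix.loc[g] = p / 2.0  # two samples sum to p
        return ds

    def test_matches_prefix_enumeration(self):
        prods = {"A": 50.0, "B": 30.0, "C": 15.0, "D": 5.0}
        ds = self.dataset(prods)
        cat = partition(list(prods), ["A", "C"])
        rec = production_coverage(ds, cat, 0.8)
        # independent oracle: enumerate every prefix of the ranked list
        ranked = sorted(prods.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(prods.values())
        expect_n = next(
            i for i in range(1, 5) if sum(v for _, v in ranked[:i]) >= 0.8 * total
        )
        assert rec.n_genes_covering == expect_n == 2
        assert rec.share_of_genome == pytest.approx(0.5)
        assert rec.n_hg_among_them == 1

    def test_fraction_near_one_takes_all_producing_genes(self):
        ds = self.dataset({"A": 50.0, "B": 30.0, "C": 15.0, "D": 5.0})
        cat = partition(list("ABCD"), [])
        rec = production_coverage(ds, cat, 0.999999)
        assert rec.n_genes_covering == 4

    def test_monotone_in_fraction(self, small_cohort):
        ds, truth = small_cohort
        cat = partition(list(ds.genes), list(truth.hg_genes))
        sizes = [
            production_coverage(ds, cat, f).n_genes_covering
            for f in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes)

    def test_all_zero_matrix_raises(self):
        ds = make_dataset({"A": 0.0, "B": 0.0})
        cat = partition(["A", "B"], [])
        with pytest.raises(ValueError, match="all-zero"):
            production_coverage(ds, cat, 0.8)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_fraction_bounds(self, toy_dataset, bad):
        cat = partition(list(toy_dataset.genes), [])
        with pytest.raises(ValueError, match="fraction"):
            production_coverage(toy_dataset, cat, bad)
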