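"""Reference panels, DE ground truth, count generation, and the copula."""

import math

import numpy as np
import pytest
from scipy import stats

from sczeros import models as M
from sczeros import simulate as sim
from sczeros.models import CountModelParams, Family


@pytest.fixture(scope="module")
def two_type_panel():
    panel = sim.sample_reference_panel(300, [("A", 150), ("B", 150)], seed=5)
    return sim.strip_zero_inflation(panel)


class TestSamplePanel:
    def test_single_gene_panel(self):
        panel = sim.sample_reference_panel(1, [("A", 10)], seed=0)
        assert panel.n_genes == 1
        assert len(panel.populations[0].gene_models) == 1

    def test_umi_preset_has_no_zero_inflation(self):
        panel = sim.sample_reference_panel(500, [("A", 10)], seed=1)
        assert all(m.zero_inflation == 0 for m in panel.populations[0].gene_models)

    def test_smartseq2_preset_has_zero_inflation(self):
        panel = sim.sample_reference_panel(500, [("A", 10)], seed=1, preset="smartseq2-like")
        frac = np.mean([m.zero_inflation > 0 for m in panel.populations[0].gene_models])
        assert 0.4 < frac < 0.6

    def test_gene_mean_moments_match_preset(self):
        panel = sim.sample_reference_panel(2000, [("A", 10)], seed=2)
        logs = np.log([m.mean for m in panel.populations[0].gene_models])
        se_mean = 1.5 / math.sqrt(2000)
        assert abs(logs.mean() - 0.0) < 3 * se_mean
        se_sd = 1.5 / math.sqrt(2 * 2000)
        assert abs(logs.std() - 1.5) < 3 * se_sd

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sim.sample_reference_panel(0, [("A", 10)], seed=0)
        with pytest.raises(ValueError):
            sim.sample_reference_panel(5, [("A", 0)], seed=0)
        with pytest.raises(ValueError):
            sim.sample_reference_panel(5, [("A", 10)], seed=0, preset="bulk")


class TestStripZeroInflation:
    def test_identity_on_clean_panel(self, two_type_panel):
        stripped = sim.strip_zero_inflation(two_type_panel)
        for p1, p2 in zip(stripped.populations, two_type_panel.populations):
            assert p1.gene_models == p2.gene_models

    def test_zip_becomes_poisson(self):
        panel = sim.ReferencePanel(
            ["g0"],
            [sim.CellTypePopulationModel(
                "A", 5, [CountModelParams(Family.ZIP, 5.0, zero_inflation=0.3)]
            )],
        )
        out = sim.strip_zero_inflation(panel)
        m = out.populations[0].gene_models[0]
        assert m.family == Family.POISSON and m.mean == 5.0 and m.zero_inflation == 0.0

    def test_zero_proportion_never_increases(self):
        panel = sim.sample_reference_panel(300, [("A", 10)], seed=3, preset="smartseq2-like")
        out = sim.strip_zero_inflation(panel)
        for before, after in zip(
            panel.populations[0].gene_models, out.populations[0].gene_models
        ):
            assert M.zero_proportion(after) <= M.zero_proportion(before) + 1e-12


class TestDeTruth:
    def test_exact_de_count(self):
        panel = sim.sample_reference_panel(4000, [("A", 10), ("B", 10)], seed=4)
        panel = sim.strip_zero_inflation(panel)
        _, truth = sim.construct_de_truth(panel, "A", "B", n_de=1500)
        assert int(truth.is_de.sum()) == 1500

    def test_non_de_means_equalized(self, two_type_panel):
        new_panel, truth = sim.construct_de_truth(two_type_panel, "A", "B", n_de=60)
        a = new_panel.population("A").means()
        b = new_panel.population("B").means()
        np.testing.assert_allclose(a[~truth.is_de], b[~truth.is_de])
        assert np.all(truth.mean_a[~truth.is_de] == truth.mean_b[~truth.is_de])
        # DE genes keep their fitted means
        orig_a = two_type_panel.population("A").means()
        np.testing.assert_allclose(a[truth.is_de], orig_a[truth.is_de])

    def test_equal_means_unchanged_by_averaging(self):
        m = [CountModelParams(Family.POISSON, 2.0)]
        panel = sim.ReferencePanel(
            ["g0"],
            [
                sim.CellTypePopulationModel("A", 5, list(m)),
                sim.CellTypePopulationModel("B", 5, list(m)),
            ],
        )
        out, truth = sim.construct_de_truth(panel, "A", "B", n_de=0)
        assert out.population("A").gene_models[0].mean == 2.0
        assert out.population("B").gene_models[0].mean == 2.0

    def test_tie_break_deterministic(self, two_type_panel):
        _, t1 = sim.construct_de_truth(two_type_panel, "A", "B", n_de=100)
        _, t2 = sim.construct_de_truth(two_type_panel, "A", "B", n_de=100)
        np.testing.assert_array_equal(t1.is_de, t2.is_de)

    def test_n_de_bounds(self, two_type_panel):
        with pytest.raises(ValueError):
            sim.construct_de_truth(two_type_panel, "A", "B", n_de=10_000)


class TestGenerateCounts:
    def test_zero_mean_gene_is_all_zero(self):
        panel = sim.ReferencePanel(
            ["g0", "g1"],
            [sim.CellTypePopulationModel(
                "A",
                50,
                [CountModelParams(Family.POISSON, 0.0), CountModelParams(Family.POISSON, 2.0)],
            )],
        )
        counts = sim.generate_counts(panel, seed=1)
        assert np.all(counts.values[0] == 0)
        assert counts.cell_types == ["A"] * 50

    def test_nb_sample_mean_within_clt_bound(self):
        panel = sim.ReferencePanel(
            ["g0"],
            [sim.CellTypePopulationModel(
                "A", 2000, [CountModelParams(Family.NB, 5.0, dispersion=2.0)]
            )],
        )
        counts = sim.generate_counts(panel, seed=2)
        bound = 3 * math.sqrt((5 + 25 / 2) / 2000)
        assert abs(counts.values.mean() - 5.0) < bound

    def test_reproducible(self, two_type_panel):
        c1 = sim.generate_counts(two_type_panel, seed=7)
        c2 = sim.generate_counts(two_type_panel, seed=7)
        np.testing.assert_array_equal(c1.values, c2.values)

    def test_observed_zero_fraction_matches_model(self, two_type_panel):
        counts = sim.generate_counts(two_type_panel, seed=8)
        pop = two_type_panel.populations[0]
        block = counts.values[:, :150]
        for g in range(0, 300, 23):
            p0 = M.zero_proportion(pop.gene_models[g])
            obs = (block[g] == 0).mean()
            se = math.sqrt(max(p0 * (1 - p0), 1e-4) / 150)
            assert abs(obs - p0) < 4 * se + 1e-9


class TestFitPanel:
    def test_recovers_nb_families(self):
        gen = sim.sample_reference_panel(400, [("A", 300)], seed=11)
        counts = sim.generate_counts(gen, seed=12)
        fitted = sim.fit_reference_panel(counts)
        hits = total = 0
        for g, m in enumerate(gen.populations[0].gene_models):
            if m.family == Family.NB and m.dispersion <= 10 and m.mean >= 1:
                total += 1
                chosen = fitted.populations[0].gene_models[g].family
                hits += chosen in (Family.NB,)
        assert total > 30
        assert hits / total >= 0.8

    def test_round_trip_mean_error_shrinks_with_cells(self):
        errs = []
        for n_cells in (200, 2000):
            gen = sim.sample_reference_panel(200, [("A", n_cells)], seed=21)
            counts = sim.generate_counts(gen, seed=22)
            fitted = sim.fit_reference_panel(counts)
            true = gen.populations[0].means()
            est = fitted.populations[0].means()
            errs.append(np.sqrt(np.mean(((est - true) / np.maximum(true, 0.1)) ** 2)))
        assert errs[1] < errs[0]

    def test_single_cell_type_rejected(self):
        from sczeros import CountMatrix

        m = CountMatrix(np.ones((5, 3), dtype=int), cell_types=["A", "A", "B"])
        with pytest.raises(ValueError):
            sim.fit_reference_panel(m)

    def test_all_zero_gene_is_poisson_zero(self):
        from sczeros import CountMatrix

        rngv = np.random.default_rng(0)
        vals = rngv.poisson(2, (4, 20))
        vals[2] = 0
        m = CountMatrix(vals, cell_types=["A"] * 10 + ["B"] * 10)
        panel = sim.fit_reference_panel(m)
        for pop in panel.populations:
            g = pop.gene_models[2]
            assert g.family == Family.POISSON and g.mean == 0

    def test_unlabeled_matrix_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            sim.fit_reference_panel(small_matrix)


def test_non_de_mean_differences_centered_at_zero():
    """Generated two-type data: non-DE genes' sample-mean differences are
    centered at 0 (gene-wise t-test non-significant in >= 90% of seeds)."""
    non_sig = 0
    n_seeds = 20
    for s in range(n_seeds):
        panel = sim.sample_reference_panel(250, [("A", 100), ("B", 100)], seed=400 + s)
        panel = sim.strip_zero_inflation(panel)
        panel, truth = sim.construct_de_truth(panel, "A", "B", n_de=50)
        counts = sim.generate_counts(panel, seed=500 + s)
        a = counts.values[:, :100].mean(axis=1)
        b = counts.values[:, 100:].mean(axis=1)
        diffs = (a - b)[~truth.is_de]
        p = stats.ttest_1samp(diffs, 0.0).pvalue
        non_sig += p > 0.05
    assert non_sig >= 18


class TestCopula:
    def _panel(self, n_genes, n_cells, seed):
        panel = sim.sample_reference_panel(n_genes, [("A", n_cells)], seed=seed)
        return sim.strip_zero_inflation(panel)

    def test_null_correlation_bounded(self):
        panel = self._panel(30, 400, 31)
        counts = sim.generate_counts(panel, seed=32)
        fitted = sim.fit_copula(counts, panel, top_k=10, seed=33)
        _, corr = fitted.copula["A"]
        off = corr[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) < 3 / math.sqrt(400) + 0.05)

    def test_recovers_planted_correlation(self):
        # two NB genes coupled through a latent Gaussian rho = 0.8
        rng = np.random.default_rng(44)
        rho = 0.8
        n = 1000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        u = stats.norm.cdf(z)
        m1 = CountModelParams(Family.NB, 8.0, dispersion=2.0)
        m2 = CountModelParams(Family.NB, 4.0, dispersion=1.5)
        from sczeros import CountMatrix

        vals = np.vstack(
            [sim.ppf_counts(m1, u[:, 0]), sim.ppf_counts(m2, u[:, 1])]
        )
        counts = CountMatrix(vals, cell_types=["A"] * n)
        panel = sim.ReferencePanel(
            ["gene0", "gene1"], [sim.CellTypePopulationModel("A", n, [m1, m2])]
        )
        fitted = sim.fit_copula(counts, panel, top_k=2, seed=45)
        _, corr = fitted.copula["A"]
        assert abs(corr[0, 1] - rho) < 0.1

    def test_top_k_one_gives_trivial_matrix(self):
        panel = self._panel(5, 50, 51)
        counts = sim.generate_counts(panel, seed=52)
        fitted = sim.fit_copula(counts, panel, top_k=1)
        idx, corr = fitted.copula["A"]
        assert idx.size == 1
        np.testing.assert_array_equal(corr, [[1.0]])

    def test_identity_copula_matches_independent_marginals(self):
        panel = self._panel(6, 800, 61)
        idx = np.arange(6)
        panel.copula = {"A": (idx, np.eye(6))}
        dep = sim.generate_counts(panel, seed=62, use_copula=True)
        indep = sim.generate_counts(panel, seed=63)
        for g in range(6):
            m = panel.populations[0].gene_models[g]
            assert abs(dep.values[g].mean() - m.mean) < 5 * math.sqrt(
                m.variance / 800
            ) + 0.05
            assert abs(dep.values[g].mean() - indep.values[g].mean()) < 6 * math.sqrt(
                m.variance / 800
            ) + 0.05

    def test_missing_copula_rejected(self):
        panel = self._panel(5, 50, 71)
        with pytest.raises(ValueError):
            sim.generate_counts(panel, seed=72, use_copula=True)
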