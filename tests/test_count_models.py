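"""Count distribution pmfs, ML fitting, and LRT model selection."""

import math

import numpy as np
import pytest
from scipy import stats

from sczeros import models as M
from sczeros.models import CountModelParams, Family, fit_model, log_pmf, lrt_nested


def params(family, mean, dispersion=math.inf, p=0.0):
    return CountModelParams(Family(family), mean, dispersion=dispersion, zero_inflation=p)


class TestLogPmf:
    def test_poisson_at_zero(self):
        assert log_pmf(params("poisson", 1.0), 0) == pytest.approx(-1.0)

    def test_zip_with_p_zero_reduces_to_poisson(self):
        ks = np.arange(0, 15)
        zip_ll = log_pmf(params("zip", 1.0, p=0.0), ks)
        pois_ll = log_pmf(params("poisson", 1.0), ks)
        np.testing.assert_allclose(zip_ll, pois_ll)

    def test_zinb_mass_at_zero(self):
        # NB(0; mu=2, psi=1) = (psi/(psi+mu))^psi = 1/3
        val = log_pmf(params("zinb", 2.0, dispersion=1.0, p=0.5), 0)
        assert val == pytest.approx(math.log(0.5 + 0.5 / 3))

    @pytest.mark.parametrize(
        "pr",
        [
            params("poisson", 3.0),
            params("zip", 3.0, p=0.4),
            params("nb", 3.0, dispersion=2.0),
            params("zinb", 3.0, dispersion=2.0, p=0.4),
        ],
        ids=["poisson", "zip", "nb", "zinb"],
    )
    def test_normalization(self, pr):
        ks = np.arange(0, 400)
        assert np.exp(log_pmf(pr, ks)).sum() == pytest.approx(1.0, abs=1e-8)

    def test_rejects_negative_and_fractional_k(self):
        with pytest.raises(ValueError):
            log_pmf(params("poisson", 1.0), -1)
        with pytest.raises(ValueError):
            log_pmf(params("poisson", 1.0), 1.5)


class TestZeroProportion:
    @pytest.mark.parametrize(
        "pr, expected",
        [
            (params("poisson", 0.0), 1.0),
            (params("poisson", 1.0), math.exp(-1)),
            (params("nb", 1.0, dispersion=1.0), 0.5),
            (params("zinb", 2.0, dispersion=1.0, p=0.5), 0.5 + 0.5 / 3),
        ],
    )
    def test_closed_forms(self, pr, expected):
        assert M.zero_proportion(pr) == pytest.approx(expected)

    def test_invariants_of_params(self):
        with pytest.raises(ValueError):
            params("poisson", 1.0, p=0.1)  # no ZI for plain Poisson
        with pytest.raises(ValueError):
            params("poisson", 1.0, dispersion=2.0)  # Poisson has no dispersion
        assert params("poisson", 2.0).variance == pytest.approx(2.0)
        assert params("nb", 2.0, dispersion=1.0).variance > 2.0


class TestFitting:
    def test_poisson_mle_is_sample_mean(self):
        fit = fit_model([0, 1, 2, 3], "poisson")
        assert fit.params.mean == pytest.approx(1.5)
        assert fit.loglik == pytest.approx(
            float(np.sum(stats.poisson.logpmf([0, 1, 2, 3], 1.5)))
        )

    @pytest.mark.parametrize("family", ["poisson", "zip", "nb", "zinb"])
    def test_all_zero_counts_degenerate(self, family):
        fit = fit_model(np.zeros(30, dtype=int), family)
        assert fit.params.mean == 0
        assert fit.params.zero_inflation == 0
        assert fit.loglik == 0.0
        assert fit.converged

    def test_zip_parameter_recovery(self):
        rng = np.random.default_rng(42)
        x = M.sample(params("zip", 5.0, p=0.3), 2000, rng)
        fit = fit_model(x, "zip")
        assert abs(fit.params.zero_inflation - 0.3) < 0.05
        assert abs(fit.params.mean - 5.0) < 0.3

    def test_zip_matches_grid_search_oracle(self):
        # brute-force MLE over (lambda, p) on a fine lattice, tiny vectors
        lams = np.arange(0.01, 5.0, 0.01)
        ps = np.arange(0.0, 0.95, 0.01)
        for counts in ([0, 0, 1, 2], [0, 1, 1, 3, 0, 2], [1, 2, 3], [0, 0, 0, 3]):
            counts = np.asarray(counts)
            pois = stats.poisson.pmf(counts[None, None, :], lams[:, None, None])
            mix = (1 - ps[None, :, None]) * pois
            mix[..., counts == 0] += ps[None, :, None]
            ll = np.log(mix).sum(axis=-1)
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            fit = fit_model(counts, "zip")
            assert fit.loglik >= ll[i, j] - 1e-4
            assert abs(fit.params.mean - lams[i]) < 0.02 or fit.loglik > ll[i, j]

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_model([], "poisson")
        with pytest.raises(ValueError):
            fit_model([1, -1], "poisson")
        with pytest.raises(ValueError):
            fit_model([1.5, 2.5], "poisson")
        with pytest.raises(ValueError):
            fit_model([3], "poisson")


@pytest.mark.parametrize("seed", range(6))
def test_nesting_of_fitted_logliks(seed):
    """Adding a parameter never decreases the maximized log-likelihood."""
    rng = np.random.default_rng(seed)
    gen = [
        params("poisson", 2.0),
        params("nb", 4.0, dispersion=1.5),
        params("zip", 3.0, p=0.3),
        params("zinb", 6.0, dispersion=2.0, p=0.25),
    ][seed % 4]
    x = M.sample(gen, 400, rng)
    ll = {f: fit_model(x, f).loglik for f in ("poisson", "zip", "nb", "zinb")}
    tol = 1e-6
    assert ll["zip"] >= ll["poisson"] - tol
    assert ll["nb"] >= ll["poisson"] - tol
    assert ll["zinb"] >= ll["nb"] - tol
    assert ll["zinb"] >= ll["zip"] - tol


def test_reduction_identities():
    """ZIP on non-inflated data collapses to the Poisson fit; equidispersed
    data drives the NB dispersion to the +inf (Poisson) sentinel."""
    rng = np.random.default_rng(7)
    x = rng.poisson(4.0, 1000)
    zip_fit = fit_model(x, "zip")
    pois_fit = fit_model(x, "poisson")
    assert zip_fit.params.zero_inflation < 0.02
    assert zip_fit.params.mean == pytest.approx(pois_fit.params.mean, rel=0.02)
    # underdispersed-ish sample: binomial counts have variance < mean
    y = rng.binomial(20, 0.2, 500)
    nb_fit = fit_model(y, "nb")
    assert math.isinf(nb_fit.params.dispersion)
    assert nb_fit.loglik == pytest.approx(fit_model(y, "poisson").loglik)


def test_parameter_consistency_with_sample_size():
    """Mean absolute estimation error decreases as n grows (20 seeds)."""
    sizes = [200, 2000, 20000]
    mae_lam = np.zeros(3)
    mae_p = np.zeros(3)
    mae_psi = np.zeros(3)
    n_seeds = 20
    for s in range(n_seeds):
        rng = np.random.default_rng(1000 + s)
        for i, n in enumerate(sizes):
            x = M.sample(params("zip", 5.0, p=0.3), n, rng)
            f = fit_model(x, "zip")
            mae_lam[i] += abs(f.params.mean - 5.0)
            mae_p[i] += abs(f.params.zero_inflation - 0.3)
            y = M.sample(params("nb", 5.0, dispersion=2.0), n, rng)
            g = fit_model(y, "nb")
            mae_psi[i] += abs(g.params.dispersion - 2.0)
    for mae in (mae_lam, mae_p, mae_psi):
        assert mae[0] > mae[1] > mae[2]


class TestLrt:
    def _fit_pair(self, x):
        return fit_model(x, "poisson"), fit_model(x, "zip")

    def test_zero_statistic_gives_p_one(self):
        x = np.array([1, 2, 3, 4])
        null = fit_model(x, "poisson")
        alt = fit_model(x, "zip")  # no zeros: identical loglik
        assert lrt_nested(null, alt, boundary=True) == 1.0

    def test_chi2_quantile(self):
        # hand-built fits with loglik gap 2.706/2 -> chi2_1 upper tail 0.10
        null = M.FittedGeneModel(params("poisson", 1.0), -10.0, 10)
        alt = M.FittedGeneModel(params("zip", 1.0, p=0.1), -10.0 + 2.706 / 2, 10)
        assert lrt_nested(null, alt, boundary=False) == pytest.approx(0.10, abs=2e-4)
        assert lrt_nested(null, alt, boundary=True) == pytest.approx(0.05, abs=1e-4)

    def test_non_nested_pair_rejected(self):
        a = M.FittedGeneModel(params("zip", 1.0, p=0.1), -5.0, 10)
        b = M.FittedGeneModel(params("nb", 1.0, dispersion=1.0), -4.0, 10)
        with pytest.raises(ValueError):
            lrt_nested(a, b, boundary=True)

    def test_inconsistent_logliks_rejected(self):
        null = M.FittedGeneModel(params("poisson", 1.0), -5.0, 10)
        alt = M.FittedGeneModel(params("zip", 1.0, p=0.1), -6.0, 10)
        with pytest.raises(ValueError):
            lrt_nested(null, alt, boundary=True)


class TestSelectModel:
    def test_poisson_data_mostly_selects_poisson(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            x = rng.poisson(2.0, 2000)
            if M.select_model(x).chosen == Family.POISSON:
                hits += 1
        assert hits >= 16  # >= 80% of seeds at the 5% test levels

    def test_zinb_data_selects_zinb(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            x = M.sample(params("zinb", 5.0, dispersion=2.0, p=0.4), 2000, rng)
            if M.select_model(x).chosen == Family.ZINB:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_all_zero_gene(self):
        res = M.select_model(np.zeros(100, dtype=int))
        assert res.chosen == Family.POISSON
        assert res.pvalue_dispersion == 1.0
        assert res.pvalue_zero_inflation == 1.0

    def test_constant_gene_skips_dispersion_test(self):
        res = M.select_model(np.full(50, 3))
        assert res.pvalue_dispersion == 1.0
        assert res.chosen == Family.POISSON
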