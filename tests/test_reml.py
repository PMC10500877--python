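"""AI-REML: grid-search oracle, recovery, invariances, bivariate behaviour."""

import numpy as np
import pytest
from scipy import optimize

from gpsm.grm import KinshipMatrix
from gpsm.reml import AgeVarianceModel, BivariateAgeModel


def _kinship(G):
    n = len(G)
    return KinshipMatrix(G, [f"i{i}" for i in range(n)],
                         np.full((n, n), 100.0))


def _random_grm(n, seed, strength=0.5):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, 2 * n))
    G = strength * A @ A.T / (2 * n) + (1 - strength) * np.eye(n)
    return G


def _structured_grm(n, seed, k=60, strength=0.8):
    """Low-rank relatedness (large off-diagonals), as pedigree data gives."""
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((n, k))
    return strength * B @ B.T / k + (1 - strength) * np.eye(n)


def restricted_loglik_dense(theta, y, G):
    """Direct dense restricted likelihood (the oracle's objective)."""
    n = len(y)
    V = theta[0] * G + theta[1] * np.eye(n)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (np.linalg.slogdet(V)[1] + np.log(XtViX[0, 0])
                   + float(r @ Vi @ r))


class TestUnivariate:
    def test_toy_matches_grid_search_oracle(self):
        # n = 6 with a fixed GRM: REML must find the same optimum as a
        # brute-force nested golden-section search of the restricted
        # likelihood over (sigma2_g, sigma2_e)
        G = _random_grm(6, seed=1)
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(2.0 * G + 0.7 * np.eye(6))
        y = 10 + L @ rng.standard_normal(6)
        fit = AgeVarianceModel(y, _kinship(G)).fit()

        def neg_profile(sg):
            inner = optimize.minimize_scalar(
                lambda se: -restricted_loglik_dense((sg, se), y, G),
                bounds=(1e-8, 50), method="bounded",
                options={"xatol": 1e-12})
            return inner.fun

        outer = optimize.minimize_scalar(neg_profile, bounds=(1e-8, 50),
                                         method="bounded",
                                         options={"xatol": 1e-10})
        assert fit.loglik == pytest.approx(-outer.fun, abs=1e-4)
        sg_star = outer.x
        assert fit.sigma2_g == pytest.approx(sg_star, abs=1e-3 * (1 + sg_star))

    def test_recovers_high_pve(self):
        # y simulated under the model with PVE = 0.9 on LE-founder structure
        n = 600
        G = _random_grm(n, seed=3, strength=0.8)
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(0.9 * G + 0.1 * np.eye(n) + 1e-9 * np.eye(n))
        y = L @ rng.standard_normal(n)
        fit = AgeVarianceModel(y, _kinship(G)).fit()
        assert abs(fit.pve - 0.9) < 3 * fit.se_pve
        assert fit.converged

    def test_null_data_hits_boundary(self):
        n = 300
        G = _structured_grm(n, seed=5)
        rng = np.random.default_rng(6)
        ps, sgs = [], []
        for _ in range(10):
            y = rng.standard_normal(n)
            fit = AgeVarianceModel(y, _kinship(G)).fit()
            sgs.append(fit.sigma2_g)
            ps.append(fit.lrt_p)
        # estimates pile up at or near the zero boundary ...
        assert np.median(sgs) < 0.1
        # ... and the boundary LRT is conservative under the null
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_scale_equivariance(self):
        G = _random_grm(80, seed=7)
        rng = np.random.default_rng(8)
        y = np.linalg.cholesky(G + 0.5 * np.eye(80)) @ rng.standard_normal(80)
        f1 = AgeVarianceModel(y, _kinship(G)).fit()
        c = 7.3
        f2 = AgeVarianceModel(c * y, _kinship(G)).fit()
        assert f2.pve == pytest.approx(f1.pve, abs=1e-6)
        assert f2.sigma2_g == pytest.approx(c**2 * f1.sigma2_g,
                                            rel=1e-4)

    def test_pve_identity_and_likelihood_ordering(self):
        G = _random_grm(100, seed=9)
        rng = np.random.default_rng(10)
        y = np.linalg.cholesky(G + np.eye(100)) @ rng.standard_normal(100)
        fit = AgeVarianceModel(y, _kinship(G)).fit()
        assert fit.pve == pytest.approx(
            fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e), abs=1e-12)
        assert fit.loglik >= fit.loglik_null - 1e-9

    def test_interval_coverage_for_pve(self):
        # nominal 95% interval covers the true PVE 95% +/- 5 points
        n, reps, true_pve = 200, 200, 0.6
        G = _random_grm(n, seed=11, strength=0.8)
        model_G = 0.6 * G + 0.4 * np.eye(n)
        L = np.linalg.cholesky(model_G + 1e-10 * np.eye(n))
        rng = np.random.default_rng(12)
        km = _kinship(G)
        covered = 0
        for _ in range(reps):
            y = L @ rng.standard_normal(n)
            fit = AgeVarianceModel(y, km).fit()
            covered += abs(fit.pve - true_pve) < 1.96 * fit.se_pve
        assert 0.90 <= covered / reps <= 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            AgeVarianceModel(np.ones(5), _kinship(np.eye(4)))


class TestBivariate:
    def _structured_world(self, n_per, seed, rg, sg=0.7, se=0.3):
        """Simulate y exactly from the bivariate model covariance."""
        n = 2 * n_per
        G = _structured_grm(n, seed=seed)
        pops = np.array(["A"] * n_per + ["B"] * n_per)
        m1 = (pops == "A").astype(float)
        m2 = 1 - m1
        g12 = rg * sg
        V = (sg * G * np.outer(m1, m1) + sg * G * np.outer(m2, m2)
             + g12 * G * (np.outer(m1, m2) + np.outer(m2, m1))
             + se * np.eye(n))
        rng = np.random.default_rng(seed + 1)
        y = np.linalg.cholesky(V + 1e-9 * np.eye(n)) @ rng.standard_normal(n)
        return y, _kinship(G), pops

    def test_recovers_rg(self):
        y, km, pops = self._structured_world(250, seed=20, rg=0.8)
        fit = BivariateAgeModel(y, km, pops).fit()
        assert abs(fit.r_g - 0.8) < 3 * fit.se_rg
        assert fit.se_rg < 0.25  # the structure identifies r_G usefully
        assert fit.converged
        if not fit.r_g_clamped:
            assert fit.r_g == pytest.approx(
                fit.sigma_g12 / np.sqrt(fit.sigma2_g1 * fit.sigma2_g2),
                abs=1e-9)

    def test_null_rg_not_significant(self):
        y, km, pops = self._structured_world(200, seed=21, rg=0.0)
        fit = BivariateAgeModel(y, km, pops).fit()
        assert abs(fit.r_g) < 3 * fit.se_rg
        assert fit.lrt_p_rg0 > 0.01

    def test_mirrored_population_drives_rg_to_one(self):
        # population B is a relabeled copy of A's genetic signal
        n_per = 150
        G = _random_grm(2 * n_per, seed=22, strength=0.8)
        rng = np.random.default_rng(23)
        d, U = np.linalg.eigh(G)
        g = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(2 * n_per))
        y = g + 0.05 * rng.standard_normal(2 * n_per)
        pops = np.array(["A"] * n_per + ["B"] * n_per)
        fit = BivariateAgeModel(y, _kinship(G), pops).fit()
        assert fit.r_g > 0.9

    def test_requires_exactly_two_populations(self):
        with pytest.raises(ValueError, match="two populations"):
            BivariateAgeModel(np.ones(6), _kinship(np.eye(6)),
                              ["A"] * 6)

    def test_duplicate_sample_across_populations_rejected(self):
        km = KinshipMatrix(np.eye(4), ["a", "b", "a", "c"],
                           np.ones((4, 4)))
        with pytest.raises(ValueError, match="both populations"):
            BivariateAgeModel(np.ones(4), km, ["A", "A", "B", "B"])

    def test_small_group_warns(self):
        y, km, pops = self._structured_world(20, seed=24, rg=0.5)
        with pytest.warns(UserWarning, match="only"):
            BivariateAgeModel(y, km, pops)
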