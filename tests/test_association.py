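"""Regression engines: OLS, logistic IRLS, clustered GEE, CC-GWAS."""

import numpy as np
import pytest
import statsmodels.api as sm

import famhist as fh
from famhist.association import linear_fit, logistic_fit


class TestLinearFit:
    def test_exact_fit_recovers_slope(self):
        x = np.arange(10.0)
        res = linear_fit(2.0 * x, x)
        assert res.beta == pytest.approx(2.0)
        assert res.pvalue < 1e-300

    def test_hand_computed_closed_form(self):
        """(X'X)^-1 X'y on a 5-point example computed by hand."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        # sums: Sx=10, Sy=14, Sxy=38, Sxx=30 -> slope=(5*38-10*14)/(5*30-100)=1.0
        res = linear_fit(y, x)
        assert res.beta == pytest.approx(1.0, rel=1e-12)

    def test_null_pvalues_uniform(self, rng):
        pvals = [
            linear_fit(rng.normal(size=200), rng.normal(size=200)).pvalue
            for _ in range(400)
        ]
        # Kolmogorov-Smirnov distance from uniform
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 1e-3

    def test_matches_statsmodels_on_random_datasets(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 120))
            X = rng.normal(size=(n, 3))
            y = X @ rng.normal(size=3) + rng.normal(size=n)
            res = linear_fit(y, X)
            ref = sm.OLS(y, sm.add_constant(X, prepend=False)).fit()
            assert res.beta == pytest.approx(ref.params[0], rel=1e-9)
            assert np.sqrt(res.variance) == pytest.approx(ref.bse[0], rel=1e-9)

    def test_rank_deficient_design_flagged(self):
        x = np.ones(20)
        res = linear_fit(np.random.default_rng(0).normal(size=20), x)
        assert not res.converged


class TestLogisticFit:
    def test_intercept_only_mle_is_logit_of_prevalence(self):
        y = np.zeros(1000)
        y[:300] = 1.0
        res = logistic_fit(y, np.ones((1000, 1)), add_intercept=False)
        # closed-form MLE of a proportion: log(K / (1-K))
        assert res.beta == pytest.approx(np.log(0.3 / 0.7), rel=1e-8)
        # information: n * p * (1 - p)
        assert res.variance == pytest.approx(1.0 / (1000 * 0.3 * 0.7), rel=1e-8)

    def test_matches_statsmodels_on_random_datasets(self, rng):
        """MLE, SE and Wald z agree with statsmodels to >= 6 significant digits."""
        for _ in range(20):
            n = int(rng.integers(80, 200))
            X = rng.normal(size=(n, 2))
            eta = -0.3 + X @ np.array([0.8, -0.5])
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
            if y.min() == y.max():
                continue
            res = logistic_fit(y, X)
            ref = sm.Logit(y, sm.add_constant(X, prepend=False)).fit(disp=0)
            assert res.beta == pytest.approx(ref.params[0], rel=1e-6)
            assert np.sqrt(res.variance) == pytest.approx(ref.bse[0], rel=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.repeat([0.0, 1.0], 20)
        res = logistic_fit(y, y.copy())
        assert not res.converged
        assert res.pvalue == 1.0

    def test_single_class_response_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(50), np.random.default_rng(1).normal(size=50))

    def test_wald_invariant_to_affine_rescaling(self, rng):
        n = 300
        X = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        a = logistic_fit(y, X)
        X2 = X.copy()
        X2[:, 1] = 100.0 * X2[:, 1] + 7.0  # rescale a covariate
        b = logistic_fit(y, X2)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-6)
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-5)


class TestClusteredFits:
    def _clustered_binary(self, rng, n_fam=300, m=3):
        fam = np.repeat(np.arange(n_fam), m)
        u = rng.normal(0, 0.8, n_fam)[fam]
        x = rng.normal(size=n_fam * m) + 0.4 * u
        eta = -0.4 + 0.5 * x + u
        y = (rng.random(n_fam * m) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        return y, x, fam, u

    def test_gee_logistic_close_to_statsmodels(self, rng):
        y, x, fam, _ = self._clustered_binary(rng)
        res = logistic_fit(y, x[:, None], clusters=fam)
        ref = sm.GEE(
            y,
            np.column_stack([x, np.ones(x.size)]),
            groups=fam,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit(cov_type="naive")
        # correlation-parameter denominators differ slightly between
        # implementations; estimates agree closely, not to machine precision
        assert res.beta == pytest.approx(ref.params[0], rel=1e-3)
        assert np.sqrt(res.variance) == pytest.approx(ref.bse[0], rel=0.02)

    def test_fgls_linear_close_to_statsmodels(self, rng):
        fam = np.repeat(np.arange(250), 3)
        u = rng.normal(0, 1.0, 250)[fam]
        x = rng.normal(size=750)
        y = 0.3 * x + u + rng.normal(size=750)
        res = linear_fit(y, x[:, None], clusters=fam)
        ref = sm.GEE(
            y,
            np.column_stack([x, np.ones(750)]),
            groups=fam,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit(cov_type="naive")
        assert res.beta == pytest.approx(ref.params[0], rel=1e-3)
        assert np.sqrt(res.variance) == pytest.approx(ref.bse[0], rel=0.05)

    def test_cluster_level_covariate_gets_wider_se(self, rng):
        """For a covariate constant within clusters, positive within-cluster
        correlation reduces the effective sample size, so the GEE variance
        must exceed the iid variance."""
        n_fam, m = 300, 3
        fam = np.repeat(np.arange(n_fam), m)
        u = rng.normal(0, 0.8, n_fam)[fam]
        x = rng.normal(size=n_fam)[fam]  # cluster-constant
        eta = -0.4 + 0.5 * x + u
        y = (rng.random(n_fam * m) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        iid = logistic_fit(y, x[:, None])
        gee = logistic_fit(y, x[:, None], clusters=fam)
        assert gee.variance > iid.variance


class TestCCGWAS:
    def test_regression_uses_offspring_only(self, nuclear_cohort, causal_sim):
        genotypes, phenos, _ = causal_sim
        res = fh.ccgwas_test(nuclear_cohort, genotypes, phenos.z, variant=7)
        assert res.n == 1000

    def test_detects_strong_common_variant(self, nuclear_cohort, causal_sim):
        genotypes, phenos, _ = causal_sim
        res = fh.ccgwas_test(nuclear_cohort, genotypes, phenos.z, variant=7)
        assert res.converged and res.beta > 0

    def test_permuted_genotypes_lose_signal(self, nuclear_cohort, causal_sim, rng):
        genotypes, phenos, _ = causal_sim
        pvals = []
        off = np.flatnonzero(nuclear_cohort.is_offspring)
        for _ in range(30):
            shuffled = genotypes.codes.copy()
            shuffled[off, 7] = rng.permutation(shuffled[off, 7])
            gt = fh.GenotypeTable(shuffled, genotypes.mafs)
            pvals.append(fh.ccgwas_test(nuclear_cohort, gt, phenos.z, variant=7).pvalue)
        assert np.mean(np.array(pvals) < 0.05) < 0.3
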