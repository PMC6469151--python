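"""Null fits, score tests and score correlations."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from minpglm import (
    CodingSpec,
    Dataset,
    FamilyLink,
    RankDeficientError,
    ScenarioSpec,
    SingularScoreError,
    fit_null,
    generate_dataset,
    realize,
    score_correlation,
    score_test,
)
from minpglm.codings import CodedDesign


def _design(col, label="c"):
    col = np.asarray(col, dtype=float)
    spec = CodingSpec.rawcut([0.0])  # placeholder spec for hand-built columns
    return CodedDesign(label, col, 1, spec)


class TestFitNull:
    def test_gaussian_intercept_only_is_sample_mean(self, fl_gauss):
        nf = fit_null([1.0, 2.0, 3.0], np.ones((3, 1)), fl_gauss)
        assert nf.gamma == pytest.approx([2.0])
        assert nf.mu == pytest.approx([2.0, 2.0, 2.0])

    def test_gaussian_equals_ols(self, fl_gauss, rng):
        n = 50
        Z = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 + 0.5 * Z[:, 1] + rng.normal(size=n)
        nf = fit_null(y, Z, fl_gauss)
        beta_ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
        assert nf.gamma == pytest.approx(beta_ols, abs=1e-10)
        # ML dispersion is RSS/n
        rss = np.sum((y - Z @ beta_ols) ** 2)
        assert nf.dispersion == pytest.approx(rss / n)

    def test_binomial_intercept_closed_form(self, fl_logit):
        y = np.r_[np.ones(25), np.zeros(75)]
        nf = fit_null(y, np.ones((100, 1)), fl_logit)
        assert nf.gamma == pytest.approx([np.log(0.25 / 0.75)], abs=1e-8)

    def test_poisson_matches_reference_glm(self, fl_poisson):
        """IRLS agrees with an independent reference fitter and recovers
        the truth within 3 SE at n=500."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(99)
        n = 500
        z = rng.normal(size=n)
        Z = np.column_stack([np.ones(n), z])
        gamma_true = np.array([0.3, -0.5])
        y = rng.poisson(np.exp(Z @ gamma_true))
        nf = fit_null(y, Z, fl_poisson)
        ref = sm.GLM(y, Z, family=sm.families.Poisson()).fit()
        assert nf.gamma == pytest.approx(ref.params, abs=1e-7)
        se = ref.bse
        assert np.all(np.abs(nf.gamma - gamma_true) < 3 * se)

    def test_rank_deficient_adjustment_names_columns(self, fl_gauss, rng):
        n = 30
        z = rng.normal(size=n)
        Z = np.column_stack([np.ones(n), z, 2 * z])
        with pytest.raises(RankDeficientError) as exc:
            fit_null(rng.normal(size=n), Z, fl_gauss)
        assert len(exc.value.columns) >= 1

    def test_invalid_support_rejected(self, fl_logit, fl_poisson):
        with pytest.raises(ValueError):
            fit_null([0.0, 0.5, 1.0], np.ones((3, 1)), fl_logit)
        with pytest.raises(ValueError):
            fit_null([-1.0, 2.0, 3.0], np.ones((3, 1)), fl_poisson)

    @pytest.mark.parametrize("family,link", [
        ("gaussian", "identity"), ("binomial", "logit"),
        ("binomial", "probit"), ("poisson", "log")])
    def test_irls_deviance_monotone(self, family, link):
        """The step-halved IRLS deviance never increases, on every family."""
        from minpglm.glm import _irls
        fl = FamilyLink.from_names(family, link)
        rng = np.random.default_rng(3)
        n = 120
        Z = np.column_stack([np.ones(n), rng.normal(size=n)])
        eta = 0.2 + 0.4 * Z[:, 1]
        mu = fl.mu(eta)
        if family == "binomial":
            y = (rng.random(n) < mu).astype(float)
        elif family == "poisson":
            y = rng.poisson(mu).astype(float)
        else:
            y = rng.normal(mu, 1.0)
        *_, trace, converged, _ = _irls(y, Z, fl, tol=1e-9, max_iter=100)
        assert converged
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-8 * (1 + np.abs(trace[:-1])))

    def test_unsupported_family_link_rejected(self):
        with pytest.raises(ValueError):
            FamilyLink.from_names("binomial", "log")
        with pytest.raises(ValueError):
            FamilyLink.from_names("gamma", "log")


class TestScoreTest:
    def test_binary_coding_equals_pearson_chi_square(self, fl_logit, rng):
        """With an intercept-only null, T^2 for one binary coding is the
        Pearson chi-square of the 2x2 table of Y by X(k)."""
        n = 200
        y = (rng.random(n) < 0.3).astype(float)
        x = rng.normal(size=n)
        nf = fit_null(y, np.ones((n, 1)), fl_logit)
        des = realize(CodingSpec.dichotomous(0.4), x)
        res = score_test(nf, des)
        c = des.matrix[:, 0]
        tab = np.array([[np.sum((y == i) & (c == j)) for j in (0, 1)]
                        for i in (0, 1)], dtype=float)
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        chi2 = float(((tab - expected) ** 2 / expected).sum())
        assert res.statistic ** 2 == pytest.approx(chi2, abs=1e-8)

    def test_column_orthogonal_to_residuals_gives_zero_score(self, fl_gauss, rng):
        """A coded column W-orthogonal to the residuals has U = 0, hence
        T = 0 and p = 1 (the score only sees the residual direction)."""
        n = 50
        y = rng.normal(size=n)
        nf = fit_null(y, np.ones((n, 1)), fl_gauss)
        resid = y - nf.mu
        c = rng.normal(size=n)
        c = c - c.mean()
        c = c - (resid @ c) / (resid @ resid) * resid   # now c @ resid == 0
        res = score_test(nf, _design(c))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_gaussian_matches_ols_t_statistic(self, fl_gauss, rng):
        n = 2000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        Z = np.ones((n, 1))
        nf = fit_null(y, Z, fl_gauss)
        des = _design((x - x.mean()) / x.std())
        res = score_test(nf, des)
        # OLS t-statistic for the slope, intercept included
        X = np.column_stack([np.ones(n), des.matrix[:, 0]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        t_ols = beta[1] / np.sqrt(cov[1, 1])
        assert res.statistic == pytest.approx(t_ols, abs=10 / n)

    def test_constant_coded_column_is_singular(self, fl_gauss, rng):
        n = 40
        nf = fit_null(rng.normal(size=n), np.ones((n, 1)), fl_gauss)
        with pytest.raises(SingularScoreError):
            score_test(nf, _design(np.ones(n), label="const"))

    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_1df(self, a, b):
        """T(aX + b) = sign(a) T(X): the statistic only sees the coded
        column through its projection orthogonal to the intercept."""
        fl = FamilyLink.from_names("gaussian", "identity")
        rng = np.random.default_rng(7)
        n = 60
        y = rng.normal(size=n)
        col = rng.normal(size=n)
        nf = fit_null(y, np.ones((n, 1)), fl)
        t0 = score_test(nf, _design(col)).statistic
        t1 = score_test(nf, _design(a * col + b)).statistic
        assert t1 == pytest.approx(np.sign(a) * t0, abs=1e-7)

    def test_multidf_reparameterization_invariance(self, fl_logit, rng):
        """Q is unchanged under X(k) -> X(k) M for invertible M."""
        n = 150
        y = (rng.random(n) < 0.4).astype(float)
        Z = np.column_stack([np.ones(n), rng.normal(size=n)])
        nf = fit_null(y, Z, fl_logit)
        M3 = rng.normal(size=(n, 3))
        spec = CodingSpec.categorical([0.25, 0.5, 0.75])
        d1 = CodedDesign("blk", M3, 3, spec)
        T = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0], [1.0, 0.0, 3.0]])
        d2 = CodedDesign("blk2", M3 @ T, 3, spec)
        r1, r2 = score_test(nf, d1), score_test(nf, d2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-8)
        assert r1.df == r2.df == 3

    def test_null_distribution_is_standard_normal(self, fl_gauss):
        """Across 2000 simulated null datasets the 1-df score statistic is
        N(0,1) by a KS test at level 0.01."""
        rng = np.random.default_rng(2024)
        n = 100
        Z = np.ones((n, 1))
        ts = np.empty(2000)
        for b in range(2000):
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            nf = fit_null(y, Z, fl_gauss)
            ts[b] = score_test(nf, _design(x)).statistic
        assert sps.kstest(ts, "norm").pvalue > 0.01


class TestScoreCorrelation:
    def test_identical_codings_have_unit_correlation(self, logit_null_ds, fl_logit):
        ds = logit_null_ds
        nf = fit_null(ds.y, ds.Z, fl_logit)
        d = realize(CodingSpec.dichotomous(0.5), ds.x)
        R = score_correlation(nf, [d, d])
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_w_orthogonal_columns_uncorrelated(self, fl_gauss, rng):
        n = 100
        y = rng.normal(size=n)
        nf = fit_null(y, np.ones((n, 1)), fl_gauss)
        a = rng.normal(size=n)
        a = a - a.mean()
        b = rng.normal(size=n)
        b = b - b.mean()
        b = b - (a @ b) / (a @ a) * a        # W is proportional to identity
        R = score_correlation(nf, [_design(a, "a"), _design(b, "b")])
        assert R[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_multi_df_design_rejected(self, logit_null_ds, fl_logit):
        ds = logit_null_ds
        nf = fit_null(ds.y, ds.Z, fl_logit)
        d = realize(CodingSpec.categorical([0.3, 0.7]), ds.x)
        with pytest.raises(ValueError, match="1-df"):
            score_correlation(nf, [d])

    def test_matches_empirical_bootstrap_correlation(self, fl_logit):
        """The closed-form R agrees with the empirical correlation of the
        statistics across 5000 parametric-bootstrap replicates (+/- 0.05)."""
        spec = ScenarioSpec(n=300, gamma=(np.log(0.3 / 0.7),), n_adjust=0,
                            seed=5)
        ds = generate_dataset(spec)
        nf = fit_null(ds.y, ds.Z, fl_logit)
        designs = [realize(CodingSpec.dichotomous(l), ds.x)
                   for l in (0.25, 0.5, 0.75)]
        R = score_correlation(nf, designs)
        rng = np.random.default_rng(77)
        B = 5000
        ts = np.empty((B, 3))
        for b in range(B):
            ystar = (rng.random(ds.n) < nf.mu).astype(float)
            nfb = fit_null(ystar, ds.Z, fl_logit)
            ts[b] = [score_test(nfb, d).statistic for d in designs]
        R_emp = np.corrcoef(ts, rowvar=False)
        assert np.max(np.abs(R - R_emp)) < 0.05

    def test_psd_and_unit_diagonal(self, logit_null_ds, fl_logit):
        ds = logit_null_ds
        nf = fit_null(ds.y, ds.Z, fl_logit)
        designs = [realize(CodingSpec.dichotomous(l), ds.x)
                   for l in (0.2, 0.4, 0.6, 0.8)]
        R = score_correlation(nf, designs)
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)
        assert np.linalg.eigvalsh(R).min() > -1e-10
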