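import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infuseg import (
    GMMParameters,
    classify,
    e_step,
    fit_em,
    m_step,
    mixture_density,
    negative_log_likelihood,
    normal_pdf,
)
from infuseg.gmm import DEFAULT_INIT, ClassCollapseError

PARAMS = GMMParameters(alpha=0.3, mu0=0.2, sigma0=0.1, mu1=0.8, sigma1=0.1)


def two_term_density(x, p):
    """Independent two-term evaluation of the mixture (oracle)."""
    n0 = math.exp(-0.5 * ((x - p.mu0) / p.sigma0) ** 2) / (p.sigma0 * math.sqrt(2 * math.pi))
    n1 = math.exp(-0.5 * ((x - p.mu1) / p.sigma1) ** 2) / (p.sigma1 * math.sqrt(2 * math.pi))
    return (1 - p.alpha) * n0 + p.alpha * n1


class TestNormalPdf:
    def test_standard_normal_at_zero(self):
        assert normal_pdf(0.0, 0.0, 1.0) == pytest.approx(0.398942, abs=1e-6)

    @pytest.mark.parametrize("d", [0.1, 1.0, 3.7])
    def test_symmetry_about_mean(self, d):
        assert normal_pdf(0.4 + d, 0.4, 0.2) == pytest.approx(normal_pdf(0.4 - d, 0.4, 0.2))

    def test_integrates_to_one(self):
        """Trapezoidal quadrature over +/- 8 sigma at step sigma/100."""
        mu, sigma = 0.3, 0.07
        x = np.arange(mu - 8 * sigma, mu + 8 * sigma, sigma / 100)
        assert np.trapezoid(normal_pdf(x, mu, sigma), x) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            normal_pdf(0.0, 0.0, 0.0)


class TestMixtureDensity:
    def test_identical_components_collapse(self):
        p = GMMParameters(0.5, 0.4, 0.15, 0.4, 0.15)
        assert mixture_density(0.6, p) == pytest.approx(normal_pdf(0.6, 0.4, 0.15))

    def test_extreme_alpha_is_foreground_density(self):
        p = GMMParameters(1 - 1e-9, 0.2, 0.1, 0.8, 0.1)
        assert mixture_density(0.7, p) == pytest.approx(normal_pdf(0.7, 0.8, 0.1), rel=1e-6)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.9])
    def test_matches_two_term_oracle(self, x):
        assert mixture_density(x, PARAMS) == pytest.approx(two_term_density(x, PARAMS), rel=1e-12)


class TestEStep:
    def test_identical_components_give_half(self):
        p = GMMParameters(0.5, 0.4, 0.15, 0.4, 0.15)
        r = e_step(np.linspace(0, 1, 11), p)
        assert np.allclose(r, 0.5)

    def test_alpha_near_one_gives_responsibility_near_one(self):
        # alpha is clamped to 1 - 1e-6 internally, so r tops out there
        p = GMMParameters(1 - 1e-9, 0.5, 0.2, 0.5, 0.2)
        assert np.all(e_step(np.array([0.2, 0.5, 0.8]), p) >= 1 - 2e-6)

    def test_matches_per_term_oracle(self):
        x = np.array([0.1, 0.5, 0.9])
        r = e_step(x, PARAMS)
        for xi, ri in zip(x, r):
            fg = PARAMS.alpha * normal_pdf(xi, PARAMS.mu1, PARAMS.sigma1)
            assert ri == pytest.approx(fg / two_term_density(xi, PARAMS), rel=1e-9)

    def test_responsibilities_in_unit_interval(self, rng):
        r = e_step(rng.random(500), PARAMS)
        assert np.all((r >= 0) & (r <= 1))

    def test_no_underflow_far_from_both_components(self):
        # raw densities underflow at |z| >> 40; log-space keeps r defined
        r = e_step(np.array([-50.0, 50.0]), PARAMS)
        assert np.all(np.isfinite(r))


class TestMStep:
    def test_all_foreground_collapses(self):
        with pytest.raises(ClassCollapseError):
            m_step(np.linspace(0, 1, 20), np.ones(20))

    def test_uniform_half_responsibility_merges_means(self):
        x = np.linspace(0.1, 0.9, 30)
        p = m_step(x, np.full(30, 0.5))
        assert p.mu0 == pytest.approx(x.mean())
        assert p.mu1 == pytest.approx(x.mean())
        assert p.alpha == pytest.approx(0.5)

    def test_weighted_moment_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(50)
        r = rng.random(50)
        p = m_step(x, r)
        # oracle: brute-force weighted mean and population variance
        mu1 = sum(ri * xi for ri, xi in zip(r, x)) / sum(r)
        var1 = sum(ri * (xi - mu1) ** 2 for ri, xi in zip(r, x)) / sum(r)
        mu0 = sum((1 - ri) * xi for ri, xi in zip(r, x)) / sum(1 - ri for ri in r)
        var0 = sum((1 - ri) * (xi - mu0) ** 2 for ri, xi in zip(r, x)) / sum(1 - ri for ri in r)
        assert p.alpha == pytest.approx(np.mean(r), abs=1e-12)
        assert p.mu1 == pytest.approx(mu1, abs=1e-12)
        assert p.sigma1 == pytest.approx(math.sqrt(var1), abs=1e-12)
        assert p.mu0 == pytest.approx(mu0, abs=1e-12)
        assert p.sigma0 == pytest.approx(math.sqrt(var0), abs=1e-12)

    def test_variance_floor_applied(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        r = np.concatenate([np.zeros(10), np.ones(10)])
        p = m_step(x, r)
        assert p.sigma0 >= 1e-4 and p.sigma1 >= 1e-4


class TestNegativeLogLikelihood:
    def test_unit_density_gives_zero(self):
        sigma = 1.0 / math.sqrt(2 * math.pi)  # peak density exactly 1
        p = GMMParameters(0.5, 0.5, sigma, 0.5, sigma)
        assert negative_log_likelihood(np.array([0.5]), p) == pytest.approx(0.0, abs=1e-9)

    def test_additive_over_concatenation(self, rng):
        a, b = rng.random(40), rng.random(25)
        assert negative_log_likelihood(np.concatenate([a, b]), PARAMS) == pytest.approx(
            negative_log_likelihood(a, PARAMS) + negative_log_likelihood(b, PARAMS)
        )

    def test_matches_summation_oracle(self):
        x = [0.1, 0.5, 0.9]
        expected = -sum(math.log(two_term_density(xi, PARAMS)) for xi in x)
        assert negative_log_likelihood(np.array(x), PARAMS) == pytest.approx(expected, rel=1e-12)


def sample_mixture(rng, n, p):
    fg = rng.random(n) < p.alpha
    x = np.where(fg, rng.normal(p.mu1, p.sigma1, n), rng.normal(p.mu0, p.sigma0, n))
    return x


class TestFitEM:
    def test_default_starting_values(self):
        assert (DEFAULT_INIT.alpha, DEFAULT_INIT.mu0, DEFAULT_INIT.sigma0,
                DEFAULT_INIT.mu1, DEFAULT_INIT.sigma1) == (0.5, 0.2, 0.2, 0.8, 0.2)

    def test_parameter_recovery_within_three_se(self):
        """EM on 1e5 samples from a well-separated mixture recovers the truth."""
        truth = GMMParameters(0.3, 0.2, 0.05, 0.7, 0.10)
        n = 100_000
        x = sample_mixture(np.random.default_rng(42), n, truth)
        fit = fit_em(x, rel_tol=1e-6)
        # asymptotic standard errors for well-separated components
        n1, n0 = truth.alpha * n, (1 - truth.alpha) * n
        se = {
            "alpha": math.sqrt(truth.alpha * (1 - truth.alpha) / n),
            "mu0": truth.sigma0 / math.sqrt(n0),
            "sigma0": truth.sigma0 / math.sqrt(2 * n0),
            "mu1": truth.sigma1 / math.sqrt(n1),
            "sigma1": truth.sigma1 / math.sqrt(2 * n1),
        }
        for name, s in se.items():
            est, true = getattr(fit.params, name), getattr(truth, name)
            assert abs(est - true) < 3 * s, f"{name}: {est} vs {true} (3 SE = {3*s:.2e})"

    @pytest.mark.parametrize("seed", range(4))
    def test_nll_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        x = sample_mixture(rng, 2000, PARAMS)
        fit = fit_em(x)
        trace = np.array(fit.nll_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_relabels_bright_foreground(self):
        # mostly-dark data can leave the brighter class as component 0;
        # after relabelling mu1 must still be the larger mean
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0.8, 0.05, 5000), rng.normal(0.3, 0.05, 300)])
        fit = fit_em(x)
        assert fit.params.mu1 >= fit.params.mu0

    def test_stationary_point_is_fixed(self):
        """One more E/M round from a converged fit moves parameters negligibly."""
        x = sample_mixture(np.random.default_rng(3), 20_000, PARAMS)
        fit = fit_em(x, rel_tol=1e-10, max_iter=2000)
        p = fit.params
        p2 = m_step(x, e_step(x, p))
        for name in ("alpha", "mu0", "sigma0", "mu1", "sigma1"):
            assert getattr(p2, name) == pytest.approx(getattr(p, name), abs=1e-6)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            fit_em(np.linspace(0, 1, 5))

    def test_zero_spread_raises(self):
        with pytest.raises(ValueError):
            fit_em(np.full(100, 0.4))

    def test_agrees_with_sklearn_reference(self):
        """Cross-check the fitted optimum against an independent EM implementation."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        x = sample_mixture(np.random.default_rng(11), 30_000, PARAMS)
        fit = fit_em(x, rel_tol=1e-8)
        ref = sklearn_mixture.GaussianMixture(
            n_components=2, covariance_type="spherical", tol=1e-8, reg_covar=1e-10,
            means_init=[[0.2], [0.8]], weights_init=[0.5, 0.5], random_state=0,
        ).fit(x.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        ref_mu0, ref_mu1 = ref.means_.ravel()[order]
        ref_alpha = ref.weights_[order][1]
        assert fit.params.mu0 == pytest.approx(ref_mu0, abs=1e-3)
        assert fit.params.mu1 == pytest.approx(ref_mu1, abs=1e-3)
        assert fit.params.alpha == pytest.approx(ref_alpha, abs=1e-3)


class TestClassify:
    def test_symmetric_threshold_at_midpoint(self):
        p = GMMParameters(0.5, 0.2, 0.1, 0.8, 0.1)
        mid = (p.mu0 + p.mu1) / 2
        x = np.array([mid - 0.01, mid, mid + 0.01])
        idx = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        mask = classify(x, idx, p, (3, 1, 1))
        # above midpoint -> foreground; the exact tie -> background
        assert mask.data.ravel().tolist() == [False, False, True]

    def test_all_dark_gives_empty_foreground(self):
        x = np.full(20, -5.0)
        idx = np.stack([np.arange(20), np.zeros(20, int), np.zeros(20, int)], axis=1)
        mask = classify(x, idx, PARAMS, (20, 1, 1))
        assert mask.n_voxels == 0

    def test_matches_bruteforce_posterior_oracle(self, rng):
        x = rng.random(1000)
        idx = np.stack([np.arange(1000) // 100, (np.arange(1000) // 10) % 10,
                        np.arange(1000) % 10], axis=1)
        mask = classify(x, idx, PARAMS, (10, 10, 10))
        for xi, (i, j, k) in zip(x, idx):
            fg = PARAMS.alpha * normal_pdf(xi, PARAMS.mu1, PARAMS.sigma1)
            bg = (1 - PARAMS.alpha) * normal_pdf(xi, PARAMS.mu0, PARAMS.sigma0)
            assert mask.data[i, j, k] == (fg > bg)

    def test_outside_box_is_background(self):
        x = np.array([0.9, 0.9])
        idx = np.array([[2, 2, 2], [3, 3, 3]])
        mask = classify(x, idx, PARAMS, (6, 6, 6))
        assert mask.n_voxels == 2
        assert not mask.data[0, 0, 0]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_em_monotone_nll_property(seed):
    """EM never increases the negative log-likelihood, whatever the data."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 400))
    x = rng.random(n)
    if x.std() == 0:
        return
    fit = fit_em(x)
    assert np.all(np.diff(fit.nll_trace) <= 1e-9)
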