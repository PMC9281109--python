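import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trajspur.gbtm import (
    GBTMFit,
    GBTMSpec,
    assign,
    fit_gbtm,
    group_conditional_loglik,
    mixture_loglik,
    posteriors,
)
from trajspur.scenarios import generate_scenario
from tests.conftest import make_panel


def manual_fit(pi, betas, sigma, censor_low=-np.inf, censor_high=np.inf):
    """GBTMFit shell holding given parameters (for likelihood operations)."""
    J = len(pi)
    spec = GBTMSpec(
        n_groups=J,
        poly_order=[len(b) - 1 for b in betas],
        censor_low=censor_low,
        censor_high=censor_high,
    )
    return GBTMFit(
        spec=spec, pi=np.asarray(pi, float), beta=[np.asarray(b, float) for b in betas],
        sigma=sigma, loglik=np.nan, n_params=spec.n_params, bic=np.nan, posterior=None,
        assignments=None, group_counts=np.zeros(J, int), converged=True,
        n_em_iterations=0, n_subjects=0,
    )


def brute_loglik_matrix(panel, fit):
    """Independent direct-summation oracle for the N x J conditional logliks."""
    out = []
    for times, y in panel.by_subject():
        row = []
        for b in fit.beta:
            mu = np.polynomial.polynomial.polyval(times, b)
            row.append(np.sum(stats.norm.logpdf(y, mu, fit.sigma)))
        out.append(row)
    return np.array(out)


# ---------------------------------------------------------------------------
# conditional and mixture likelihoods
# ---------------------------------------------------------------------------


def test_single_occasion_equals_censored_density():
    from trajspur.families import CensoredNormalFamily, cnorm_logdensity

    val = group_conditional_loglik([2.0], [3.0], [0.5, 0.5], sigma=1.2)
    fam = CensoredNormalFamily(mu=0.5 + 0.5 * 3.0, sigma=1.2)
    assert val == pytest.approx(cnorm_logdensity(2.0, fam), abs=1e-12)


def test_on_curve_series_gives_t_times_mode_density():
    beta = [1.0, 2.0, -0.3]
    times = np.arange(1.0, 6.0)
    y = np.polynomial.polynomial.polyval(times, beta)
    sigma = 0.7
    expected = 5 * (-np.log(sigma) - 0.5 * np.log(2 * np.pi))
    assert group_conditional_loglik(y, times, beta, sigma) == pytest.approx(expected, abs=1e-10)


def test_conditional_loglik_matches_term_by_term_sum():
    rng = np.random.default_rng(2)
    times = np.array([0.0, 0.5, 2.0])
    y = rng.standard_normal(3)
    beta = [0.3, -0.2, 0.1]
    sigma = 1.4
    mu = np.polynomial.polynomial.polyval(times, beta)
    hand = sum(stats.norm.logpdf(yi, mi, sigma) for yi, mi in zip(y, mu))
    assert group_conditional_loglik(y, times, beta, sigma) == pytest.approx(hand, abs=1e-12)


def test_mixture_loglik_degenerates_for_single_group(tiny_panel):
    fit = manual_fit([1.0], [[2.0, 0.5]], sigma=1.5)
    direct = brute_loglik_matrix(tiny_panel, fit).sum()
    assert mixture_loglik(tiny_panel, fit) == pytest.approx(direct, abs=1e-10)


def test_mixture_loglik_matches_brute_force_double_sum(tiny_panel):
    fit = manual_fit(
        [0.3, 0.7], [[1.0, 1.0], [8.0, -0.4]], sigma=0.9
    )
    ll = brute_loglik_matrix(tiny_panel, fit)
    expected = np.sum(np.log(np.exp(ll) @ fit.pi))
    assert mixture_loglik(tiny_panel, fit) == pytest.approx(expected, abs=1e-10)


def test_loglik_invariant_under_label_permutation(tiny_panel):
    fit = manual_fit([0.2, 0.5, 0.3], [[1, 1], [4, 0.0], [8, -0.4]], sigma=1.1)
    perm = manual_fit([0.3, 0.2, 0.5], [[8, -0.4], [1, 1], [4, 0.0]], sigma=1.1)
    assert mixture_loglik(tiny_panel, fit) == pytest.approx(
        mixture_loglik(tiny_panel, perm), abs=1e-10
    )


def test_posteriors_match_hand_bayes_rule():
    panel = make_panel(np.array([[1.0, 2.0]]), times=[1.0, 2.0])
    fit = manual_fit([0.4, 0.6], [[0.0, 1.0], [3.0, -0.5]], sigma=0.8)
    ll = brute_loglik_matrix(panel, fit)[0]
    w = fit.pi * np.exp(ll)
    hand = w / w.sum()
    post = posteriors(fit, panel)
    assert np.allclose(post[0], hand, atol=1e-12)
    assert post.sum() == pytest.approx(1.0)


def test_posteriors_uniform_under_symmetry(tiny_panel):
    # identical groups with equal weights: posterior must be exactly uniform
    fit = manual_fit([0.5, 0.5], [[2.0, 0.3], [2.0, 0.3]], sigma=1.0)
    post = posteriors(fit, tiny_panel)
    assert np.allclose(post, 0.5, atol=1e-12)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def test_assign_argmax_and_tie_break():
    post = np.array([[0.2, 0.8], [0.5, 0.5], [0.7, 0.3]])
    assert np.array_equal(assign(post), [1, 0, 0])


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_assign_equals_rowwise_brute_force(seed):
    rng = np.random.default_rng(seed)
    post = rng.dirichlet(np.ones(4), size=8)
    expected = [int(np.flatnonzero(r == r.max())[0]) for r in post]
    assert np.array_equal(assign(post), expected)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def test_em_loglik_monotone_and_converges(two_line_config):
    panel = generate_scenario(two_line_config)
    fit = fit_gbtm(panel, GBTMSpec(n_groups=2, poly_order=1, n_starts=3), seed=0)
    assert fit.converged
    diffs = np.diff(fit.loglik_history)
    assert np.all(diffs > -1e-9)


def test_separable_groups_recovered_to_high_precision():
    """Noise-free limit: weights and coefficients recovered ~exactly."""
    from trajspur.scenarios import ScenarioConfig

    cfg = ScenarioConfig(
        scenario_id=1, n=100, t=5,
        group_weights=np.array([0.5, 0.5]),
        mean_coefficients=[np.array([0.0, 2.0]), np.array([30.0, -1.0])],
        random_intercept=[{"dist": "none"}] * 2,
        residual_sd=np.full((2, 5), 1e-6),
        seed=3,
    )
    panel = generate_scenario(cfg)
    fit = fit_gbtm(panel, GBTMSpec(n_groups=2, poly_order=1, n_starts=3), seed=0)
    w_true = np.bincount(panel.true_groups() - 1) / 100
    assert np.allclose(np.sort(fit.pi), np.sort(w_true), atol=1e-6)
    betas = sorted(fit.beta, key=lambda b: b[0])
    assert np.allclose(betas[0], [0.0, 2.0], atol=1e-5)
    assert np.allclose(betas[1], [30.0, -1.0], atol=1e-5)


def test_one_group_fit_equals_polynomial_least_squares():
    rng = np.random.default_rng(8)
    times = np.arange(1.0, 6.0)
    N = 40
    Y = 2.0 + 0.8 * times - 0.1 * times**2 + rng.standard_normal((N, 5))
    panel = make_panel(Y)
    fit = fit_gbtm(panel, GBTMSpec(n_groups=1, poly_order=2, n_starts=1), seed=0)
    X = np.vander(np.tile(times, N), 3, increasing=True)
    beta_ols, *_ = np.linalg.lstsq(X, Y.ravel(), rcond=None)
    assert np.allclose(fit.beta[0], beta_ols, atol=1e-8)
    resid = Y.ravel() - X @ beta_ols
    assert fit.sigma**2 == pytest.approx(np.mean(resid**2), abs=1e-8)


def test_censored_path_reduces_to_normal_with_infinite_bounds(tiny_panel):
    fit = manual_fit([0.5, 0.5], [[1, 1], [8, -0.4]], sigma=0.9)
    fit_c = manual_fit(
        [0.5, 0.5], [[1, 1], [8, -0.4]], sigma=0.9,
        censor_low=-1e9, censor_high=1e9,
    )
    assert mixture_loglik(tiny_panel, fit) == pytest.approx(
        mixture_loglik(tiny_panel, fit_c), abs=1e-12
    )


def test_censored_fit_handles_bounded_outcomes():
    """Censored EM recovers a mean pushed against the scale ceiling."""
    rng = np.random.default_rng(4)
    latent = 4.0 + 0.5 * np.arange(1.0, 4.0) + rng.standard_normal((60, 3))
    Y = np.clip(latent, 0.0, 6.0)
    panel = make_panel(Y, times=[1.0, 2.0, 3.0])
    spec = GBTMSpec(n_groups=1, poly_order=1, censor_low=0.0, censor_high=6.0, n_starts=1)
    fit = fit_gbtm(panel, spec, seed=0)
    # naive OLS on clipped data is biased low; censored ML should not be
    assert fit.beta[0][0] + fit.beta[0][1] * 3.0 > np.mean(Y[:, 2])


def test_n_params_bookkeeping():
    spec = GBTMSpec(n_groups=3, poly_order=[3, 2, 0])
    assert spec.n_params == (4 + 3 + 1) + 1 + 2
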