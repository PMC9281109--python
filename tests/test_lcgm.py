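import numpy as np
import pytest
from scipy import stats

from trajspur.gbtm import GBTMSpec, fit_gbtm
from trajspur.lcgm import fit_lcgm, lcgm_class_loglik
from trajspur.scenarios import ScenarioConfig, generate_scenario
from tests.conftest import make_panel


def test_zero_tau_equals_gbtm_conditional_loglik():
    from trajspur.gbtm import group_conditional_loglik

    y = [1.2, 2.1, 2.8]
    t = [1.0, 2.0, 3.0]
    beta = [0.5, 0.8]
    assert lcgm_class_loglik(y, t, beta, tau_j=0.0, sigma=1.1) == pytest.approx(
        group_conditional_loglik(y, t, beta, 1.1), abs=1e-10
    )


def test_single_occasion_is_univariate_normal():
    val = lcgm_class_loglik([2.0], [1.0], [1.0, 0.5], tau_j=0.7, sigma=1.2)
    assert val == pytest.approx(
        stats.norm.logpdf(2.0, loc=1.5, scale=np.sqrt(0.7**2 + 1.2**2)), abs=1e-12
    )


def test_matches_dense_multivariate_normal_oracle():
    y = np.array([1.0, 2.5, 1.8])
    t = np.array([0.0, 1.0, 2.0])
    beta = np.array([1.2, 0.4])
    tau, sigma = 0.9, 0.6
    mu = beta[0] + beta[1] * t
    cov = tau**2 * np.ones((3, 3)) + sigma**2 * np.eye(3)
    dense = stats.multivariate_normal.logpdf(y, mean=mu, cov=cov)
    assert lcgm_class_loglik(y, t, beta, tau, sigma) == pytest.approx(dense, abs=1e-10)


def test_invalid_variance_parameters():
    with pytest.raises(ValueError):
        lcgm_class_loglik([1.0], [1.0], [0.0], tau_j=-0.1, sigma=1.0)
    with pytest.raises(ValueError):
        lcgm_class_loglik([1.0], [1.0], [0.0], tau_j=0.1, sigma=0.0)


def _lcgm_config(seed):
    return ScenarioConfig(
        scenario_id=1, n=400, t=5,
        group_weights=np.array([0.5, 0.5]),
        mean_coefficients=[np.array([0.0, 1.5]), np.array([14.0, -1.0])],
        random_intercept=[{"dist": "normal", "sd": 1.2}, {"dist": "normal", "sd": 0.6}],
        residual_sd=np.full((2, 5), 0.8),
        seed=seed,
    )


def test_lcgm_recovers_its_own_generating_process():
    cfg = _lcgm_config(31)
    panel = generate_scenario(cfg)
    fit = fit_lcgm(panel, GBTMSpec(n_groups=2, poly_order=1, n_starts=3), seed=1)
    assert fit.converged
    order = np.argsort([b[0] for b in fit.beta])
    betas = [fit.beta[k] for k in order]
    taus = fit.tau[order]
    assert np.allclose(betas[0], [0.0, 1.5], atol=0.25)
    assert np.allclose(betas[1], [14.0, -1.0], atol=0.25)
    assert taus[0] == pytest.approx(1.2, abs=0.3)
    assert taus[1] == pytest.approx(0.6, abs=0.3)
    assert fit.sigma == pytest.approx(0.8, abs=0.1)


def test_tau_pinned_to_zero_matches_gbtm_loglik():
    cfg = _lcgm_config(5)
    panel = generate_scenario(cfg)
    spec = GBTMSpec(n_groups=2, poly_order=1, n_starts=2)
    gfit = fit_gbtm(panel, spec, seed=2)
    lfit = fit_lcgm(panel, spec, seed=2, tau_fixed=np.zeros(2))
    assert lfit.loglik == pytest.approx(gfit.loglik, abs=1e-4)


def test_lcgm_nests_gbtm():
    """sup over tau >= 0 of the LCGM loglik dominates the GBTM loglik."""
    cfg = _lcgm_config(9)
    panel = generate_scenario(cfg)
    spec = GBTMSpec(n_groups=2, poly_order=1, n_starts=2)
    gfit = fit_gbtm(panel, spec, seed=0)
    lfit = fit_lcgm(panel, spec, seed=0)
    assert lfit.loglik >= gfit.loglik - 1e-6


def test_nonconvergence_is_reported_not_raised():
    rng = np.random.default_rng(0)
    panel = make_panel(rng.standard_normal((30, 4)))
    fit = fit_lcgm(panel, GBTMSpec(n_groups=2, poly_order=1, n_starts=1), seed=0, max_iter=2)
    assert not fit.converged
    assert fit.failure_reason is not None
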