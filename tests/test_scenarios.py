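import numpy as np
import pytest

from trajspur.scenarios import ScenarioConfig, default_config, generate_scenario


@pytest.mark.parametrize("sid,expected_n", [(1, 500), (2, 300), (3, 500), (4, 500), (5, 500), (6, 500)])
def test_shipped_sample_sizes(sid, expected_n):
    cfg = default_config(sid)
    assert cfg.n == expected_n
    assert cfg.t == 5


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario_id"):
        default_config(7)


def test_scenarios_without_subgroups_have_single_weight():
    for sid in (5, 6):
        cfg = default_config(sid)
        assert len(cfg.group_weights) == 1
        assert cfg.group_weights[0] == 1.0


def test_config_validation():
    with pytest.raises(ValueError, match="probability vector"):
        ScenarioConfig(
            scenario_id=1, n=10, t=2,
            group_weights=np.array([0.5, 0.6]),
            mean_coefficients=[np.zeros(1)] * 2,
            random_intercept=[{"dist": "none"}] * 2,
            residual_sd=np.ones((2, 2)),
        )
    with pytest.raises(ValueError, match="residual_sd"):
        ScenarioConfig(
            scenario_id=1, n=10, t=2,
            group_weights=np.array([1.0]),
            mean_coefficients=[np.zeros(1)],
            random_intercept=[{"dist": "none"}],
            residual_sd=np.zeros((1, 2)),
        )


def test_generation_deterministic_and_stable_in_n():
    cfg = default_config(3, seed=42)
    p1 = generate_scenario(cfg)
    p2 = generate_scenario(cfg)
    assert p1.data.equals(p2.data)
    # growing n must not reshuffle earlier subjects (counter-based streams)
    cfg_small = default_config(3, seed=42)
    cfg_small.n = 50
    p_small = generate_scenario(cfg_small)
    merged = p1.data.merge(
        p_small.data, on=["subject_id", "occasion"], suffixes=("", "_small")
    )
    assert np.allclose(merged["y"], merged["y_small"])
    assert np.array_equal(merged["true_group"], merged["true_group_small"])


def test_noise_free_limit_reproduces_group_means():
    cfg = ScenarioConfig(
        scenario_id=1, n=40, t=4,
        group_weights=np.array([0.5, 0.5]),
        mean_coefficients=[np.array([1.0, 2.0]), np.array([10.0, -1.0, 0.5])],
        random_intercept=[{"dist": "none"}] * 2,
        residual_sd=np.full((2, 4), 1e-12),
        seed=7,
    )
    panel = generate_scenario(cfg)
    Y, times = panel.balanced()
    means = cfg.group_means()
    groups = panel.true_groups() - 1
    assert np.allclose(Y, means[groups], atol=1e-9)


def test_group_frequencies_match_weights_binomially():
    cfg = default_config(3, seed=123)
    cfg.n = 2000
    panel = generate_scenario(cfg)
    groups = panel.true_groups()
    for j, w in enumerate(cfg.group_weights, start=1):
        freq = np.mean(groups == j)
        se = np.sqrt(w * (1 - w) / cfg.n)
        assert abs(freq - w) < 3 * se


def test_cell_moments_match_generator():
    """Sample mean -> polynomial mean; sample variance -> tau^2 + sd^2."""
    cfg = default_config(1, seed=9)
    cfg.n = 4000
    panel = generate_scenario(cfg)
    Y, times = panel.balanced()
    groups = panel.true_groups() - 1
    means = cfg.group_means()
    for j in range(cfg.n_groups):
        sub = Y[groups == j]
        tau = cfg.random_intercept[j]["sd"]
        for tt in range(cfg.t):
            var_true = tau**2 + cfg.residual_sd[j, tt] ** 2
            se_mean = np.sqrt(var_true / len(sub))
            assert abs(sub[:, tt].mean() - means[j, tt]) < 4 * se_mean
            assert abs(sub[:, tt].var(ddof=1) - var_true) < 4 * var_true * np.sqrt(2 / len(sub))


def test_rainbow_scenario_is_flat_topped_not_bimodal():
    """Uniform-intercept continuum: cross-sections show no central dip."""
    cfg = default_config(5, seed=21)
    cfg.n = 4000
    panel = generate_scenario(cfg)
    Y, _ = panel.balanced()
    x = Y[:, 2] - np.mean(Y[:, 2])
    hist, edges = np.histogram(x, bins=np.linspace(-3, 3, 13), density=True)
    centre = hist[4:8].mean()
    shoulders = (hist[2:4].mean() + hist[8:10].mean()) / 2
    assert centre >= shoulders  # flat-topped, no multimodality


def test_no_pattern_scenario_has_vanishing_trend():
    cfg = default_config(6, seed=3)
    cfg.n = 5000
    panel = generate_scenario(cfg)
    t = panel.data["time"].to_numpy()
    y = panel.data["y"].to_numpy()
    slope = np.polyfit(t, y, 1)[0]
    # slope standard error ~ sd(y)/(sd(t)*sqrt(n_obs))
    se = y.std() / (t.std() * np.sqrt(len(y)))
    assert abs(slope) < 4 * se


def test_config_yaml_roundtrip(tmp_path):
    cfg = default_config(4, seed=5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = ScenarioConfig.from_yaml(path)
    assert back.scenario_id == 4 and back.n == cfg.n and back.seed == cfg.seed
    assert np.allclose(back.residual_sd, cfg.residual_sd)
    assert generate_scenario(back).data.equals(generate_scenario(cfg).data)
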