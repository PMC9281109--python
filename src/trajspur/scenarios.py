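"""Synthetic longitudinal scenarios.

Six shipped scenarios emulate recurring situations in applied trajectory
analysis: clearly separated subgroups (1), subgroups whose value ranges
differ by an order of magnitude (2), subgroup distributions overlapping at
specific time points (3), within-subgroup variance growing over follow-up
(4), a continuum of individual trajectories rather than discrete subgroups
— the "rainbow" situation (5), and pure noise with no temporal pattern (6).

Each scenario draws, per subject, a generating subgroup, a persistent
subject-level intercept, and independent occasion-level noise:

    y_it = polynomial_g(time_t) + b_i + e_it,
    b_i ~ N(0, tau_g) or U(-a_g, a_g) or 0,   e_it ~ N(0, sd_gt)

Subject-level random streams are derived from (seed, subject index), so
panels are reproducible and growing ``n`` never reshuffles earlier
subjects.  The generating parameters ship as versioned YAML files under
``trajspur/data`` and can be overridden by user-supplied config files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from trajspur.panel import LongitudinalPanel

SCHEMA_VERSION = 1

_INTERCEPT_DISTS = ("normal", "uniform", "none")


@dataclass
class ScenarioConfig:
    """Full generating specification for one synthetic scenario."""

    scenario_id: int
    n: int
    t: int
    group_weights: np.ndarray
    mean_coefficients: list[np.ndarray]  # ascending-order polynomial coefficients
    random_intercept: list[dict]  # per group: {"dist": ..., "sd"/"halfwidth": ...}
    residual_sd: np.ndarray  # shape (G, t)
    time_start: float = 1.0
    time_step: float = 1.0
    seed: int = 0
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.group_weights = np.asarray(self.group_weights, dtype=float)
        self.mean_coefficients = [np.asarray(b, dtype=float) for b in self.mean_coefficients]
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        G = len(self.group_weights)
        if self.group_weights.min() < 0 or abs(self.group_weights.sum() - 1.0) > 1e-8:
            raise ValueError("group_weights must be a probability vector")
        if len(self.mean_coefficients) != G or len(self.random_intercept) != G:
            raise ValueError("per-group fields must all have length G")
        if self.residual_sd.shape != (G, self.t):
            raise ValueError(f"residual_sd must have shape (G, t) = ({G}, {self.t})")
        if np.any(self.residual_sd <= 0):
            raise ValueError("residual_sd entries must be > 0")
        for spec in self.random_intercept:
            if spec.get("dist") not in _INTERCEPT_DISTS:
                raise ValueError(f"unknown intercept dist: {spec.get('dist')}")
        if any(len(b) > 4 for b in self.mean_coefficients):
            raise ValueError("mean polynomials are at most cubic")

    @property
    def n_groups(self) -> int:
        return len(self.group_weights)

    @property
    def times(self) -> np.ndarray:
        return self.time_start + self.time_step * np.arange(self.t)

    def group_means(self) -> np.ndarray:
        """Generating mean curves, shape (G, t)."""
        return np.stack(
            [np.polynomial.polynomial.polyval(self.times, b) for b in self.mean_coefficients]
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "scenario_id": self.scenario_id,
            "name": self.name,
            "description": self.description,
            "n": self.n,
            "t": self.t,
            "time_start": self.time_start,
            "time_step": self.time_step,
            "seed": self.seed,
            "groups": [
                {
                    "weight": float(w),
                    "beta": [float(c) for c in b],
                    "intercept": dict(ri),
                    "residual_sd": [float(s) for s in sd],
                }
                for w, b, ri, sd in zip(
                    self.group_weights,
                    self.mean_coefficients,
                    self.random_intercept,
                    self.residual_sd,
                )
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        if d.get("schema_version", 1) != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {d.get('schema_version')}")
        groups = d["groups"]
        t = int(d["t"])
        residual = []
        for g in groups:
            sd = g["residual_sd"]
            residual.append([float(sd)] * t if np.isscalar(sd) else list(sd))
        return cls(
            scenario_id=int(d["scenario_id"]),
            n=int(d["n"]),
            t=t,
            group_weights=np.array([g["weight"] for g in groups]),
            mean_coefficients=[np.array(g["beta"]) for g in groups],
            random_intercept=[dict(g["intercept"]) for g in groups],
            residual_sd=np.array(residual),
            time_start=float(d.get("time_start", 1.0)),
            time_step=float(d.get("time_step", 1.0)),
            seed=int(d.get("seed", 0)),
            name=d.get("name", ""),
            description=d.get("description", ""),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(scenario_id: int, seed: int = 0) -> ScenarioConfig:
    """Load the packaged generating parameters for scenario 1..6."""
    if scenario_id not in range(1, 7):
        raise ValueError(f"unknown scenario_id {scenario_id}; must be 1..6")
    ref = importlib.resources.files("trajspur.data").joinpath(f"scenario{scenario_id}.yaml")
    cfg = ScenarioConfig.from_dict(yaml.safe_load(ref.read_text()))
    cfg.seed = seed
    return cfg


def _draw_intercept(rng: np.random.Generator, spec: dict) -> float:
    dist = spec["dist"]
    if dist == "normal":
        return rng.normal(0.0, spec["sd"])
    if dist == "uniform":
        a = spec["halfwidth"]
        return rng.uniform(-a, a)
    return 0.0


def generate_scenario(config: ScenarioConfig) -> LongitudinalPanel:
    """Simulate a balanced panel from a scenario configuration.

    Deterministic given ``config.seed``; subject ``i`` uses the random
    stream keyed by ``(seed, i)``.
    """
    times = config.times
    means = config.group_means()
    cum_w = np.cumsum(config.group_weights)
    rows_y = np.empty((config.n, config.t))
    groups = np.empty(config.n, dtype=int)
    for i in range(config.n):
        rng = np.random.default_rng([config.seed, i])
        g = int(np.searchsorted(cum_w, rng.random(), side="right"))
        g = min(g, config.n_groups - 1)  # guard against cum_w[-1] < 1 by rounding
        b = _draw_intercept(rng, config.random_intercept[g])
        noise = rng.standard_normal(config.t) * config.residual_sd[g]
        rows_y[i] = means[g] + b + noise
        groups[i] = g + 1
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(1, config.n + 1), config.t),
            "occasion": np.tile(np.arange(1, config.t + 1), config.n),
            "time": np.tile(times, config.n),
            "y": rows_y.ravel(),
            "true_group": np.repeat(groups, config.t),
        }
    )
    return LongitudinalPanel(df)
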