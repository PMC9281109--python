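"""End-to-end scenario runner.

Reproduces the simulation study design on any of the shipped scenarios:
simulate a panel, fit cubic GBTMs with 1..10 subgroups, select the number
of subgroups by the Bayes-factor rule, prune non-significant polynomial
terms, compute classification-adequacy criteria, compare the fitted
subgroups with the generating truth, and run the LCGM sensitivity
analysis.  Replicated runs aggregate the selected subgroup count by
majority vote and the adequacy criteria by mean +/- SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from trajspur.adequacy import AdequacyReport, adequacy_report
from trajspur.gbtm import GBTMFit
from trajspur.lcgm import lcgm_fitter
from trajspur.panel import LongitudinalPanel
from trajspur.scenarios import ScenarioConfig, default_config, generate_scenario
from trajspur.selection import SelectionTrace, select_num_groups

# "correct shape" = matched-curve RMSE below this fraction of the pooled y SD
# AND agreement of the sign pattern of the mean curve's first differences
SHAPE_RMSE_FRACTION = 0.25
# "correct size" = every matched group within this many percentage points
SIZE_TOL_PP = 5.0


@dataclass
class ScenarioReport:
    scenario_id: int
    seed: int
    config: ScenarioConfig
    trace: SelectionTrace
    selected_k_gbtm: int
    group_sizes_pct: np.ndarray
    adequacy: AdequacyReport
    shape_match: dict
    truth_recovery: dict
    lcgm_outcome: dict | None = None
    panel: LongitudinalPanel = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "seed": self.seed,
            "selected_k_gbtm": self.selected_k_gbtm,
            "group_sizes_pct": self.group_sizes_pct.tolist(),
            "adequacy": self.adequacy.to_dict(),
            "shape_match": _jsonable(self.shape_match),
            "truth_recovery": self.truth_recovery,
            "lcgm_outcome": self.lcgm_outcome,
            "min_group_count": self.trace.min_group_count,
            "bic_values": [None if b is None else float(b) for b in self.trace.bic_values],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def match_groups_to_truth(fit: GBTMFit, panel: LongitudinalPanel, config: ScenarioConfig) -> dict:
    """Match fitted subgroups to generating subgroups and diagnose recovery.

    Matching minimises the integrated squared distance between mean curves
    over the observation grid (optimal one-to-one assignment).  When more
    subgroups were fitted than generated, the unmatched fits are reported
    as spurious splits; shape agreement combines curve RMSE with the sign
    pattern of the curve's first differences.
    """
    if not panel.has_true_group:
        raise ValueError("panel carries no true_group labels")
    times = config.times
    true_curves = config.group_means()
    est_curves = fit.mean_curves(times)
    G, K = len(true_curves), len(est_curves)
    cost = np.array(
        [[np.mean((tc - ec) ** 2) for ec in est_curves] for tc in true_curves]
    )
    rows, cols = linear_sum_assignment(cost)
    pooled_sd = float(panel.data["y"].std())
    # realized group shares in this panel, not the nominal weights
    true_sizes = np.bincount(panel.true_groups() - 1, minlength=G) / panel.n_subjects * 100.0
    est_sizes = fit.group_counts / fit.n_subjects * 100.0
    matches = []
    for g, k in zip(rows, cols):
        rmse = float(np.sqrt(cost[g, k]))
        sign_true = np.sign(np.round(np.diff(true_curves[g]), 10))
        sign_est = np.sign(np.round(np.diff(est_curves[k]), 10))
        matches.append(
            {
                "true_group": int(g),
                "est_group": int(k),
                "rmse": rmse,
                "rmse_ok": rmse < SHAPE_RMSE_FRACTION * pooled_sd,
                "slope_signs_agree": bool(np.all(sign_true == sign_est)),
                "size_diff_pp": float(est_sizes[k] - true_sizes[g]),
            }
        )
    surplus = sorted(set(range(K)) - set(cols.tolist()))
    unmatched_true = sorted(set(range(G)) - set(rows.tolist()))
    shapes_ok = all(m["rmse_ok"] and m["slope_signs_agree"] for m in matches) and not unmatched_true
    sizes_ok = (
        K == G
        and not unmatched_true
        and all(abs(m["size_diff_pp"]) <= SIZE_TOL_PP for m in matches)
    )
    return {
        "matches": matches,
        "spurious_est_groups": surplus,
        "unmatched_true_groups": unmatched_true,
        "correct_number": K == G,
        "correct_shapes": shapes_ok,
        "correct_sizes": sizes_ok,
        "pooled_sd": pooled_sd,
    }


def run_scenario(
    scenario_id: int,
    seed: int = 0,
    n_replicates: int = 1,
    k_max: int = 10,
    rule: str = "bayes_factor",
    n_starts: int = 10,
    run_lcgm: bool = False,
    lcgm_k_max: int = 4,
    config: ScenarioConfig | None = None,
    keep_panel: bool = False,
) -> "ScenarioReport | list[ScenarioReport]":
    """Run the full chain for one scenario; replicates vary the seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reports = []
    for r in range(n_replicates):
        rep_seed = seed + r
        cfg = config if config is not None else default_config(scenario_id)
        cfg.seed = rep_seed
        panel = generate_scenario(cfg)
        trace = select_num_groups(
            panel, k_max=k_max, rule=rule, seed=rep_seed, n_starts=n_starts
        )
        fit = trace.selected_fit
        adequacy = adequacy_report(fit)
        shape = match_groups_to_truth(fit, panel, cfg)
        lcgm_outcome = None
        if run_lcgm:
            lcgm_trace = select_num_groups(
                panel,
                k_max=lcgm_k_max,
                rule=rule,
                seed=rep_seed,
                prune_selected=False,
                fitter=lcgm_fitter(),
            )
            lf = lcgm_trace.selected_fit
            lcgm_outcome = {
                "selected_k": lcgm_trace.selected_k,
                "converged": bool(lf.converged),
                "failure_reason": lf.failure_reason,
                "any_nonconverged": any(
                    f is not None and not f.converged for f in lcgm_trace.fits
                ),
            }
        reports.append(
            ScenarioReport(
                scenario_id=scenario_id,
                seed=rep_seed,
                config=cfg,
                trace=trace,
                selected_k_gbtm=trace.selected_k,
                group_sizes_pct=fit.group_counts / fit.n_subjects * 100.0,
                adequacy=adequacy,
                shape_match=shape,
                truth_recovery={
                    "correct_number": shape["correct_number"],
                    "correct_shapes": shape["correct_shapes"],
                    "correct_sizes": shape["correct_sizes"],
                },
                lcgm_outcome=lcgm_outcome,
                panel=panel if keep_panel else None,
            )
        )
    return reports[0] if n_replicates == 1 else reports


def aggregate_reports(reports: list[ScenarioReport]) -> dict:
    """Majority vote for selected k and recovery booleans; mean +/- SD for
    the adequacy criteria, across replicate seeds."""
    ks = [r.selected_k_gbtm for r in reports]
    vals, counts = np.unique(ks, return_counts=True)
    majority_k = int(vals[np.argmax(counts)])
    ents = np.array([r.adequacy.relative_entropy for r in reports])
    out = {
        "scenario_id": reports[0].scenario_id,
        "n_replicates": len(reports),
        "selected_k_majority": majority_k,
        "selected_k_all": ks,
        "entropy_mean": float(ents.mean()),
        "entropy_sd": float(ents.std(ddof=1)) if len(ents) > 1 else 0.0,
        "min_app_mean": float(np.mean([np.nanmin(r.adequacy.app) for r in reports])),
        "max_abs_mismatch_mean": float(
            np.mean([np.max(np.abs(r.adequacy.mismatch_pct)) for r in reports])
        ),
    }
    for key in ("correct_number", "correct_shapes", "correct_sizes"):
        votes = [r.truth_recovery[key] for r in reports]
        out[f"{key}_majority"] = bool(sum(votes) * 2 > len(votes))
    out["largest_group_pct_mean"] = float(
        np.mean([np.max(r.group_sizes_pct) for r in reports])
    )
    for flag in ("app_ok", "entropy_ok", "mismatch_ok"):
        votes = [getattr(r.adequacy, flag) for r in reports]
        out[f"{flag}_majority"] = bool(sum(votes) * 2 > len(votes))
    return out


def run_study(
    seeds=range(1, 11),
    scenarios=range(1, 7),
    k_max: int = 10,
    n_starts: int = 5,
) -> dict:
    """Replicate the whole six-scenario study and aggregate per scenario."""
    out = {}
    for sid in scenarios:
        reports = [run_scenario(sid, seed=s, k_max=k_max, n_starts=n_starts) for s in seeds]
        out[sid] = aggregate_reports(reports)
        out[sid]["reports"] = reports
    return out
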