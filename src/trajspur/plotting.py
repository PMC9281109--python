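"""Figure and table rendering for scenario reports.

Per scenario: occasion-wise boxplots of the simulated data by generating
subgroup with the estimated mean trajectories overlaid, a spaghetti plot of
a seeded random subset of individual series coloured by assigned subgroup
(the recommended visual check for within-subgroup heterogeneity), an
adequacy table and a fit-index table.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from trajspur.pipeline import ScenarioReport
from trajspur.scenarios import generate_scenario

SPAGHETTI_SUBJECTS = 60


def render_outputs(reports: list[ScenarioReport], out_dir) -> list[Path]:
    """Write figures (PNG) and tables (CSV + text) for each report.

    Returns the list of files written; an empty report list writes nothing.
    """
    out = Path(out_dir)
    written: list[Path] = []
    if not reports:
        return written
    out.mkdir(parents=True, exist_ok=True)
    for rep in reports:
        tag = f"scenario{rep.scenario_id}_seed{rep.seed}"
        panel = rep.panel if rep.panel is not None else generate_scenario(rep.config)
        fit = rep.trace.selected_fit
        written.append(_boxplot_figure(panel, rep, fit, out / f"{tag}_boxplots.png"))
        written.append(_spaghetti_figure(panel, rep, fit, out / f"{tag}_spaghetti.png"))
        written.append(_adequacy_table(rep, out / f"{tag}_adequacy"))
        written.append(_fit_index_table(rep, out / f"{tag}_fit_indices"))
    return written


def _boxplot_figure(panel, rep, fit, path: Path) -> Path:
    df = panel.data
    occasions = sorted(df["occasion"].unique())
    groups = sorted(df["true_group"].unique()) if panel.has_true_group else [None]
    G = len(groups)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    width = 0.8 / G
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(groups):
        sub = df if g is None else df[df["true_group"] == g]
        data = [sub.loc[sub["occasion"] == occ, "y"].to_numpy() for occ in occasions]
        # shift boxes per subgroup so they do not overlap at an occasion
        positions = [occ + (gi - (G - 1) / 2) * width for occ in occasions]
        bp = ax.boxplot(
            data, positions=positions, widths=width * 0.9, patch_artist=True,
            showfliers=False, medianprops={"color": "black"},
        )
        for box in bp["boxes"]:
            box.set_facecolor(cmap(gi))
            box.set_alpha(0.45)
    time_by_occ = df.groupby("occasion")["time"].first()
    grid = np.linspace(time_by_occ.min(), time_by_occ.max(), 50)
    occ_grid = np.interp(
        grid, time_by_occ.to_numpy(), np.array(occasions, dtype=float)
    )
    for k, curve in enumerate(fit.mean_curves(grid)):
        ax.plot(occ_grid, curve, lw=2, color="black")
        ax.plot(occ_grid, curve, lw=1.4, color=cmap(k), ls="--")
    ax.set_xticks(occasions)
    ax.set_xticklabels(occasions)
    ax.set_xlabel("occasion")
    ax.set_ylabel("y")
    ax.set_title(
        f"Scenario {rep.scenario_id}: simulated subgroups (boxes) "
        f"and {fit.n_groups} estimated trajectories"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _spaghetti_figure(panel, rep, fit, path: Path) -> Path:
    rng = np.random.default_rng(rep.seed)
    ids = panel.subject_ids
    take = min(SPAGHETTI_SUBJECTS, len(ids))
    chosen = rng.choice(ids, size=take, replace=False)
    id_to_row = {sid: i for i, sid in enumerate(sorted(ids))}
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in chosen:
        sub = panel.data[panel.data["subject_id"] == sid]
        k = fit.assignments[id_to_row[sid]]
        ax.plot(sub["time"], sub["y"], color=cmap(int(k)), alpha=0.5, lw=0.8)
    grid = np.linspace(panel.data["time"].min(), panel.data["time"].max(), 50)
    for k, curve in enumerate(fit.mean_curves(grid)):
        ax.plot(grid, curve, color=cmap(k), lw=2.5)
    ax.set_xlabel("time")
    ax.set_ylabel("y")
    ax.set_title(
        f"Scenario {rep.scenario_id}: individual series by assigned subgroup "
        f"({take} subjects)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _adequacy_table(rep, stem: Path) -> Path:
    ad = rep.adequacy
    J = len(ad.app)
    df = pd.DataFrame(
        {
            "group": np.arange(1, J + 1),
            "app": ad.app,
            "mismatch_pct": ad.mismatch_pct,
            "assigned_prop": ad.assigned_prop,
            "pi_hat": ad.pi_hat,
        }
    )
    df["relative_entropy"] = [ad.relative_entropy] + [np.nan] * (J - 1)
    csv_path = stem.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    stem.with_suffix(".txt").write_text(ad.table() + "\n")
    return csv_path


def _fit_index_table(rep, stem: Path) -> Path:
    trace = rep.trace
    rows = []
    prev = None
    for k, (f, b) in enumerate(zip(trace.fits, trace.bic_values), start=1):
        rows.append(
            {
                "k": k,
                "n_params": None if f is None else f.n_params,
                "loglik": None if f is None else f.loglik,
                "bic": b,
                "two_delta_bic": None if (b is None or prev is None) else 2 * (b - prev),
                "selected": k == trace.selected_k,
            }
        )
        if b is not None:
            prev = b
    csv_path = stem.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    stem.with_suffix(".txt").write_text(trace.table() + "\n")
    return csv_path
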