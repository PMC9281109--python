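"""Classification-adequacy criteria for fitted trajectory models.

Three complementary diagnostics of how well subjects are classified into
the fitted subgroups:

* **APP** — average posterior probability of membership among subjects
  assigned to a subgroup; > 0.70 in every subgroup is the conventional
  adequacy bar.
* **Relative entropy** — one minus the normalised Shannon entropy of the
  posterior matrix, E = 1 - sum_ij(-p_ij log p_ij) / (N log J); 1 means
  crisp classification, 0 uninformative; > 0.80 is the conventional bar.
* **Mismatch** — estimated mixing proportion minus the proportion actually
  assigned to the subgroup, in percentage points; values near 0 indicate
  agreement between the model's and the classification's subgroup sizes.

APP alone is known to stay high even when the fitted subgroups are
artefacts; entropy and mismatch are the criteria that tend to expose them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from trajspur.gbtm import GBTMFit, assign

APP_CUTOFF = 0.70
ENTROPY_CUTOFF = 0.80
MISMATCH_CUTOFF_PP = 2.0


def average_posterior_probability(posterior: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """APP_j: mean posterior probability p_ij over subjects assigned to j.

    Empty subgroups get NaN (flagged downstream, never silently passed).
    """
    post = np.asarray(posterior, dtype=float)
    J = post.shape[1]
    out = np.full(J, np.nan)
    for j in range(J):
        members = assignments == j
        if members.any():
            out[j] = post[members, j].mean()
    return out


def relative_entropy(posterior: np.ndarray, log_base: float | None = None) -> float:
    """Normalised classification certainty in [0, 1].

    ``log_base=None`` uses the natural log (the normaliser N ln J); any
    base cancels in the ratio, so the value is base-invariant — the knob
    exists only for reporting raw entropies elsewhere.  For J = 1 the
    classification is vacuous and the conventional value 1 is returned.
    """
    post = np.asarray(posterior, dtype=float)
    N, J = post.shape
    if J == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    shannon = -plogp.sum()
    return float(1.0 - shannon / (N * np.log(J)))


def mismatch(pi_hat: np.ndarray, assignments: np.ndarray, N: int) -> np.ndarray:
    """Per-group mismatch in percentage points: 100*(pi_hat_j - n_j/N)."""
    pi_hat = np.asarray(pi_hat, dtype=float)
    counts = np.bincount(np.asarray(assignments), minlength=len(pi_hat))
    return 100.0 * (pi_hat - counts / N)


@dataclass
class AdequacyReport:
    app: np.ndarray
    relative_entropy: float
    mismatch_pct: np.ndarray
    assigned_prop: np.ndarray
    pi_hat: np.ndarray
    app_ok: bool
    entropy_ok: bool
    mismatch_ok: bool

    @property
    def all_ok(self) -> bool:
        return self.app_ok and self.entropy_ok and self.mismatch_ok

    def to_dict(self) -> dict:
        return {
            "app": self.app.tolist(),
            "relative_entropy": self.relative_entropy,
            "mismatch_pct": self.mismatch_pct.tolist(),
            "assigned_prop": self.assigned_prop.tolist(),
            "pi_hat": self.pi_hat.tolist(),
            "app_ok": bool(self.app_ok),
            "entropy_ok": bool(self.entropy_ok),
            "mismatch_ok": bool(self.mismatch_ok),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        """Formatted adequacy table: per-group APP and mismatch rows, a
        single entropy row, and a verdict column."""
        J = len(self.app)
        head = "Criterion".ljust(30) + "".join(f"{j + 1:>9}" for j in range(J))
        app_row = "Average posterior probability".ljust(30) + "".join(
            f"{v:9.2f}" for v in self.app
        )
        mis_row = "Mismatch".ljust(30) + "".join(f"{v:9.2f}" for v in self.mismatch_pct)
        ent_row = "Relative entropy".ljust(30) + f"{self.relative_entropy:9.2f}"
        verdict = (
            "All criteria suggest good classification"
            if self.all_ok
            else "Criteria failing: "
            + ", ".join(
                name
                for name, ok in [
                    ("APP", self.app_ok),
                    ("entropy", self.entropy_ok),
                    ("mismatch", self.mismatch_ok),
                ]
                if not ok
            )
        )
        return "\n".join([head, app_row, mis_row, ent_row, verdict])


def adequacy_report(
    fit: GBTMFit,
    app_cutoff: float = APP_CUTOFF,
    entropy_cutoff: float = ENTROPY_CUTOFF,
    mismatch_cutoff_pp: float = MISMATCH_CUTOFF_PP,
) -> AdequacyReport:
    """Assemble APP, relative entropy and mismatch with pass/fail flags."""
    post = fit.posterior
    assignments = fit.assignments if fit.assignments is not None else assign(post)
    N = post.shape[0]
    app = average_posterior_probability(post, assignments)
    ent = relative_entropy(post)
    mis = mismatch(fit.pi, assignments, N)
    counts = np.bincount(assignments, minlength=post.shape[1])
    return AdequacyReport(
        app=app,
        relative_entropy=ent,
        mismatch_pct=mis,
        assigned_prop=counts / N,
        pi_hat=np.asarray(fit.pi, dtype=float),
        app_ok=bool(np.all(np.nan_to_num(app, nan=-1.0) > app_cutoff)),
        entropy_ok=bool(ent > entropy_cutoff),
        mismatch_ok=bool(np.max(np.abs(mis)) < mismatch_cutoff_pp),
    )
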