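"""Choosing the number of trajectory subgroups and polynomial orders.

The number of subgroups is selected by the BIC approximation to the Bayes
factor: models with 1..k_max subgroups (cubic trajectories) are fitted and
k+1 is preferred over k as long as 2*(BIC_{k+1} - BIC_k) > 10, the
conventional "very strong evidence" bound on 2 log B10.  BIC is on the
log-likelihood-minus-penalty scale (larger is better),

    BIC = loglik - (n_params / 2) * log(N),   N = number of subjects.

After selection, non-significant highest-order polynomial terms are pruned
group by group at the 5% level using Wald tests with observed-information
standard errors, refitting after each reduction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from trajspur.gbtm import (
    DegenerateSolutionError,
    GBTMFit,
    GBTMSpec,
    _beta_from_original,
    _Problem,
    fit_gbtm,
)
from trajspur.panel import LongitudinalPanel

BAYES_FACTOR_THRESHOLD = 10.0  # on 2*delta(BIC), i.e. ~2 log B10


def bic(fit: GBTMFit, N: int) -> float:
    """BIC on the larger-is-better scale: loglik - (p/2) log N."""
    if N <= 0:
        raise ValueError("N must be positive")
    return float(fit.loglik - (fit.n_params / 2.0) * np.log(N))


@dataclass
class SelectionTrace:
    """Record of the model-selection path over k = 1..k_max."""

    fits: list
    bic_values: list
    decisions: list
    selected_k: int
    selected_fit: GBTMFit
    min_group_count: int
    rule: str
    threshold: float = BAYES_FACTOR_THRESHOLD
    pruning_log: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def table(self) -> str:
        """Human-readable fit-index table (k, params, loglik, BIC, 2dBIC)."""
        lines = [f"{'k':>3} {'n_params':>9} {'loglik':>12} {'BIC':>12} {'2*dBIC':>10} decision"]
        prev = None
        for k, (f, b) in enumerate(zip(self.fits, self.bic_values), start=1):
            if f is None:
                lines.append(f"{k:>3} {'-':>9} {'-':>12} {'-':>12} {'-':>10} failed")
                continue
            stat = "" if prev is None else f"{2 * (b - prev):10.2f}"
            mark = " <- selected" if k == self.selected_k else ""
            lines.append(
                f"{k:>3} {f.n_params:>9} {f.loglik:>12.2f} {b:>12.2f} {stat:>10}{mark}"
            )
            prev = b
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "threshold_on": "2*delta_BIC",
            "threshold": self.threshold,
            "bic_values": [None if b is None else float(b) for b in self.bic_values],
            "decisions": self.decisions,
            "selected_k": self.selected_k,
            "min_group_count": self.min_group_count,
            "pruning_log": self.pruning_log,
            "failures": self.failures,
            "selected_fit": self.selected_fit.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def select_num_groups(
    panel: LongitudinalPanel,
    k_max: int = 10,
    rule: str = "bayes_factor",
    seed: int = 0,
    poly_order: int = 3,
    censor_low: float = -np.inf,
    censor_high: float = np.inf,
    n_starts: int = 10,
    max_iter: int = 500,
    prune_selected: bool = True,
    alpha: float = 0.05,
    fitter=None,
) -> SelectionTrace:
    """Fit 1..k_max subgroup models and select k by ``rule``.

    rule = "bayes_factor": accept k+1 over k while 2*(BIC_{k+1}-BIC_k) > 10,
    stop at the first failure.  rule = "min_bic": pick the k maximising BIC
    (equivalently minimising BIC on the opposite sign convention).
    ``fitter`` overrides the model-fitting callable (used for LCGM selection).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if rule not in ("bayes_factor", "min_bic"):
        raise ValueError(f"unknown rule {rule!r}")
    fit_one = fitter if fitter is not None else _gbtm_fitter(
        poly_order, censor_low, censor_high, n_starts, max_iter
    )

    fits: list = []
    bics: list = []
    failures: list = []
    for k in range(1, k_max + 1):
        fit = None
        for attempt in range(2):
            try:
                fit = fit_one(panel, k, seed + 7919 * k + 104729 * attempt)
            except DegenerateSolutionError as exc:
                failures.append({"k": k, "attempt": attempt, "reason": str(exc)})
                continue
            if fit.converged:
                break
            failures.append({"k": k, "attempt": attempt, "reason": "non-convergence"})
        if fit is None:
            warnings.warn(f"no admissible fit for k={k}; skipped in the selection rule")
            fits.append(None)
            bics.append(None)
            continue
        fits.append(fit)
        bics.append(bic(fit, fit.n_subjects))

    selected_k, decisions = apply_selection_rule(bics, rule=rule)

    selected_fit = fits[selected_k - 1]
    pruning_log: list = []
    if prune_selected and fitter is None:
        selected_fit = prune_polynomials(panel, selected_fit, alpha=alpha, seed=seed)
        pruning_log = list(getattr(selected_fit, "pruning_log", []))
    min_group_count = int(selected_fit.group_counts.min())
    return SelectionTrace(
        fits=fits,
        bic_values=bics,
        decisions=decisions,
        selected_k=selected_k,
        selected_fit=selected_fit,
        min_group_count=min_group_count,
        rule=rule,
        pruning_log=pruning_log,
        failures=failures,
    )


def apply_selection_rule(
    bic_values: list, rule: str = "bayes_factor", threshold: float = BAYES_FACTOR_THRESHOLD
) -> tuple[int, list]:
    """Pure rule arithmetic on a BIC sequence for k = 1, 2, ... .

    ``bayes_factor`` walks up the sequence accepting k+1 while
    2*(BIC_{k+1} - BIC_k) > threshold and stops at the first failure;
    ``min_bic`` picks the global BIC maximum.  ``None`` entries (failed
    fits) are skipped, comparing the nearest available neighbours.
    Returns ``(selected_k, decisions)``.
    """
    available = [(k, b) for k, b in enumerate(bic_values, start=1) if b is not None]
    if not available:
        raise RuntimeError("no model could be fitted for any k")
    decisions = []
    if rule == "bayes_factor":
        selected_k = available[0][0]
        stopped = False
        for (k0, b0), (k1, b1) in zip(available, available[1:]):
            stat = 2.0 * (b1 - b0)
            accept = stat > threshold
            decisions.append(
                {"from_k": k0, "to_k": k1, "two_delta_bic": float(stat), "accept": accept}
            )
            if not stopped and accept:
                selected_k = k1
            elif not stopped:
                stopped = True
    elif rule == "min_bic":
        selected_k = max(available, key=lambda kb: kb[1])[0]
        for (k0, b0), (k1, b1) in zip(available, available[1:]):
            stat = 2.0 * (b1 - b0)
            decisions.append(
                {"from_k": k0, "to_k": k1, "two_delta_bic": float(stat), "accept": stat > 0}
            )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return selected_k, decisions


def _gbtm_fitter(poly_order, censor_low, censor_high, n_starts, max_iter):
    def fit_one(panel, k, seed):
        spec = GBTMSpec(
            n_groups=k,
            poly_order=poly_order,
            censor_low=censor_low,
            censor_high=censor_high,
            n_starts=n_starts,
            max_iter=max_iter,
        )
        return fit_gbtm(panel, spec, seed=seed)

    return fit_one


# ---------------------------------------------------------------------------
# Wald tests on polynomial coefficients
# ---------------------------------------------------------------------------


def _pack_params(fit: GBTMFit, prob: _Problem):
    """Unconstrained parameter vector: multinomial-logit weights,
    scaled-basis coefficients, log sigma."""
    betas_z = [
        _beta_from_original(b, prob.t_center, prob.t_scale)[: o + 1]
        for b, o in zip(fit.beta, fit.spec.orders)
    ]
    alpha = np.log(fit.pi[1:] / fit.pi[0]) if fit.n_groups > 1 else np.array([])
    theta = np.concatenate([alpha, *betas_z, [np.log(fit.sigma)]])
    sizes = [o + 1 for o in fit.spec.orders]
    return theta, sizes


def _loglik_fn(prob: _Problem, J: int, sizes: list[int]):
    splits = np.cumsum(sizes)[:-1]
    n_alpha = J - 1

    def f(theta):
        alpha = theta[:n_alpha]
        logits = np.concatenate([[0.0], alpha])
        pi = np.exp(logits - logsumexp(logits))
        betas = np.split(theta[n_alpha:-1], splits)
        sigma = float(np.exp(theta[-1]))
        ll = prob.loglik_matrix(list(betas), sigma)
        return float(np.sum(logsumexp(np.log(pi) + ll, axis=1)))

    return f


def _observed_information(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Negative Hessian of ``f`` at ``theta`` by central differences."""
    p = len(theta)
    H = np.empty((p, p))
    hs = h * np.maximum(1.0, np.abs(theta))
    for a in range(p):
        for b in range(a, p):
            ea = np.zeros(p)
            eb = np.zeros(p)
            ea[a] = hs[a]
            eb[b] = hs[b]
            val = (
                f(theta + ea + eb) - f(theta + ea - eb) - f(theta - ea + eb) + f(theta - ea - eb)
            ) / (4.0 * hs[a] * hs[b])
            H[a, b] = H[b, a] = val
    return -H


def coefficient_wald_tests(panel: LongitudinalPanel, fit: GBTMFit) -> list[dict]:
    """Wald z and p-value for each group's highest-order coefficient,
    using observed-information standard errors on the scaled time basis."""
    prob = _Problem(panel, fit.spec.censor_low, fit.spec.censor_high)
    theta, sizes = _pack_params(fit, prob)
    f = _loglik_fn(prob, fit.n_groups, sizes)
    info = _observed_information(f, theta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular observed information: {exc}") from exc
    diag = np.diag(cov)
    if np.any(diag[: -1] < 0):
        warnings.warn("observed information not positive definite at the ML solution")
    n_alpha = fit.n_groups - 1
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    for j, o in enumerate(fit.spec.orders):
        idx = n_alpha + offsets[j] + o  # leading coefficient of group j
        betas_z = _beta_from_original(fit.beta[j], prob.t_center, prob.t_scale)
        est = betas_z[o]
        var = diag[idx]
        se = np.sqrt(var) if var > 0 else np.nan
        z = est / se if se and np.isfinite(se) else np.inf
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        out.append({"group": j, "order": o, "estimate": float(est), "se": float(se), "z": float(z), "p": float(p)})
    return out


def prune_polynomials(
    panel: LongitudinalPanel, fit: GBTMFit, alpha: float = 0.05, seed: int = 0
) -> GBTMFit:
    """Drop non-significant highest-order polynomial terms.

    Greedy per group, from the top order down, refitting (warm-started)
    after each reduction; intercepts are never dropped.  Returns the pruned
    fit carrying a ``pruning_log`` attribute; if the observed information is
    singular, the original fit is returned unpruned with a diagnostic.
    """
    log: list = []
    current = fit
    while True:
        orders = current.spec.orders
        if all(o == 0 for o in orders):
            break
        try:
            tests = coefficient_wald_tests(panel, current)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"pruning aborted: {exc}")
            log.append({"aborted": str(exc)})
            break
        candidates = [t for t in tests if t["order"] > 0 and t["p"] >= alpha]
        if not candidates:
            break
        drop = candidates[0]  # groups processed in reported label order
        j = drop["group"]
        new_orders = list(orders)
        new_orders[j] -= 1
        log.append(
            {"group": j, "dropped_order": drop["order"], "p": drop["p"], "z": drop["z"]}
        )
        new_spec = GBTMSpec(
            n_groups=current.spec.n_groups,
            poly_order=new_orders,
            censor_low=current.spec.censor_low,
            censor_high=current.spec.censor_high,
            max_iter=current.spec.max_iter,
            tol=current.spec.tol,
            n_starts=max(2, current.spec.n_starts // 2),
        )
        warm = (current.pi, [b[: o + 1] for b, o in zip(current.beta, new_orders)], current.sigma)
        current = fit_gbtm(panel, new_spec, seed=seed, init=warm)
    current.pruning_log = log
    return current
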