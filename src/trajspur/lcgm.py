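"""Latent class growth model (LCGM) with class-specific random intercepts.

Sensitivity-analysis companion to the GBTM: each latent class keeps its
polynomial mean trajectory, but subjects within class j carry a persistent
random intercept b_i ~ N(0, tau_j^2), so a subject's series is multivariate
normal with compound-symmetric covariance

    V_j = tau_j^2 * J_t + sigma^2 * I_t        (J_t = all-ones matrix).

This relaxes the GBTM's within-class homogeneity assumption (GBTM is the
tau_j = 0 special case) at the price of a harder marginal likelihood;
non-convergence is reported explicitly rather than raised, mirroring how
such failures are reported in applied trajectory analyses.

Estimation is by (generalized) EM: E-step responsibilities as usual; the
M-step profiles each class's GLS coefficients and improves (tau_1..J,
sigma) by bounded quasi-Newton steps on the expected complete-data
log-likelihood, using the rank-one Woodbury/determinant identities for the
compound-symmetric inverse and determinant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from trajspur.gbtm import GBTMSpec, _beta_to_original, _initial_partition, _Problem
from trajspur.panel import LongitudinalPanel

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LCGMFit:
    """Fitted LCGM; ``tau`` holds per-class random-intercept SDs."""

    spec: GBTMSpec
    pi: np.ndarray
    beta: list[np.ndarray]
    tau: np.ndarray
    sigma: float
    loglik: float
    n_params: int
    bic: float
    posterior: np.ndarray
    assignments: np.ndarray
    group_counts: np.ndarray
    converged: bool
    n_em_iterations: int
    n_subjects: int
    failure_reason: str | None = None
    _scaled: dict = field(default=None, repr=False)

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    def mean_curves(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return np.stack([np.polynomial.polynomial.polyval(times, b) for b in self.beta])

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "poly_order": self.spec.orders,
            "pi": self.pi.tolist(),
            "beta": [b.tolist() for b in self.beta],
            "tau": self.tau.tolist(),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "group_counts": self.group_counts.tolist(),
            "converged": bool(self.converged),
            "failure_reason": self.failure_reason,
            "n_subjects": self.n_subjects,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def lcgm_class_loglik(subject_y, subject_times, beta_j, tau_j: float, sigma: float) -> float:
    """Marginal log-density of one subject's series under class j.

    Multivariate normal with mean = polynomial curve (original-scale
    ``beta_j``) and covariance tau_j^2 J + sigma^2 I, evaluated through the
    rank-one identities: no dense t x t solve is formed.
    """
    if tau_j < 0:
        raise ValueError("tau_j must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    yy = np.asarray(subject_y, dtype=float)
    tt = np.asarray(subject_times, dtype=float)
    t = len(yy)
    mu = np.polynomial.polynomial.polyval(tt, np.asarray(beta_j, dtype=float))
    r = yy - mu
    s2 = sigma * sigma
    t2 = tau_j * tau_j
    logdet = (t - 1) * np.log(s2) + np.log(s2 + t * t2)
    c = t2 / (s2 + t * t2)
    quad = (r @ r - c * r.sum() ** 2) / s2
    return float(-0.5 * (t * _LOG2PI + logdet + quad))


# ---------------------------------------------------------------------------
# vectorised likelihood pieces (balanced panels)
# ---------------------------------------------------------------------------


def _class_loglik_matrix(prob: _Problem, betas_z, tau, sigma) -> np.ndarray:
    J = len(betas_z)
    out = np.empty((prob.N, J))
    s2 = sigma * sigma
    if prob.balanced:
        t = len(prob.z)
        for j in range(J):
            mu = np.polynomial.polynomial.polyval(prob.z, betas_z[j])
            R = prob.Y - mu
            t2 = tau[j] * tau[j]
            logdet = (t - 1) * np.log(s2) + np.log(s2 + t * t2)
            c = t2 / (s2 + t * t2)
            quad = (np.sum(R * R, axis=1) - c * R.sum(axis=1) ** 2) / s2
            out[:, j] = -0.5 * (t * _LOG2PI + logdet + quad)
    else:
        for i, (z_i, (tt, yy)) in enumerate(zip(prob.z_list, prob.subjects)):
            t = len(yy)
            for j in range(J):
                mu = np.polynomial.polynomial.polyval(z_i, betas_z[j])
                r = yy - mu
                t2 = tau[j] * tau[j]
                logdet = (t - 1) * np.log(s2) + np.log(s2 + t * t2)
                c = t2 / (s2 + t * t2)
                quad = (r @ r - c * r.sum() ** 2) / s2
                out[i, j] = -0.5 * (t * _LOG2PI + logdet + quad)
    return out


def _mstep_variances(prob, post, orders, tau0, sigma0, tau_max):
    """Improve (tau_1..J, sigma) on the expected complete loglik, with each
    class's GLS coefficients profiled out.  Balanced panels only."""
    J = post.shape[1]
    t = len(prob.z)
    W = post.sum(axis=0)
    M = post.T @ prob.Y  # (J, t) weighted sums of subject vectors
    E = [np.einsum("i,it,is->ts", post[:, j], prob.Y, prob.Y) for j in range(J)]
    Xs = [prob.design(o) for o in orders]
    ones = np.ones(t)

    def profile(theta):
        tau = theta[:J]
        sigma = max(theta[J], 1e-6)
        s2 = sigma * sigma
        total = 0.0
        betas = []
        for j in range(J):
            t2 = tau[j] * tau[j]
            c = t2 / (s2 + t * t2)
            X = Xs[j]
            # A = (I - c 11^T)/s2 applied through the rank-one structure
            AX = (X - c * np.outer(ones, ones @ X)) / s2
            XtAX = X.T @ AX
            rhs = AX.T @ (M[j] / max(W[j], 1e-300))
            beta = np.linalg.solve(XtAX, rhs)
            mu = X @ beta
            Amu = (mu - c * ones * (ones @ mu)) / s2
            AE = (E[j] - c * np.outer(ones, ones @ E[j])) / s2
            quad = (
                np.trace(AE)
                - 2.0 * (M[j] @ Amu)
                + W[j] * (mu @ Amu)
            )
            logdet = (t - 1) * np.log(s2) + np.log(s2 + t * t2)
            total += -0.5 * (W[j] * (t * _LOG2PI + logdet) + quad)
            betas.append(beta)
        return total, betas

    def neg(theta):
        return -profile(theta)[0]

    theta0 = np.concatenate([tau0, [sigma0]])
    bounds = [(0.0, tau_max)] * J + [(1e-6, None)]
    # generalized EM: a few bounded quasi-Newton steps that improve Q suffice
    res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 6})
    theta = res.x if res.fun <= neg(theta0) else theta0
    q, betas = profile(theta)
    return list(theta[:J]), float(max(theta[J], 1e-6)), betas


def fit_lcgm(
    panel: LongitudinalPanel,
    spec: GBTMSpec,
    seed: int = 0,
    tau_fixed: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> LCGMFit:
    """Fit an LCGM by multi-start generalized EM.

    Never raises on failure to converge: the returned fit carries
    ``converged=False`` and a ``failure_reason`` so selection pipelines can
    report the failure.  ``tau_fixed`` pins the random-intercept SDs (all
    zeros reproduces the GBTM likelihood, used as a nesting check).
    """
    if panel.n_subjects < spec.n_groups:
        raise ValueError("need at least as many subjects as classes")
    prob = _Problem(panel, -np.inf, np.inf)
    if not prob.balanced:
        raise NotImplementedError("LCGM fitting currently requires a balanced panel")
    orders = spec.orders
    J = spec.n_groups
    data_sd = float(prob.Y.std())
    tau_max = 10.0 * data_sd

    starts = []
    labels0 = _initial_partition(prob, J, None)
    starts.append(labels0)
    rng = np.random.default_rng(seed)
    for _ in range(spec.n_starts - 1):
        starts.append(_initial_partition(prob, J, rng))

    best = None
    reasons = []
    for labels in starts:
        post = np.zeros((prob.N, J))
        post[np.arange(prob.N), labels] = 1.0
        post = 0.95 * post + 0.05 / J
        betas, sigma = prob.wls_mstep(post, orders)
        pi = post.mean(axis=0)
        tau = list(np.full(J, 0.5 * sigma)) if tau_fixed is None else list(tau_fixed)
        sigma = max(sigma, 1e-3)
        loglik = -np.inf
        converged = False
        reason = None
        for it in range(max_iter):
            ll = _class_loglik_matrix(prob, betas, tau, sigma)
            lp = np.log(np.maximum(pi, 1e-300)) + ll
            norm = logsumexp(lp, axis=1)
            new_loglik = float(norm.sum())
            post = np.exp(lp - norm[:, None])
            if new_loglik - loglik < tol and it > 0:
                if new_loglik - loglik < -1e-6:
                    reason = "log-likelihood oscillation beyond tolerance"
                else:
                    converged = True
                loglik = max(loglik, new_loglik)
                break
            loglik = new_loglik
            mass = post.sum(axis=0)
            if np.any(mass < 1.0):
                reason = "degenerate class (posterior mass < 1 subject)"
                break
            pi = mass / prob.N
            if tau_fixed is None:
                tau, sigma, betas = _mstep_variances(prob, post, orders, tau, sigma, tau_max)
                if any(tt >= tau_max - 1e-9 for tt in tau):
                    reason = "random-intercept SD diverged"
                    break
            else:
                # tau pinned: only beta, sigma and pi move; profile with fixed tau
                _, sigma, betas = _profile_fixed_tau(prob, post, orders, tau, sigma)
        else:
            reason = f"max_iter ({max_iter}) reached"
        reasons.append(reason)
        cand = {
            "pi": pi, "betas": betas, "tau": np.array(tau), "sigma": sigma,
            "loglik": loglik, "converged": converged, "reason": reason, "n_iter": it + 1,
        }
        if reason == "degenerate class (posterior mass < 1 subject)":
            continue
        if best is None or cand["loglik"] > best["loglik"] or (
            cand["converged"] and not best["converged"] and cand["loglik"] >= best["loglik"] - 1e-6
        ):
            best = cand
    if best is None:
        best = {
            "pi": np.full(J, 1.0 / J), "betas": [np.zeros(o + 1) for o in orders],
            "tau": np.zeros(J), "sigma": data_sd, "loglik": np.nan,
            "converged": False, "reason": "all starts degenerate", "n_iter": 0,
        }
    if not best["converged"]:
        warnings.warn(f"LCGM did not converge: {best['reason']}")

    order = np.argsort(
        [np.polynomial.polynomial.polyval(prob.z[0], b) for b in best["betas"]], kind="stable"
    )
    pi = best["pi"][order]
    betas_z = [best["betas"][k] for k in order]
    tau = best["tau"][order]
    sigma = best["sigma"]
    ll = _class_loglik_matrix(prob, betas_z, tau, sigma)
    lp = np.log(np.maximum(pi, 1e-300)) + ll
    norm = logsumexp(lp, axis=1)
    loglik = float(norm.sum()) if np.isfinite(best["loglik"]) else float("nan")
    posterior = np.exp(lp - norm[:, None])
    assignments = np.argmax(posterior, axis=1)
    counts = np.bincount(assignments, minlength=J)
    n_params = sum(o + 1 for o in orders) + J + 1 + (J - 1)
    bic_val = loglik - (n_params / 2.0) * np.log(prob.N)
    return LCGMFit(
        spec=spec,
        pi=pi,
        beta=[_beta_to_original(b, prob.t_center, prob.t_scale) for b in betas_z],
        tau=tau,
        sigma=sigma,
        loglik=loglik,
        n_params=n_params,
        bic=float(bic_val),
        posterior=posterior,
        assignments=assignments,
        group_counts=counts,
        converged=bool(best["converged"]),
        n_em_iterations=int(best["n_iter"]),
        n_subjects=prob.N,
        failure_reason=best["reason"],
        _scaled={"t_center": prob.t_center, "t_scale": prob.t_scale, "betas_z": betas_z},
    )


def _profile_fixed_tau(prob, post, orders, tau, sigma0):
    """M-step with pinned tau: GLS betas and a 1-D sigma improvement."""
    J = post.shape[1]
    t = len(prob.z)
    W = post.sum(axis=0)
    M = post.T @ prob.Y
    E = [np.einsum("i,it,is->ts", post[:, j], prob.Y, prob.Y) for j in range(J)]
    Xs = [prob.design(o) for o in orders]
    ones = np.ones(t)

    def q_of(sigma):
        s2 = sigma * sigma
        total = 0.0
        betas = []
        for j in range(J):
            t2 = tau[j] * tau[j]
            c = t2 / (s2 + t * t2)
            X = Xs[j]
            AX = (X - c * np.outer(ones, ones @ X)) / s2
            beta = np.linalg.solve(X.T @ AX, AX.T @ (M[j] / max(W[j], 1e-300)))
            mu = X @ beta
            Amu = (mu - c * ones * (ones @ mu)) / s2
            AE = (E[j] - c * np.outer(ones, ones @ E[j])) / s2
            quad = np.trace(AE) - 2.0 * (M[j] @ Amu) + W[j] * (mu @ Amu)
            logdet = (t - 1) * np.log(s2) + np.log(s2 + t * t2)
            total += -0.5 * (W[j] * (t * _LOG2PI + logdet) + quad)
            betas.append(beta)
        return total, betas

    res = optimize.minimize_scalar(
        lambda s: -q_of(max(s, 1e-6))[0],
        bounds=(max(1e-6, 0.2 * sigma0), 5.0 * sigma0),
        method="bounded",
    )
    sigma = float(max(res.x, 1e-6)) if res.fun <= -q_of(sigma0)[0] else sigma0
    q, betas = q_of(sigma)
    return q, sigma, betas


def lcgm_fitter(poly_order: int = 3, n_starts: int = 5, max_iter: int = 300):
    """Adapter so ``selection.select_num_groups`` can drive LCGM fits."""
    def fit_one(panel, k, seed):
        spec = GBTMSpec(n_groups=k, poly_order=poly_order, n_starts=n_starts)
        return fit_lcgm(panel, spec, seed=seed, max_iter=max_iter)

    return fit_one
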