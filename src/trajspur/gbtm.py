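"""Group-based trajectory model: finite mixture of censored-normal
polynomial trajectories with a shared residual SD.

The model for subject ``i`` with observed series ``Y_i = (y_i1..y_it)``:

    P(Y_i) = sum_j pi_j * prod_t f_cnorm(y_it | poly_j(time_t), sigma)

where ``poly_j`` is a polynomial of order up to 3 specific to latent
subgroup ``j`` and ``sigma`` is one residual SD shared across subgroups and
occasions — the defining (and deliberately restrictive) GBTM assumption.
Estimation is by EM with multiple starts; posteriors follow from Bayes'
rule and subjects are assigned by the maximum-probability rule.

Polynomials are evaluated on centred-and-scaled time internally for
numerical stability; reported coefficients are on the original time scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from trajspur.panel import LongitudinalPanel

_LOG2PI = float(np.log(2.0 * np.pi))
_SIGMA_FLOOR = 1e-8


class DegenerateSolutionError(RuntimeError):
    """Raised when every EM start collapses a subgroup to (near-)zero mass."""


@dataclass
class GBTMSpec:
    """Model specification: number of subgroups, per-group polynomial
    orders (cubic by default), censoring bounds and optimizer controls."""

    n_groups: int
    poly_order: int | list[int] = 3
    censor_low: float = -np.inf
    censor_high: float = np.inf
    max_iter: int = 500
    tol: float = 1e-6
    n_starts: int = 10

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not self.censor_low < self.censor_high:
            raise ValueError("censor_low must be < censor_high")
        orders = self.orders
        if any(o not in (0, 1, 2, 3) for o in orders):
            raise ValueError("poly_order entries must be in {0,1,2,3}")

    @property
    def orders(self) -> list[int]:
        if isinstance(self.poly_order, int):
            return [self.poly_order] * self.n_groups
        if len(self.poly_order) != self.n_groups:
            raise ValueError("per-group poly_order must have length n_groups")
        return list(self.poly_order)

    @property
    def n_params(self) -> int:
        """Free parameters: coefficients + shared sigma + (J-1) weights."""
        return sum(o + 1 for o in self.orders) + 1 + (self.n_groups - 1)


@dataclass
class GBTMFit:
    """Fitted GBTM.  ``beta`` holds per-group ascending polynomial
    coefficients on the original time scale; ``posterior`` is the N x J
    matrix of membership probabilities in subject-id order."""

    spec: GBTMSpec
    pi: np.ndarray
    beta: list[np.ndarray]
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
    loglik_history: np.ndarray = field(default=None, repr=False)
    _scaled: dict = field(default=None, repr=False)

    @property
    def n_groups(self) -> int:
        return self.spec.n_groups

    def mean_curves(self, times: np.ndarray) -> np.ndarray:
        """Fitted mean trajectories evaluated at ``times``, shape (J, len(times))."""
        times = np.asarray(times, dtype=float)
        return np.stack([np.polynomial.polynomial.polyval(times, b) for b in self.beta])

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "poly_order": self.spec.orders,
            "pi": self.pi.tolist(),
            "beta": [b.tolist() for b in self.beta],
            "sigma": self.sigma,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "group_counts": self.group_counts.tolist(),
            "converged": bool(self.converged),
            "n_em_iterations": self.n_em_iterations,
            "n_subjects": self.n_subjects,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# data preprocessing
# ---------------------------------------------------------------------------


class _Problem:
    """Dense, likelihood-ready view of a panel."""

    def __init__(self, panel: LongitudinalPanel, censor_low: float, censor_high: float):
        self.censor_low = censor_low
        self.censor_high = censor_high
        self.finite_bounds = np.isfinite(censor_low) or np.isfinite(censor_high)
        bal = panel.balanced()
        all_times = panel.data["time"].to_numpy()
        self.t_center = float(all_times.mean())
        spread = float(all_times.std())
        self.t_scale = spread if spread > 0 else 1.0
        if bal is not None:
            self.balanced = True
            self.Y, self.times = bal
            self.N = self.Y.shape[0]
            self.z = (self.times - self.t_center) / self.t_scale
            self._rowsq = np.einsum("it,it->i", self.Y, self.Y)
            self._design_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            if self.finite_bounds:
                self.low_mask = self.Y <= censor_low
                self.high_mask = self.Y >= censor_high
        else:
            self.balanced = False
            self.subjects = panel.by_subject()
            self.N = len(self.subjects)
            self.z_list = [(tt - self.t_center) / self.t_scale for tt, _ in self.subjects]
        self.n_obs = len(all_times)

    def design(self, order: int) -> np.ndarray:
        return self._design_with_pinv(order)[0]

    def _design_with_pinv(self, order: int) -> tuple[np.ndarray, np.ndarray]:
        cached = self._design_cache.get(order)
        if cached is None:
            X = np.vander(self.z, order + 1, increasing=True)
            cached = (X, np.linalg.pinv(X))
            self._design_cache[order] = cached
        return cached

    def design_for(self, z: np.ndarray, order: int) -> np.ndarray:
        return np.vander(z, order + 1, increasing=True)

    # -- log-likelihood matrix -------------------------------------------
    def loglik_matrix(self, betas_z: list[np.ndarray], sigma: float) -> np.ndarray:
        """N x J matrix of per-subject conditional log-likelihoods."""
        J = len(betas_z)
        out = np.empty((self.N, J))
        if self.balanced:
            if not self.finite_bounds:
                # ||y_i - mu_j||^2 = ||y_i||^2 - 2 y_i.mu_j + ||mu_j||^2, one GEMM
                MU = np.stack(
                    [np.polynomial.polynomial.polyval(self.z, b) for b in betas_z]
                )
                sq = self._rowsq[:, None] - 2.0 * (self.Y @ MU.T) + np.einsum(
                    "jt,jt->j", MU, MU
                )
                return -0.5 * sq / (sigma * sigma) - len(self.z) * (
                    np.log(sigma) + 0.5 * _LOG2PI
                )
            for j, b in enumerate(betas_z):
                mu = np.polynomial.polynomial.polyval(self.z, b)
                cell = stats.norm.logpdf(self.Y, loc=mu, scale=sigma)
                if np.isfinite(self.censor_low):
                    cell = np.where(
                        self.low_mask,
                        stats.norm.logcdf(self.censor_low, loc=mu, scale=sigma),
                        cell,
                    )
                if np.isfinite(self.censor_high):
                    cell = np.where(
                        self.high_mask,
                        stats.norm.logsf(self.censor_high, loc=mu, scale=sigma),
                        cell,
                    )
                out[:, j] = cell.sum(axis=1)
        else:
            for i, (z_i, (tt, yy)) in enumerate(zip(self.z_list, self.subjects)):
                for j, b in enumerate(betas_z):
                    mu = np.polynomial.polynomial.polyval(z_i, b)
                    if not self.finite_bounds:
                        r = yy - mu
                        out[i, j] = (
                            -0.5 * np.sum(r * r) / (sigma * sigma)
                            - len(yy) * (np.log(sigma) + 0.5 * _LOG2PI)
                        )
                    else:
                        cell = stats.norm.logpdf(yy, loc=mu, scale=sigma)
                        lowm = yy <= self.censor_low
                        highm = yy >= self.censor_high
                        if np.isfinite(self.censor_low) and lowm.any():
                            cell[lowm] = stats.norm.logcdf(
                                self.censor_low, loc=mu[lowm], scale=sigma
                            )
                        if np.isfinite(self.censor_high) and highm.any():
                            cell[highm] = stats.norm.logsf(
                                self.censor_high, loc=mu[highm], scale=sigma
                            )
                        out[i, j] = cell.sum()
        return out

    # -- weighted least squares M-step (infinite bounds) -----------------
    def wls_mstep(self, post: np.ndarray, orders: list[int]) -> tuple[list[np.ndarray], float]:
        J = post.shape[1]
        betas = []
        sse = 0.0
        if self.balanced:
            w = post.sum(axis=0)  # group weights (subject-equivalents)
            Ybar = (post.T @ self.Y) / np.maximum(w, 1e-300)[:, None]  # (J, t)
            qw = post.T @ self._rowsq  # sum_i p_ij ||y_i||^2
            for j in range(J):
                X, pinv = self._design_with_pinv(orders[j])
                beta = pinv @ Ybar[j]
                mu = X @ beta
                # sum_i p_ij ||y_i - mu_j||^2 via sufficient statistics
                sse += qw[j] - 2.0 * w[j] * (Ybar[j] @ mu) + w[j] * (mu @ mu)
                betas.append(beta)
            sigma2 = max(sse, 0.0) / self.n_obs
        else:
            for j in range(J):
                XtX = 0.0
                Xty = 0.0
                for i, (z_i, (tt, yy)) in enumerate(zip(self.z_list, self.subjects)):
                    X = self.design_for(z_i, orders[j])
                    XtX = XtX + post[i, j] * (X.T @ X)
                    Xty = Xty + post[i, j] * (X.T @ yy)
                beta = np.linalg.lstsq(XtX, Xty, rcond=None)[0]
                betas.append(beta)
            for i, (z_i, (tt, yy)) in enumerate(zip(self.z_list, self.subjects)):
                for j in range(J):
                    mu = np.polynomial.polynomial.polyval(z_i, betas[j])
                    sse += post[i, j] * np.sum((yy - mu) ** 2)
            sigma2 = sse / self.n_obs
        return betas, float(np.sqrt(max(sigma2, _SIGMA_FLOOR**2)))

    # -- censored M-step (finite bounds): numeric ------------------------
    def censored_mstep(
        self, post: np.ndarray, orders: list[int], betas0: list[np.ndarray], sigma0: float
    ) -> tuple[list[np.ndarray], float]:
        sizes = [o + 1 for o in orders]
        splits = np.cumsum(sizes)[:-1]

        def unpack(theta):
            bs = np.split(theta[:-1], splits)
            return list(bs), float(np.exp(theta[-1]))

        def negq(theta):
            bs, sig = unpack(theta)
            ll = self.loglik_matrix(bs, max(sig, _SIGMA_FLOOR))
            return -float(np.sum(post * ll))

        theta0 = np.concatenate([np.concatenate(betas0), [np.log(sigma0)]])
        res = optimize.minimize(negq, theta0, method="L-BFGS-B", options={"maxiter": 50})
        theta = res.x if res.fun <= negq(theta0) else theta0
        bs, sig = unpack(theta)
        return bs, max(sig, _SIGMA_FLOOR)


def _beta_to_original(beta_z: np.ndarray, center: float, scale: float) -> np.ndarray:
    """Re-express a polynomial in z = (t - center)/scale as a polynomial in t."""
    P = np.polynomial.Polynomial
    p = P(beta_z)(P([-center / scale, 1.0 / scale]))
    out = np.zeros(len(beta_z))
    out[: len(p.coef)] = p.coef
    return out


def _beta_from_original(beta: np.ndarray, center: float, scale: float) -> np.ndarray:
    P = np.polynomial.Polynomial
    p = P(beta)(P([center, scale]))
    out = np.zeros(len(beta))
    out[: len(p.coef)] = p.coef
    return out


# ---------------------------------------------------------------------------
# public likelihood operations
# ---------------------------------------------------------------------------


def group_conditional_loglik(
    subject_y,
    subject_times,
    beta_j,
    sigma: float,
    censor_low: float = -np.inf,
    censor_high: float = np.inf,
) -> float:
    """Conditional log-likelihood of one subject's series given membership
    in the subgroup with (original-scale) coefficients ``beta_j``."""
    from trajspur.families import CensoredNormalFamily, cnorm_logdensity

    yy = np.asarray(subject_y, dtype=float)
    tt = np.asarray(subject_times, dtype=float)
    if yy.shape != tt.shape:
        raise ValueError("subject_y and subject_times must have equal length")
    mu = np.polynomial.polynomial.polyval(tt, np.asarray(beta_j, dtype=float))
    total = 0.0
    for y_val, m in zip(yy, mu):
        total += cnorm_logdensity(
            float(y_val), CensoredNormalFamily(float(m), sigma, censor_low, censor_high)
        )
    return float(total)


def _fit_loglik_matrix(panel: LongitudinalPanel, fit: GBTMFit) -> np.ndarray:
    prob = _Problem(panel, fit.spec.censor_low, fit.spec.censor_high)
    betas_z = [_beta_from_original(b, prob.t_center, prob.t_scale) for b in fit.beta]
    return prob.loglik_matrix(betas_z, fit.sigma)


def mixture_loglik(panel: LongitudinalPanel, fit: GBTMFit) -> float:
    """Observed-data log-likelihood sum_i log sum_j pi_j P^j(Y_i)."""
    if panel.n_subjects == 0:
        raise ValueError("empty panel")
    ll = _fit_loglik_matrix(panel, fit)
    return float(np.sum(logsumexp(np.log(fit.pi) + ll, axis=1)))


def posteriors(fit: GBTMFit, panel: LongitudinalPanel) -> np.ndarray:
    """Posterior membership probabilities p_ij by Bayes' rule; rows sum to 1."""
    ll = _fit_loglik_matrix(panel, fit)
    lp = np.log(fit.pi) + ll
    lp -= logsumexp(lp, axis=1, keepdims=True)
    return np.exp(lp)


def assign(posterior: np.ndarray) -> np.ndarray:
    """Maximum-probability assignment; ties go to the lowest group index."""
    post = np.asarray(posterior)
    return np.argmax(post, axis=1)  # np.argmax returns the first (lowest) maximiser


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def _logsumexp_rows(lp: np.ndarray) -> np.ndarray:
    m = np.max(lp, axis=1)
    return m + np.log(np.einsum("ij->i", np.exp(lp - m[:, None])))


def _initial_partition(prob: _Problem, J: int, rng: np.random.Generator | None) -> np.ndarray:
    """Hard initial grouping: quantiles of subject mean y (rng=None) or a
    random partition."""
    if prob.balanced:
        means = prob.Y.mean(axis=1)
    else:
        means = np.array([yy.mean() for _, yy in prob.subjects])
    if rng is None:
        ranks = np.argsort(np.argsort(means, kind="stable"), kind="stable")
        return (ranks * J) // prob.N
    labels = rng.integers(0, J, size=prob.N)
    # ensure every group non-empty
    for j in range(J):
        if not np.any(labels == j):
            labels[rng.integers(0, prob.N)] = j
    return labels


def _params_from_partition(
    prob: _Problem, labels: np.ndarray, orders: list[int]
) -> tuple[np.ndarray, list[np.ndarray], float]:
    J = len(orders)
    post = np.zeros((prob.N, J))
    post[np.arange(prob.N), labels] = 1.0
    # soften slightly so no group starts empty-handed
    post = 0.95 * post + 0.05 / J
    betas, sigma = prob.wls_mstep(post, orders)
    pi = post.mean(axis=0)
    return pi, betas, max(sigma, 1e-3)


def _run_em(
    prob: _Problem,
    spec: GBTMSpec,
    pi: np.ndarray,
    betas: list[np.ndarray],
    sigma: float,
) -> dict:
    orders = spec.orders
    history = []
    loglik = -np.inf
    converged = False
    degenerate = False
    post = None
    for it in range(spec.max_iter):
        ll = prob.loglik_matrix(betas, sigma)
        lp = np.log(np.maximum(pi, 1e-300)) + ll
        norm = _logsumexp_rows(lp)
        new_loglik = float(norm.sum())
        post = np.exp(lp - norm[:, None])
        history.append(new_loglik)
        if new_loglik - loglik < spec.tol and it > 0:
            converged = True
            loglik = max(loglik, new_loglik)
            break
        loglik = new_loglik
        mass = post.sum(axis=0)
        if np.any(mass < 1.0):
            degenerate = True
            break
        pi = mass / prob.N
        if prob.finite_bounds:
            betas, sigma = prob.censored_mstep(post, orders, betas, sigma)
        else:
            betas, sigma = prob.wls_mstep(post, orders)
    return {
        "pi": pi,
        "betas": betas,
        "sigma": sigma,
        "loglik": loglik,
        "posterior": post,
        "converged": converged,
        "degenerate": degenerate,
        "n_iter": len(history),
        "history": np.array(history),
    }


def fit_gbtm(
    panel: LongitudinalPanel,
    spec: GBTMSpec,
    seed: int = 0,
    init: tuple | None = None,
) -> GBTMFit:
    """Fit a GBTM by multi-start EM.

    ``init``, when given, is a warm start ``(pi, beta_original, sigma)``
    run as a single additional start (used by polynomial pruning).
    """
    if panel.n_subjects < spec.n_groups:
        raise ValueError("need at least as many subjects as groups")
    prob = _Problem(panel, spec.censor_low, spec.censor_high)
    orders = spec.orders
    J = spec.n_groups

    starts = []
    if init is not None:
        pi0, beta0, sig0 = init
        betas_z = [
            _beta_from_original(np.asarray(b), prob.t_center, prob.t_scale)[: o + 1]
            for b, o in zip(beta0, orders)
        ]
        starts.append((np.asarray(pi0, dtype=float), betas_z, float(sig0)))
    n_random = spec.n_starts if init is not None else spec.n_starts - 1
    labels0 = _initial_partition(prob, J, None)
    starts.append(_params_from_partition(prob, labels0, orders))
    rng = np.random.default_rng(seed)
    for _ in range(max(n_random, 0)):
        labels = _initial_partition(prob, J, rng)
        starts.append(_params_from_partition(prob, labels, orders))

    best = None
    n_degenerate = 0
    for pi0, betas0, sig0 in starts:
        res = _run_em(prob, spec, np.array(pi0), [np.array(b) for b in betas0], sig0)
        if res["degenerate"]:
            n_degenerate += 1
            continue
        if best is None or res["loglik"] > best["loglik"]:
            best = res
    if best is None:
        # every start collapsed: retry with fresh random partitions
        for _ in range(spec.n_starts):
            labels = _initial_partition(prob, J, rng)
            pi0, betas0, sig0 = _params_from_partition(prob, labels, orders)
            res = _run_em(prob, spec, pi0, betas0, sig0)
            if not res["degenerate"]:
                best = res
                break
        if best is None:
            raise DegenerateSolutionError(
                f"all EM starts produced a degenerate subgroup (J={J})"
            )
    if not best["converged"]:
        warnings.warn(f"EM did not converge in {spec.max_iter} iterations (J={J})")

    # order groups by fitted mean at the first occasion for reproducible labels
    if prob.balanced:
        z_first = prob.z[0]
    else:
        z_first = min(z.min() for z in prob.z_list)
    first_means = [np.polynomial.polynomial.polyval(z_first, b) for b in best["betas"]]
    order = np.argsort(first_means, kind="stable")
    pi = best["pi"][order]
    betas_z = [best["betas"][k] for k in order]
    sigma = best["sigma"]
    permuted_orders = [orders[k] for k in order]
    if permuted_orders != orders:
        spec = replace(spec, poly_order=permuted_orders)

    ll = prob.loglik_matrix(betas_z, sigma)
    lp = np.log(pi) + ll
    norm = logsumexp(lp, axis=1)
    loglik = float(norm.sum())
    posterior = np.exp(lp - norm[:, None])
    assignments = assign(posterior)
    counts = np.bincount(assignments, minlength=J)

    beta_orig = [
        _beta_to_original(b, prob.t_center, prob.t_scale) for b in betas_z
    ]
    n_params = spec.n_params
    bic_val = loglik - (n_params / 2.0) * np.log(prob.N)
    return GBTMFit(
        spec=spec,
        pi=pi,
        beta=beta_orig,
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
        loglik_history=best["history"],
        _scaled={
            "t_center": prob.t_center,
            "t_scale": prob.t_scale,
            "betas_z": betas_z,
        },
    )
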