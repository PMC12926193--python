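"""Random-intercept generalized linear mixed models (Poisson, logistic).

This is the estimation engine behind single-cell Poisson mixed-effects
(sc-PME) caQTL mapping and the mixed-effects logistic topic-phenotype test.
The model is

    g(E[y_i]) = offset_i + x_i' beta + sum_f u_{f, group_f(i)},
    u_f ~ N(0, sigma_f^2 I)

with one or more crossed random-intercept factors (donor, library). Two
estimation modes are provided:

``laplace``
    Variance components maximize the Laplace approximation of the marginal
    log-likelihood (Nelder-Mead over log sigma); fixed and random effects
    solve the penalized IRLS (PIRLS) system jointly at each evaluation.

``pql``
    A fast mode in the spirit of lme4's zero-quadrature setting: joint
    PIRLS for (beta, u) with variance components updated by EM-type steps
    sigma_f^2 <- mean_d(u_d^2 + Var(u_d | y)).

Wald standard errors are conditional on the estimated variance components,
as in standard GLMM software. Random-effect dimensionality is assumed small
(tens of donors and libraries), so the mixed-model equations are solved
densely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special

__all__ = ["GlmmResult", "fit_glmm"]

_SIGMA_FLOOR = 1e-4  # effects SD below this is treated as pinned to zero
_LOG_SIGMA_BOUNDS = (-7.0, 2.5)


@dataclass
class GlmmResult:
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma: np.ndarray  # one SD per random-effect factor
    u: list[np.ndarray] = field(repr=False, default_factory=list)
    loglik: float = np.nan
    converged: bool = False
    flags: dict = field(default_factory=dict)
    eta: np.ndarray | None = field(repr=False, default=None)
    n_iter: int = 0


def _family_funcs(family: str):
    if family == "poisson":
        def mu_of(eta):
            return np.exp(np.clip(eta, -300, 30))

        def weight(mu):
            return np.maximum(mu, 1e-12)

        def loglik(y, eta, mu):
            return float(np.sum(y * eta - mu) - _poisson_const(y))

        return mu_of, weight, loglik
    if family == "binomial":
        def mu_of(eta):
            return special.expit(eta)

        def weight(mu):
            return np.maximum(mu * (1.0 - mu), 1e-12)

        def loglik(y, eta, mu):
            # Bernoulli log-likelihood, numerically stable
            return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

        return mu_of, weight, loglik
    raise ValueError(f"unknown family {family!r}")


def _poisson_const(y):
    return float(special.gammaln(y + 1.0).sum())


def _assemble(X, W, z, codes, n_levels, inv_var):
    """Build and solve the mixed-model normal equations.

    Returns (solution, cho_factor, system_matrix). System layout is
    [fixed | factor 0 levels | factor 1 levels | ...].
    """
    n, p = X.shape
    q = int(sum(n_levels))
    dim = p + q
    A = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    WX = W[:, None] * X
    A[:p, :p] = X.T @ WX
    Wz = W * z
    rhs[:p] = X.T @ Wz
    offs = np.cumsum([p] + list(n_levels))
    for f, cf in enumerate(codes):
        s, e = offs[f], offs[f + 1]
        A[np.arange(s, e), np.arange(s, e)] = (
            np.bincount(cf, weights=W, minlength=n_levels[f]) + inv_var[f]
        )
        M = np.zeros((n_levels[f], p))
        np.add.at(M, cf, WX)
        A[:p, s:e] = M.T
        A[s:e, :p] = M
        rhs[s:e] = np.bincount(cf, weights=Wz, minlength=n_levels[f])
        for g2 in range(f + 1, len(codes)):
            s2, e2 = offs[g2], offs[g2 + 1]
            C = np.zeros((n_levels[f], n_levels[g2]))
            np.add.at(C, (cf, codes[g2]), W)
            A[s:e, s2:e2] = C
            A[s2:e2, s:e] = C.T
    try:
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        sol = linalg.cho_solve(cho, rhs, check_finite=False)
    except linalg.LinAlgError:
        # ridge fallback for numerically singular systems
        A[np.arange(dim), np.arange(dim)] += 1e-8 * (1.0 + np.abs(A.diagonal()))
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        sol = linalg.cho_solve(cho, rhs, check_finite=False)
    return sol, cho, A


def _pirls(y, X, codes, n_levels, sigmas, offset, family, eta0, tol=1e-10, max_iter=60):
    """Penalized IRLS for (beta, u) at fixed variance components."""
    mu_of, weight, loglik = _family_funcs(family)
    n, p = X.shape
    inv_var = [1.0 / max(s, _SIGMA_FLOOR) ** 2 for s in sigmas]
    eta = eta0.copy()
    sol = None
    converged = False
    pl_prev = -np.inf
    pl_flat = 0
    for it in range(max_iter):
        mu = mu_of(eta)
        W = weight(mu)
        z = (eta - offset) + (y - mu) / W
        sol, cho, A = _assemble(X, W, z, codes, n_levels, inv_var)
        eta_new = offset + X @ sol[:p]
        offs = np.cumsum([p] + list(n_levels))
        for f, cf in enumerate(codes):
            eta_new = eta_new + sol[offs[f] : offs[f + 1]][cf]
        step = eta_new - eta
        m = np.max(np.abs(step))
        if not np.isfinite(m):
            return None
        if m > 8.0:  # damp large steps to keep exp() in range
            eta = eta + step * (8.0 / m)
            continue
        eta = eta_new
        if m < tol:
            converged = True
            break
        # separation makes coefficients drift while the likelihood plateaus;
        # accept convergence once the penalized log-likelihood is flat
        mu_c = mu_of(eta)
        u_off = np.cumsum([p] + list(n_levels))
        pen = 0.0
        for f in range(len(codes)):
            uf = sol[u_off[f] : u_off[f + 1]]
            pen += 0.5 * inv_var[f] * float(uf @ uf)
        pl = loglik(y, eta, mu_c) - pen
        if abs(pl - pl_prev) < 1e-9 * (1.0 + abs(pl)):
            pl_flat += 1
            if pl_flat >= 2:
                converged = True
                break
        else:
            pl_flat = 0
        pl_prev = pl
    if sol is None:
        return None
    mu = mu_of(eta)
    W = weight(mu)
    offs = np.cumsum([p] + list(n_levels))
    u = [sol[offs[f] : offs[f + 1]] for f in range(len(codes))]
    pen = 0.5 * sum(iv * float(uf @ uf) for iv, uf in zip(inv_var, u))
    ll_cond = loglik(y, eta, mu)
    # Laplace correction: -1/2 log det(D Z'WZ + I) = -1/2 [log det S + log det D]
    q = int(sum(n_levels))
    lap = 0.0
    if q:
        S = A[len(sol) - q :, len(sol) - q :].copy()
        # S already includes D^{-1} on its diagonal
        sign, logdet_S = np.linalg.slogdet(S)
        logdet_D = -sum(
            np.log(iv) * nl for iv, nl in zip(inv_var, n_levels)
        )
        lap = -0.5 * (logdet_S + logdet_D)
    laplace_ll = ll_cond - pen + lap
    return {
        "beta": sol[: X.shape[1]],
        "u": u,
        "eta": eta,
        "W": W,
        "A": A,
        "converged": converged,
        "n_iter": it + 1,
        "laplace_ll": laplace_ll,
        "cond_ll": ll_cond,
    }


def _fixed_vcov(A, p):
    dim = A.shape[0]
    cho = linalg.cho_factor(A, lower=True, check_finite=False)
    E = np.zeros((dim, p))
    E[np.arange(p), np.arange(p)] = 1.0
    return linalg.cho_solve(cho, E, check_finite=False)[:p, :]


def _u_cond_var(A, p, n_levels):
    """Diagonal of the conditional covariance of u, per factor."""
    dim = A.shape[0]
    cho = linalg.cho_factor(A, lower=True, check_finite=False)
    E = np.eye(dim)[:, p:]
    V = linalg.cho_solve(cho, E, check_finite=False)[p:, :]
    d = np.diag(V)
    out = []
    s = 0
    for nl in n_levels:
        out.append(d[s : s + nl])
        s += nl
    return out


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[np.ndarray],
    *,
    family: str = "poisson",
    offset: np.ndarray | None = None,
    method: str = "laplace",
    sigma_init: np.ndarray | None = None,
    sigma_fixed: np.ndarray | None = None,
    max_outer: int = 25,
    inner_tol: float = 1e-10,
    eta_start: np.ndarray | None = None,
) -> GlmmResult:
    """Fit a random-intercept GLMM.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (including the intercept column).
    groups
        Integer-coded grouping factors, one array of length n per factor.
    offset
        Known additive term on the linear-predictor scale (log library size).
    method
        "laplace" (default) or "pql" (fast EM-type variance updates).
    sigma_fixed
        If given, variance components are held at these SDs and only the
        penalized IRLS solve is performed (used in windowed scans where the
        components are estimated once per peak).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    codes = [np.asarray(g) for g in groups]
    n_levels = [int(c.max()) + 1 if c.size else 0 for c in codes]
    n_factors = len(codes)
    mu_of, _, _ = _family_funcs(family)

    if eta_start is not None:
        eta0 = eta_start.copy()
    elif family == "poisson":
        eta0 = np.log(y + 0.5)
    else:
        eta0 = np.log((y + 0.5) / (1.5 - y))

    def run(sigmas, eta_init):
        return _pirls(
            y, X, codes, n_levels, sigmas, offset, family, eta_init, tol=inner_tol
        )

    flags: dict = {}

    if sigma_fixed is not None:
        sigmas = np.asarray(sigma_fixed, dtype=float)
        fit = run(sigmas, eta0)
        outer_iters = 0
        converged = fit is not None and fit["converged"]
    elif method == "pql":
        sigmas = (
            np.full(n_factors, 0.3)
            if sigma_init is None
            else np.asarray(sigma_init, dtype=float).copy()
        )
        fit = None
        converged = False
        eta_cur = eta0
        outer_iters = 0
        for outer_iters in range(1, max_outer + 1):
            fit = run(sigmas, eta_cur)
            if fit is None:
                break
            eta_cur = fit["eta"]
            vdiag = _u_cond_var(fit["A"], p, n_levels)
            new = np.array(
                [
                    np.sqrt(max(float(np.mean(uf**2 + vd)), _SIGMA_FLOOR**2))
                    for uf, vd in zip(fit["u"], vdiag)
                ]
            )
            # a component decaying to the floor counts as settled
            settled = (np.abs(new - sigmas) < 1e-3) | (new <= _SIGMA_FLOOR * 2)
            if np.all(settled):
                sigmas = new
                converged = fit["converged"]
                break
            sigmas = new
        if fit is not None and sigma_fixed is None:
            fit = run(sigmas, eta_cur)  # final solve at converged components
            converged = converged and fit is not None and fit["converged"]
    elif method == "laplace":
        s0 = (
            np.full(n_factors, 0.3)
            if sigma_init is None
            else np.asarray(sigma_init, dtype=float)
        )
        state = {"eta": eta0}

        def negll(log_s):
            s = np.exp(np.clip(log_s, *_LOG_SIGMA_BOUNDS))
            f = run(s, state["eta"])
            if f is None or not np.isfinite(f["laplace_ll"]):
                return 1e12
            state["eta"] = f["eta"]
            return -f["laplace_ll"]

        if n_factors:
            res = optimize.minimize(
                negll,
                np.log(np.maximum(s0, _SIGMA_FLOOR)),
                method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200 * n_factors},
            )
            sigmas = np.exp(np.clip(res.x, *_LOG_SIGMA_BOUNDS))
            outer_iters = int(res.nit)
        else:
            sigmas = np.array([])
            outer_iters = 0
        fit = run(sigmas, state["eta"])
        converged = fit is not None and fit["converged"]
    else:
        raise ValueError(f"unknown method {method!r}")

    if fit is None:
        return GlmmResult(
            beta=np.full(p, np.nan),
            se=np.full(p, np.nan),
            vcov=np.full((p, p), np.nan),
            sigma=np.full(n_factors, np.nan),
            converged=False,
            flags={"diverged": True},
        )

    if n_factors and np.any(np.asarray(sigmas) <= _SIGMA_FLOOR * 1.01):
        flags["variance_pinned"] = True
    vcov = _fixed_vcov(fit["A"], p)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    if not converged:
        flags["not_converged"] = True
    return GlmmResult(
        beta=fit["beta"],
        se=se,
        vcov=vcov,
        sigma=np.asarray(sigmas, dtype=float),
        u=fit["u"],
        loglik=fit["laplace_ll"],
        converged=bool(converged),
        flags=flags,
        eta=fit["eta"],
        n_iter=fit["n_iter"],
    )
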