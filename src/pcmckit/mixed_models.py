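"""Mixed models for consolation/reconciliation occurrence and dyadic tendencies.

Binomial-logit mixed models with independent Gaussian random intercepts
are fitted by maximum likelihood under a Laplace approximation: for fixed
variance components the fixed effects and random modes are found jointly
by penalised iteratively reweighted least squares, the marginal
log-likelihood is approximated by the Laplace formula, and the variance
components are profiled out by a derivative-free outer optimisation.
This is the same approximation lme4's ``glmer`` uses at ``nAGQ = 1``.
Gaussian responses (per-dyad contact tendency, consolation index) are
fitted through :mod:`statsmodels`' ``MixedLM`` with crossed random
intercepts expressed as variance components.

Model selection enumerates all covariate subsets (plus any explicitly
listed two-way interactions whose main effects are present), drops
candidate models containing collinear predictor pairs (|r| > 0.7), ranks
converged fits by AIC = -2*loglik + 2*k (k = fixed effects + variance
components, + residual variance for Gaussian fits) and compares the best
model to the random-effects-only null model with a likelihood-ratio test.
Significance of individual coefficients in the best Gaussian model is
assessed by posterior simulation from the estimated sampling distribution.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, sparse
from scipy import stats as sps

BINOMIAL = "binomial_logit"
GAUSSIAN = "gaussian_identity"

#: enumeration guard: all-subsets search is capped at this many main effects
DEFAULT_POOL_CAP = 12
COLLINEARITY_THRESHOLD = 0.7


class RankDeficientError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed_effects: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    random_effects: tuple[str, ...] = ("conflict_id",)
    family: str = BINOMIAL

    def __post_init__(self):
        if not self.random_effects:
            raise ValueError("at least one random effect is required")
        present = set(self.fixed_effects)
        for a, b in self.interactions:
            if a not in present or b not in present:
                raise ValueError(f"interaction ({a},{b}) lacks a main effect")

    @property
    def term_names(self) -> tuple[str, ...]:
        return (("intercept",) + self.fixed_effects
                + tuple(f"{a}:{b}" for a, b in self.interactions))


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    log_likelihood: float
    aic: float
    n_obs: int
    k_params: int
    converged: bool
    vc_sd: dict[str, float] = field(default_factory=dict)
    cov_params: Optional[np.ndarray] = None


def build_design(table: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Model matrix with intercept; interactions are element-wise products."""
    n = len(table)
    cols = [np.ones(n)]
    for name in spec.fixed_effects:
        cols.append(table[name].to_numpy(dtype=float))
    for a, b in spec.interactions:
        cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(
            f"design is rank deficient for terms {spec.term_names}"
        )
    return X


# ---------------------------------------------------------------------------
# binomial Laplace machinery
# ---------------------------------------------------------------------------


def _factor_codes(table: pd.DataFrame, names: Sequence[str]):
    factors = []
    for name in names:
        codes, _levels = pd.factorize(table[name], sort=True)
        factors.append((name, codes.astype(np.int64), int(codes.max()) + 1))
    return factors


def _binomial_pll(y, eta, u_blocks, inv_var):
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    pen = 0.5 * sum(iv * float(u @ u) for u, iv in zip(u_blocks, inv_var))
    return ll - pen


def _pirls_single(y, X, codes, n_levels, inv_var, beta, u, max_iter=60):
    """Joint (beta, u) Newton optimisation for one random factor.

    Exploits the diagonal Z'WZ block via a Schur complement; cost is
    O(n p^2) per iteration regardless of the number of levels.
    """
    n, p = X.shape
    obj = _binomial_pll(y, X @ beta + u[codes], [u], inv_var)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + u[codes], -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = y - mu
        g_beta = X.T @ r
        g_u = np.bincount(codes, weights=r, minlength=n_levels) - inv_var[0] * u
        d_u = np.bincount(codes, weights=w, minlength=n_levels) + inv_var[0]
        Xw = X * w[:, None]
        B = np.zeros((n_levels, p))
        np.add.at(B, codes, Xw)                      # B = Z'WX
        H_bb = X.T @ Xw
        S = H_bb - (B / d_u[:, None]).T @ B          # Schur complement
        rhs = g_beta - B.T @ (g_u / d_u)
        try:
            c, low = sla.cho_factor(S, check_finite=False)
            db = sla.cho_solve((c, low), rhs, check_finite=False)
        except np.linalg.LinAlgError:
            return beta, u, obj, False, None
        du = (g_u - B @ db) / d_u
        step = 1.0
        for _ in range(25):
            nb, nu = beta + step * db, u + step * du
            new_obj = _binomial_pll(y, X @ nb + nu[codes], [nu], inv_var)
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        else:
            return beta, u, obj, True, (S, d_u)
        gain = new_obj - obj
        beta, u, obj = nb, nu, new_obj
        if gain < 1e-8 and np.linalg.norm(db) * step < 1e-6:
            break
    eta = np.clip(X @ beta + u[codes], -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    Xw = X * w[:, None]
    d_u = np.bincount(codes, weights=w, minlength=n_levels) + inv_var[0]
    B = np.zeros((n_levels, p))
    np.add.at(B, codes, Xw)
    S = (X.T @ Xw) - (B / d_u[:, None]).T @ B
    return beta, u, obj, True, (S, d_u)


def _pirls_multi(y, X, factors, inv_var, beta, u_flat, max_iter=60):
    """Joint Newton optimisation with several crossed random factors (dense)."""
    n, p = X.shape
    sizes = [L for _, _, L in factors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    q = offsets[-1]
    rows = np.arange(n)
    Z = sparse.csr_matrix(
        (np.ones(n * len(factors)),
         (np.tile(rows, len(factors)),
          np.concatenate([off + codes for off, (_, codes, _) in zip(offsets, factors)]))),
        shape=(n, q),
    )
    dinv = np.concatenate([np.full(L, iv) for L, iv in zip(sizes, inv_var)])

    def blocks(u):
        return [u[offsets[i]: offsets[i + 1]] for i in range(len(factors))]

    obj = _binomial_pll(y, X @ beta + Z @ u_flat, blocks(u_flat), inv_var)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + Z @ u_flat, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = y - mu
        g_b = X.T @ r
        g_u = Z.T @ r - dinv * u_flat
        Xw = X * w[:, None]
        Huu = (Z.T @ sparse.diags(w) @ Z).toarray()
        Huu[np.diag_indices_from(Huu)] += dinv
        Hbu = np.asarray(Z.T @ Xw).T  # p x q
        try:
            c_u, low_u = sla.cho_factor(Huu, check_finite=False)
            # Schur complement on the (small) fixed-effect block
            HuuinvHub = sla.cho_solve((c_u, low_u), Hbu.T, check_finite=False)
            S = X.T @ Xw - Hbu @ HuuinvHub
            rhs = g_b - HuuinvHub.T @ g_u
            c_s, low_s = sla.cho_factor(S, check_finite=False)
            db = sla.cho_solve((c_s, low_s), rhs, check_finite=False)
            du = sla.cho_solve((c_u, low_u), g_u - Hbu.T @ db,
                               check_finite=False)
        except np.linalg.LinAlgError:
            return beta, u_flat, obj, False, None, Z
        step = 1.0
        for _ in range(25):
            nb, nu = beta + step * db, u_flat + step * du
            new_obj = _binomial_pll(y, X @ nb + Z @ nu, blocks(nu), inv_var)
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        else:
            break
        gain = new_obj - obj
        beta, u_flat, obj = nb, nu, new_obj
        if gain < 1e-8 and (np.linalg.norm(db) + np.linalg.norm(du)) * step < 1e-6:
            break
    return beta, u_flat, obj, True, None, Z


def _u_pirls_single(y, X, codes, n_levels, ivar, beta, u, tol=1e-9, max_iter=40):
    """Newton optimisation of the random modes u at fixed beta (diagonal system)."""
    xb = X @ beta
    obj = _binomial_pll(y, xb + u[codes], [u], [ivar])
    for _ in range(max_iter):
        eta = np.clip(xb + u[codes], -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        g = np.bincount(codes, weights=y - mu, minlength=n_levels) - ivar * u
        d = np.bincount(codes, weights=w, minlength=n_levels) + ivar
        du = g / d
        step = 1.0
        for _ in range(20):
            nu = u + step * du
            new_obj = _binomial_pll(y, xb + nu[codes], [nu], [ivar])
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        gain = new_obj - obj
        u, obj = nu, new_obj
        if gain < tol:
            break
    eta = np.clip(xb + u[codes], -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    d = np.bincount(codes, weights=w, minlength=n_levels) + ivar
    return u, mu, w, d


def _laplace_ll_single(y, X, codes, n_levels, ivar, beta, u):
    """Laplace marginal log-likelihood at (beta, u_hat(beta)) for one factor."""
    u, mu, w, d = _u_pirls_single(y, X, codes, n_levels, ivar, beta, u)
    eta = np.clip(X @ beta + u[codes], -30.0, 30.0)
    ll_bin = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll = (ll_bin - 0.5 * ivar * float(u @ u)
          + 0.5 * n_levels * math.log(ivar) - 0.5 * float(np.sum(np.log(d))))
    return ll, u, mu, w, d


def _refine_beta_single(y, X, codes, n_levels, ivar, beta, u, max_iter=25):
    """Newton refinement of beta on the Laplace objective itself.

    The gradient accounts for the beta-dependence of both the random modes
    and the log-determinant term, matching the full Laplace ML criterion
    (the fast joint-mode step alone attenuates the fixed effects).
    """
    ll, u, mu, w, d = _laplace_ll_single(y, X, codes, n_levels, ivar, beta, u)
    p = X.shape[1]
    for _ in range(max_iter):
        Xw = X * w[:, None]
        B = np.zeros((n_levels, p))
        np.add.at(B, codes, Xw)                       # B = Z'WX
        c = w * (1.0 - 2.0 * mu)
        C = np.zeros((n_levels, p))
        np.add.at(C, codes, X * c[:, None])           # C_j = sum_i c_i x_i
        cbar = np.bincount(codes, weights=c, minlength=n_levels)
        grad_logdet = ((C / d[:, None])
                       - (cbar / d**2)[:, None] * B).sum(axis=0)
        grad = X.T @ (y - mu) - 0.5 * grad_logdet
        S = (X.T @ Xw) - (B / d[:, None]).T @ B
        try:
            c_f, low = sla.cho_factor(S, check_finite=False)
            db = sla.cho_solve((c_f, low), grad, check_finite=False)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(20):
            cand = beta + step * db
            new_ll, nu, nmu, nw, nd = _laplace_ll_single(
                y, X, codes, n_levels, ivar, cand, u)
            if new_ll >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        gain = new_ll - ll
        beta, u, mu, w, d, ll = cand, nu, nmu, nw, nd, new_ll
        if gain < 1e-9 and float(np.linalg.norm(db)) * step < 1e-7:
            break
    Xw = X * w[:, None]
    B = np.zeros((n_levels, X.shape[1]))
    np.add.at(B, codes, Xw)
    S = (X.T @ Xw) - (B / d[:, None]).T @ B
    return beta, u, ll, S


def _laplace_ll_multi(y, X, Z, dinv, sizes, log_sd, beta, u, max_iter=40):
    """Laplace log-likelihood with u profiled out, several crossed factors."""
    xb = X @ beta
    inv_var_blocks = None
    obj = None
    for _ in range(max_iter):
        eta = np.clip(xb + Z @ u, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        g = Z.T @ (y - mu) - dinv * u
        Huu = (Z.T @ sparse.diags(w) @ Z).toarray() + np.diag(dinv)
        try:
            c_f, low = sla.cho_factor(Huu, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        du = sla.cho_solve((c_f, low), g, check_finite=False)
        cur = float(np.sum(y * eta - np.logaddexp(0.0, eta))
                    - 0.5 * np.sum(dinv * u * u))
        step = 1.0
        for _ in range(20):
            nu = u + step * du
            eta2 = np.clip(xb + Z @ nu, -30.0, 30.0)
            new = float(np.sum(y * eta2 - np.logaddexp(0.0, eta2))
                        - 0.5 * np.sum(dinv * nu * nu))
            if new >= cur - 1e-12:
                break
            step *= 0.5
        gain = new - cur
        u = nu
        if gain < 1e-9:
            break
    eta = np.clip(xb + Z @ u, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    Huu = (Z.T @ sparse.diags(w) @ Z).toarray() + np.diag(dinv)
    sign, logdet = np.linalg.slogdet(Huu)
    if sign <= 0:
        return None
    ll_bin = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    logdet_D = 2.0 * float(np.sum(np.asarray(sizes) * np.asarray(log_sd)))
    ll = (ll_bin - 0.5 * float(np.sum(dinv * u * u))
          - 0.5 * logdet_D - 0.5 * logdet)
    return ll, u, w


def _fit_binomial_laplace(
    y: np.ndarray,
    X: np.ndarray,
    factors,
    theta0: Optional[np.ndarray] = None,
    theta_fixed: Optional[np.ndarray] = None,
    refine: bool = True,
) -> dict:
    """Laplace-approximate ML for a logistic model with random intercepts.

    ``theta_fixed`` evaluates the fit at frozen log-SD variance components
    instead of profiling them — used to make large model-set enumerations
    tractable (the best models are then refitted with full profiling).
    """
    n, p = X.shape
    if y.min() == y.max():
        return {"converged": False, "reason": "separation"}
    state = {"beta": np.zeros(p), "u": {}}
    state["beta"][0] = math.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    single = len(factors) == 1

    sizes = [L for _, _, L in factors]
    q = sum(sizes)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    Z = None
    if not single:
        rows = np.arange(n)
        Z = sparse.csr_matrix(
            (np.ones(n * len(factors)),
             (np.tile(rows, len(factors)),
              np.concatenate([off + codes
                              for off, (_, codes, _) in zip(offsets, factors)]))),
            shape=(n, q),
        )

    def laplace_nll(log_sd, do_refine=False):
        log_sd = np.atleast_1d(np.asarray(log_sd, dtype=float))
        sd = np.exp(log_sd)
        inv_var = 1.0 / np.maximum(sd**2, 1e-12)
        if single:
            name, codes, L = factors[0]
            u0 = state["u"].get("flat")
            u0 = np.zeros(L) if u0 is None or u0.size != L else u0.copy()
            beta, u, obj, ok, aux = _pirls_single(
                y, X, codes, L, inv_var, state["beta"].copy(), u0
            )
            if not ok or aux is None:
                return 1e10
            if do_refine:
                beta, u, ll, S = _refine_beta_single(
                    y, X, codes, L, inv_var[0], beta, u
                )
            else:
                S, d_u = aux
                ll, u, _mu, _w, _d = _laplace_ll_single(
                    y, X, codes, L, inv_var[0], beta, u
                )
            state.update(beta=beta)
            state["u"]["flat"] = u
            state["aux"] = S
        else:
            dinv = np.concatenate([np.full(L, iv)
                                   for L, iv in zip(sizes, inv_var)])
            u0 = state["u"].get("flat")
            u0 = np.zeros(q) if u0 is None or u0.size != q else u0.copy()
            beta, u, obj, ok, H, _Z = _pirls_multi(
                y, X, factors, inv_var, state["beta"].copy(), u0
            )
            if not ok:
                return 1e10
            if do_refine:
                warm = {"u": u.copy()}

                def neg_ll(b):
                    out = _laplace_ll_multi(y, X, Z, dinv, sizes, log_sd, b,
                                            warm["u"].copy())
                    if out is None:
                        return 1e10
                    llv, uv, _w = out
                    warm["u"] = uv
                    return -llv

                res_b = optimize.minimize(neg_ll, beta, method="L-BFGS-B",
                                          options={"maxiter": 40, "ftol": 1e-10})
                beta = res_b.x
            out = _laplace_ll_multi(y, X, Z, dinv, sizes, log_sd, beta,
                                    u.copy())
            if out is None:
                return 1e10
            ll, u, _w = out
            state.update(beta=beta)
            state["u"]["flat"] = u
            state["dinv"] = dinv
        state["ll"] = ll
        return -ll

    d = len(factors)
    if theta0 is None:
        theta0 = np.zeros(d)
    if theta_fixed is not None:
        theta_hat = np.atleast_1d(np.asarray(theta_fixed, dtype=float))
    elif d == 1:
        res = optimize.minimize_scalar(
            laplace_nll, bounds=(-6.0, 3.0), method="bounded",
            options={"xatol": 0.02},
        )
        theta_hat = np.array([res.x])
    else:
        res = optimize.minimize(
            laplace_nll, np.clip(theta0, -5.9, 2.9), method="Nelder-Mead",
            bounds=[(-6.0, 3.0)] * d,
            options={"xatol": 0.03, "fatol": 1e-3, "maxiter": 60 * d},
        )
        theta_hat = np.atleast_1d(res.x)
    # the variance profile is run with the fast joint-mode evaluation; the
    # final fixed effects and likelihood are refined once at theta_hat
    nll = laplace_nll(theta_hat if d > 1 else theta_hat[0], do_refine=refine)
    if nll >= 1e9 or not np.isfinite(nll):
        return {"converged": False, "reason": "inner_failure"}
    beta = state["beta"]
    if np.max(np.abs(beta)) > 30.0:
        return {"converged": False, "reason": "separation"}
    if single:
        cov_beta = sla.inv(state["aux"])
    else:
        # observed joint information at the final (beta, u)
        u = state["u"]["flat"]
        dinv = state["dinv"]
        eta = np.clip(X @ beta + Z @ u, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        Xw = X * w[:, None]
        Zd = Z.toarray()
        H = np.block([[X.T @ Xw, Xw.T @ Zd],
                      [(Xw.T @ Zd).T,
                       (Z.T @ sparse.diags(w) @ Z).toarray() + np.diag(dinv)]])
        cov = sla.inv(H)
        cov_beta = cov[:p, :p]
    return {
        "converged": True,
        "beta": beta,
        "cov_beta": cov_beta,
        "llf": state["ll"],
        "sd": {factors[i][0]: float(np.exp(theta_hat[i])) for i in range(d)},
        "theta": theta_hat,
    }


# ---------------------------------------------------------------------------
# gaussian fits via statsmodels MixedLM
# ---------------------------------------------------------------------------


def _fit_gaussian_ml(y, X, names, table, random_effects) -> dict:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if float(np.var(y)) < 1e-12:
        # degenerate flat response: slopes are exactly zero
        p = X.shape[1]
        beta = np.zeros(p)
        beta[0] = float(np.mean(y))
        llf = float(np.sum(sps.norm.logpdf(y - np.mean(y), scale=1e-6)))
        return {"converged": True, "beta": beta,
                "cov_beta": np.zeros((p, p)), "llf": llf,
                "sd": {f: 0.0 for f in random_effects}}
    df = table.copy()
    df["_y"] = y
    for j, name in enumerate(names[1:], start=1):
        df[f"_x{j}"] = X[:, j]
    rhs = " + ".join(f"_x{j}" for j in range(1, X.shape[1])) or "1"
    vcf = {f: f"0 + C({f})" for f in random_effects}
    df["_all"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM.from_formula(
            f"_y ~ {rhs}", groups="_all", vc_formula=vcf, re_formula="0", data=df
        )
        # variance components sit on the boundary for many dyadic tables;
        # fall through a cascade of optimisers and keep the best ML point
        res = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500,
                                 disp=False)
            except Exception:
                continue
            if res is None or (cand.llf > res.llf + 1e-6):
                res = cand
            if res is not None and res.converged:
                break
        if res is None:
            return {"converged": False, "reason": "fit_error"}
    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
    sd = {}
    for i, f in enumerate(random_effects):
        try:
            sd[f] = float(np.sqrt(res.vcomp[i]))
        except Exception:
            sd[f] = float("nan")
    return {"converged": bool(res.converged), "beta": beta, "cov_beta": cov,
            "llf": float(res.llf), "sd": sd}


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def fit_mixed(spec: ModelSpec, table: pd.DataFrame,
              theta0: Optional[np.ndarray] = None,
              theta_fixed: Optional[np.ndarray] = None,
              refine: bool = True) -> ModelFit:
    """Fit one mixed-model specification by (approximate) maximum likelihood.

    AIC is always -2*loglik + 2*k with k counting fixed effects plus
    variance components (plus the residual variance for Gaussian fits).
    Non-converged fits carry ``converged=False`` and NaN statistics; the
    selection step skips them.
    """
    y = table[spec.response].to_numpy(dtype=float)
    X = build_design(table, spec)
    names = list(spec.term_names)
    factors = _factor_codes(table, spec.random_effects)
    if spec.family == BINOMIAL:
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial family requires a 0/1 outcome")
        raw = _fit_binomial_laplace(y, X, factors, theta0=theta0,
                                    theta_fixed=theta_fixed, refine=refine)
        k = X.shape[1] + len(factors)
    elif spec.family == GAUSSIAN:
        raw = _fit_gaussian_ml(y, X, names, table, spec.random_effects)
        k = X.shape[1] + len(factors) + 1  # + residual variance
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    idx = pd.Index(names)
    if not raw.get("converged"):
        nan = pd.Series(np.nan, index=idx)
        return ModelFit(spec, nan, nan, nan, float("nan"), float("nan"),
                        len(table), k, False)
    beta = pd.Series(raw["beta"], index=idx)
    se = pd.Series(np.sqrt(np.maximum(np.diag(raw["cov_beta"]), 0.0)), index=idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    llf = raw["llf"]
    return ModelFit(spec, beta, se, z, llf, -2.0 * llf + 2.0 * k, len(table), k,
                    True, raw["sd"], raw["cov_beta"])


# ---------------------------------------------------------------------------
# all-subsets AIC selection
# ---------------------------------------------------------------------------


def collinear_pairs(table: pd.DataFrame, pool: Sequence[str],
                    threshold: float = COLLINEARITY_THRESHOLD) -> set[frozenset]:
    """Predictor pairs whose absolute Pearson correlation exceeds threshold."""
    out = set()
    cols = [c for c in pool if table[c].std() > 0]
    corr = table[cols].corr().abs()
    for a, b in itertools.combinations(cols, 2):
        if corr.loc[a, b] > threshold:
            out.add(frozenset((a, b)))
    return out


@dataclass
class SelectionResult:
    results: pd.DataFrame
    best: ModelFit
    null: ModelFit
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    screened_pairs: set[frozenset] = field(default_factory=set)

    @property
    def best_spec(self) -> ModelSpec:
        return self.best.spec


def enumerate_and_select(
    table: pd.DataFrame,
    response: str,
    pool: Sequence[str],
    interactions: Sequence[tuple[str, str]] = (),
    random_effects: Sequence[str] = ("conflict_id",),
    family: str = BINOMIAL,
    cap: int = DEFAULT_POOL_CAP,
    corr_threshold: float = COLLINEARITY_THRESHOLD,
    reoptimize_theta: bool = True,
) -> SelectionResult:
    """All-subsets AIC model selection over a candidate predictor pool.

    Every subset of main effects up to ``cap`` terms is fitted, expanded by
    every combination of the listed two-way interactions whose parents are
    present.  Subsets containing a collinear pair are skipped.  Ranked by
    AIC ascending, ties broken by fewer parameters; the best model is
    compared against the random-effects-only null by likelihood ratio.

    With ``reoptimize_theta=False`` the variance components are estimated
    once on the largest admissible model and frozen during enumeration
    (the selected best model is then refitted with full profiling), which
    keeps many-random-effect enumerations tractable.
    """
    # constant columns (e.g. after a reduction filter) cannot enter any model
    pool = [p for p in pool if table[p].std() > 0]
    blocked = collinear_pairs(table, pool, corr_threshold)
    re_tuple = tuple(random_effects)

    theta0 = theta_fixed = None
    if family == BINOMIAL and pool:
        free = [p for p in pool
                if not any(frozenset((p, q)) in blocked for q in pool if q != p)]
        warm = fit_mixed(
            ModelSpec(response, tuple(free), (), re_tuple, family), table
        )
        if warm.converged:
            theta0 = np.log(np.maximum(
                np.array([warm.vc_sd[f] for f in re_tuple]), 1e-4))
            if not reoptimize_theta:
                theta_fixed = theta0

    fits: list[ModelFit] = []
    rows = []
    for size in range(0, min(len(pool), cap) + 1):
        for subset in itertools.combinations(pool, size):
            sset = set(subset)
            if any(frozenset(p) <= sset for p in blocked):
                continue
            eligible = [i for i in interactions if i[0] in sset and i[1] in sset]
            for r in range(len(eligible) + 1):
                for ints in itertools.combinations(eligible, r):
                    spec = ModelSpec(response, subset, tuple(ints), re_tuple, family)
                    try:
                        fit = fit_mixed(spec, table, theta0=theta0,
                                        theta_fixed=theta_fixed, refine=False)
                    except RankDeficientError:
                        continue
                    fits.append(fit)
                    rows.append({
                        "fixed_effects": subset,
                        "interactions": tuple(ints),
                        "k": fit.k_params,
                        "loglik": fit.log_likelihood,
                        "aic": fit.aic,
                        "converged": fit.converged,
                    })
    results = pd.DataFrame(rows)
    null_fit = next(
        (f for f in fits if not f.spec.fixed_effects and not f.spec.interactions),
        None,
    )
    null_fit = fit_mixed(ModelSpec(response, (), (), re_tuple, family), table,
                         theta0=theta0)
    ok = [f for f in fits if f.converged]
    if not ok:
        raise RuntimeError("no candidate model converged")
    best = min(ok, key=lambda f: (f.aic, f.k_params))
    refit = fit_mixed(best.spec, table, theta0=theta0)
    if refit.converged:
        best = refit
    chi2 = 2.0 * (best.log_likelihood - null_fit.log_likelihood)
    df = max(best.k_params - null_fit.k_params, 0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else (0.0 if chi2 > 0 else 1.0)
    if not results.empty:
        results = results.sort_values(["aic", "k"], na_position="last").reset_index(drop=True)
    return SelectionResult(results, best, null_fit, float(chi2), df, p, blocked)


EXCLUSIONS = ("mother_reared_bystanders", "juvenile_bystanders")


def reduced_model_runs(
    table: pd.DataFrame,
    exclusion: str,
    response: str = "outcome",
    **select_kwargs,
) -> dict:
    """Re-run selection on a filtered table (standard robustness reductions).

    ``mother_reared_bystanders`` drops rows contributed by mother-reared
    bystanders (their rearing is confounded with juvenility);
    ``juvenile_bystanders`` drops juvenile bystanders, restricting the
    analysis to mature individuals for comparability with studies that
    exclude immatures.
    """
    if exclusion not in EXCLUSIONS:
        raise ValueError(f"unknown exclusion {exclusion!r}")
    col = ("bystander_mother_reared" if exclusion == "mother_reared_bystanders"
           else "bystander_juvenile")
    filtered = table[table[col] == 0.0].reset_index(drop=True)
    if filtered.empty:
        raise ValueError(f"exclusion {exclusion!r} removed every row")
    selection = enumerate_and_select(filtered, response, **select_kwargs)
    return {
        "exclusion": exclusion,
        "n_before": len(table),
        "n_after": len(filtered),
        "n_bystanders_before": table["bystander_id"].nunique()
        if "bystander_id" in table else None,
        "n_bystanders_after": filtered["bystander_id"].nunique()
        if "bystander_id" in filtered else None,
        "selection": selection,
    }


# ---------------------------------------------------------------------------
# dyadic gaussian models with simulation-based p-values
# ---------------------------------------------------------------------------


def posterior_sim_pvalues(fit: ModelFit, n_draws: int = 10_000,
                          seed: int = 0) -> pd.Series:
    """Coefficient p-values from simulation of the sampling distribution.

    Draws from N(beta_hat, cov_hat) and reports, per coefficient, twice the
    smaller tail fraction around zero (with the +1 small-sample guard), in
    the spirit of the posterior-simulation p-values traditionally used for
    lmer models.
    """
    rng = np.random.default_rng(seed)
    if fit.cov_params is None or not fit.converged:
        return pd.Series(np.nan, index=fit.params.index)
    cov = np.asarray(fit.cov_params)
    cov = (cov + cov.T) / 2.0
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0.0):
        return pd.Series(np.where(fit.params == 0.0, 1.0, 0.0),
                         index=fit.params.index)
    draws = rng.multivariate_normal(fit.params.to_numpy(), cov, size=n_draws,
                                    method="eigh")
    pos = (draws > 0).sum(axis=0)
    neg = (draws < 0).sum(axis=0)
    p = 2.0 * (np.minimum(pos, neg) + 1) / (n_draws + 1)
    return pd.Series(np.minimum(p, 1.0), index=fit.params.index)


def lmm_dyadic(
    table: pd.DataFrame,
    response: str,
    pool: Sequence[str],
    random_effects: Sequence[str] = ("victim_id", "bystander_id", "group_id"),
    n_draws: int = 10_000,
    seed: int = 0,
    **select_kwargs,
) -> tuple[SelectionResult, pd.Series]:
    """AIC-selected Gaussian mixed model for a dyadic tendency response.

    Returns the selection result and posterior-simulation p-values for the
    best model's coefficients.
    """
    clean = table.dropna(subset=[response]).reset_index(drop=True)
    selection = enumerate_and_select(
        clean, response, pool, random_effects=random_effects,
        family=GAUSSIAN, **select_kwargs,
    )
    pvals = posterior_sim_pvalues(selection.best, n_draws=n_draws, seed=seed)
    return selection, pvals
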