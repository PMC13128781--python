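"""Mixed-effects fitters for crossed random intercepts (participant x item).

Trial-level lexical-decision data have two crossed grouping factors:
every participant responds to many items and every item is seen by many
participants. The fitters here handle exactly that structure —
``y = X beta + u_participant + u_item + error`` — which is all the model
comparison machinery needs, and exploit the indicator structure of the
random-effect design for speed (hundreds of maximum-likelihood fits run in
a parameter-recovery harness).

* :func:`fit_lmm_crossed` — Gaussian response. The deviance is profiled
  over the fixed effects and the residual variance in the usual way
  (penalized least squares on the spherical random effects, then a
  two-parameter search over the relative covariance factors), giving the
  maximum-likelihood fit directly. ML rather than REML is used throughout
  so AICs are comparable across different fixed-effect sets.
* :func:`fit_glmm_logit_crossed` — Bernoulli response with logit link,
  Laplace approximation to the marginal likelihood: an inner Newton solve
  for the joint random-effect mode, an outer quasi-Newton search over the
  fixed effects and the two random-intercept standard deviations.

Both report the log-likelihood, a parameter count ``k`` (fixed effects +
variance components + residual variance where applicable) and
``AIC = 2k - 2 logL``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "MixedFitResult",
    "ConvergenceError",
    "RankDeficientError",
    "SeparationError",
    "fit_lmm_crossed",
    "fit_glmm_logit_crossed",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; message carries the diagnostics."""


class RankDeficientError(ValueError):
    """Fixed-effect design matrix is not full column rank."""


class SeparationError(ValueError):
    """Binary response is (quasi-)completely separated; no finite MLE."""


@dataclass
class MixedFitResult:
    """A fitted mixed model with the quantities model comparison needs."""

    kind: str                      # "linear" | "binomial"
    fe_params: pd.Series           # fixed effects (log-odds scale for binomial)
    bse: pd.Series                 # standard errors of fe_params
    vc: dict[str, float]           # random-intercept variances (tau00) per grouping
    scale: float | None            # residual variance sigma^2 (linear only)
    llf: float
    k: int                         # estimated-parameter count entering the AIC
    n_obs: int
    converged: bool
    fitted_fixed_var: float        # variance of X @ beta over the sample
    optimizer_message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    @property
    def odds_ratios(self) -> pd.Series:
        if self.kind != "binomial":
            raise ValueError("odds ratios are defined for binomial fits only")
        return np.exp(self.fe_params)

    @property
    def odds_ratio_bse(self) -> pd.Series:
        """Delta-method SEs on the odds-ratio scale (exp(beta) * se(beta))."""
        if self.kind != "binomial":
            raise ValueError("odds ratios are defined for binomial fits only")
        return np.exp(self.fe_params) * self.bse


def _as_codes(values) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(values))
    return codes.astype(np.int64), len(uniques)


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(
            "fixed-effect design is rank deficient (collinear predictors)"
        )


def _design(X: np.ndarray, names) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("names length does not match X columns")
    _check_design(X)
    return X, names


# ---------------------------------------------------------------------------
# Linear mixed model, profiled ML
# ---------------------------------------------------------------------------

def fit_lmm_crossed(
    y,
    X,
    participant,
    item,
    names=None,
    group_names: tuple[str, str] = ("participant", "item"),
) -> MixedFitResult:
    """ML fit of a linear mixed model with crossed random intercepts.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design, including the intercept column
    participant, item : (n,) grouping labels (any hashable values)
    names : fixed-effect column names

    Notes
    -----
    With ``Lambda = diag(theta_p I_P, theta_i I_I)`` the profiled ML
    deviance is ``log det(Lambda' Z'Z Lambda + I) + n (1 + log(2 pi r2/n))``
    where ``r2`` is the penalized residual sum of squares at the joint
    least-squares solution for the fixed effects and spherical random
    effects. The search space is just ``theta = (theta_p, theta_i) >= 0``.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(X, names)
    n, p = X.shape
    p_idx, P = _as_codes(participant)
    i_idx, I = _as_codes(item)
    q = P + I

    rows = np.arange(n)
    Z = sparse.csr_matrix(
        (np.ones(2 * n), (np.concatenate([rows, rows]),
                          np.concatenate([p_idx, P + i_idx]))),
        shape=(n, q),
    )
    ZtZ = np.asarray((Z.T @ Z).todense())
    ZtX = np.asarray(Z.T @ X)
    Zty = np.asarray(Z.T @ y).ravel()
    XtX = X.T @ X
    Xty = X.T @ y

    lam_mask_p = np.zeros(q)
    lam_mask_p[:P] = 1.0

    def solve_at(theta: np.ndarray):
        tp, ti = np.maximum(theta, 0.0)
        lam = np.where(lam_mask_p == 1.0, tp, ti)
        A = (lam[:, None] * lam[None, :]) * ZtZ
        A[np.diag_indices_from(A)] += 1.0
        c = cho_factor(A, lower=True)
        logdetA = 2.0 * np.sum(np.log(np.diag(c[0])))
        CZX = lam[:, None] * ZtX
        CZy = lam * Zty
        AiZX = cho_solve(c, CZX)
        AiZy = cho_solve(c, CZy)
        S = XtX - CZX.T @ AiZX
        rhs = Xty - CZX.T @ AiZy
        try:
            beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise RankDeficientError(str(exc)) from exc
        u = AiZy - AiZX @ beta
        b = lam * u
        fitted = X @ beta + np.asarray(Z @ b).ravel()
        resid = y - fitted
        pwrss = resid @ resid + u @ u
        dev = logdetA + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
        return dev, beta, S, pwrss

    def objective(theta: np.ndarray) -> float:
        return solve_at(theta)[0]

    res = optimize.minimize(
        objective,
        x0=np.array([1.0, 1.0]),
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None)],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-6},
    )
    if not res.success:
        # The 2-d profiled deviance is cheap and smooth; if the quasi-Newton
        # line search trips on finite-difference noise, fall back to
        # Nelder-Mead from the best point seen.
        nm = optimize.minimize(
            objective,
            x0=res.x if np.all(np.isfinite(res.x)) else np.array([1.0, 1.0]),
            method="Nelder-Mead",
            bounds=[(0.0, None), (0.0, None)],
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        if not nm.success:
            raise ConvergenceError(
                f"linear mixed model did not converge: {res.message} / {nm.message}"
            )
        res = nm

    dev, beta, S, pwrss = solve_at(res.x)
    sigma2 = pwrss / n
    tau_p = sigma2 * res.x[0] ** 2
    tau_i = sigma2 * res.x[1] ** 2
    cov_beta = sigma2 * np.linalg.inv(S)
    llf = -dev / 2.0
    fitted_fixed = X @ beta
    return MixedFitResult(
        kind="linear",
        fe_params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=names),
        vc={group_names[0]: float(tau_p), group_names[1]: float(tau_i)},
        scale=float(sigma2),
        llf=float(llf),
        k=p + 3,  # fixed effects + two tau00 + residual variance
        n_obs=n,
        converged=True,
        fitted_fixed_var=float(np.var(fitted_fixed)),
        optimizer_message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Logistic mixed model, Laplace approximation
# ---------------------------------------------------------------------------

def _logistic(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    big = eta > 30
    out[big] = eta[big]
    out[~big] = np.log1p(np.exp(eta[~big]))
    return out


def fit_glmm_logit_crossed(
    y,
    X,
    participant,
    item,
    names=None,
    group_names: tuple[str, str] = ("participant", "item"),
    maxiter: int = 500,
) -> MixedFitResult:
    """ML (Laplace) fit of a logistic mixed model with crossed random intercepts.

    The marginal likelihood is approximated by the Laplace method: for each
    candidate ``(beta, sigma_p, sigma_i)`` the joint posterior mode of the
    random effects is found by Newton iteration (the penalized-likelihood
    Hessian is a dense (P+I) x (P+I) matrix built from group-wise sums),
    and the approximate log-likelihood

    ``logL = loglik(y | eta_hat) - u'D^{-1}u/2 - log det(D)/2 - log det(H)/2``

    is maximized over the fixed effects and the log standard deviations.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary response must be coded 0/1")
    if y.min() == y.max():
        raise SeparationError(
            "response is constant (all 0 or all 1); the logistic MLE diverges"
        )
    X_orig, names = _design(X, names)
    n, p = X_orig.shape
    p_idx, P = _as_codes(participant)
    i_idx, I = _as_codes(item)
    q = P + I

    # Standardize non-constant columns internally: covariates on wildly
    # different scales (ms vs ratings) otherwise wreck the quasi-Newton
    # search. ``transform`` maps standardized coefficients back.
    spans = np.ptp(X_orig, axis=0)
    const_cols = np.flatnonzero(spans == 0)
    std_cols = np.flatnonzero(spans > 0)
    means = np.zeros(p)
    sds = np.ones(p)
    sds[std_cols] = X_orig[:, std_cols].std(axis=0)
    if len(const_cols):  # centering needs a constant column to absorb it
        means[std_cols] = X_orig[:, std_cols].mean(axis=0)
    X = X_orig.copy()
    X[:, std_cols] = (X_orig[:, std_cols] - means[std_cols]) / sds[std_cols]
    transform = np.diag(1.0 / sds)
    if len(const_cols) and len(std_cols):
        c0 = const_cols[0]
        v = X_orig[0, c0]
        transform[c0, std_cols] = -means[std_cols] / (sds[std_cols] * v)

    def zt_dot(v: np.ndarray) -> np.ndarray:
        return np.concatenate([
            np.bincount(p_idx, weights=v, minlength=P),
            np.bincount(i_idx, weights=v, minlength=I),
        ])

    def z_dot(u: np.ndarray) -> np.ndarray:
        return u[p_idx] + u[P + i_idx]

    def ztwz(w: np.ndarray) -> np.ndarray:
        H = np.zeros((q, q))
        dp = np.bincount(p_idx, weights=w, minlength=P)
        di = np.bincount(i_idx, weights=w, minlength=I)
        cross = np.zeros((P, I))
        np.add.at(cross, (p_idx, i_idx), w)
        H[:P, :P][np.diag_indices(P)] = dp
        H[P:, P:][np.diag_indices(I)] = di
        H[:P, P:] = cross
        H[P:, :P] = cross.T
        return H

    u_warm = np.zeros(q)

    def laplace_nll(x: np.ndarray) -> float:
        nonlocal u_warm
        beta = x[:p]
        sp, si = np.exp(x[p]), np.exp(x[p + 1])
        d = np.concatenate([np.full(P, sp**2), np.full(I, si**2)])
        d = np.maximum(d, 1e-10)
        xb = X @ beta
        u = u_warm.copy()

        def joint(uv: np.ndarray) -> float:
            eta = xb + z_dot(uv)
            return float(y @ eta - _log1pexp(eta).sum() - 0.5 * (uv**2 / d).sum())

        g_u = joint(u)
        H = None
        for _ in range(80):
            eta = xb + z_dot(u)
            mu = _logistic(eta)
            grad = zt_dot(y - mu) - u / d
            if np.max(np.abs(grad)) < 1e-10:
                break
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            H = ztwz(w)
            H[np.diag_indices(q)] += 1.0 / d
            try:
                step = cho_solve(cho_factor(H, lower=True), grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(q), grad)
            t = 1.0
            for _ in range(30):
                cand = u + t * step
                g_cand = joint(cand)
                if g_cand >= g_u - 1e-12:
                    u, g_u = cand, g_cand
                    break
                t *= 0.5
            else:
                break
        eta = xb + z_dot(u)
        mu = _logistic(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        H = ztwz(w)
        H[np.diag_indices(q)] += 1.0 / d
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        u_warm = u
        ll = g_u - 0.5 * np.log(d).sum() - 0.5 * logdetH
        return -ll

    # Start the fixed effects from an ordinary logistic regression.
    import statsmodels.api as sm

    try:
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        beta0 = np.asarray(glm.params)
        if not np.all(np.isfinite(beta0)) or np.abs(beta0).max() > 50:
            raise SeparationError("logistic start values diverged (separation?)")
    except SeparationError:
        raise
    except Exception:
        beta0 = np.zeros(p)
    x0 = np.concatenate([beta0, [np.log(0.5), np.log(0.5)]])

    # Forward differences with a step large enough to dominate the inner
    # Newton solve's noise floor; the standardized design keeps all
    # parameters on comparable scales so one step size works.
    res = optimize.minimize(
        laplace_nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(-6.0, 3.0), (-6.0, 3.0)],
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7, "eps": 1e-6},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"logistic mixed model did not converge: {res.message}")

    beta_std = res.x[:p]
    sp, si = np.exp(res.x[p]), np.exp(res.x[p + 1])
    if np.abs(beta_std).max() > 50:
        raise SeparationError(
            "fixed effects diverged during fitting (quasi-complete separation)"
        )
    llf = -laplace_nll(res.x)
    beta = transform @ beta_std

    # Conditional (penalized-likelihood) covariance for the fixed effects.
    d = np.concatenate([np.full(P, sp**2), np.full(I, si**2)])
    d = np.maximum(d, 1e-10)
    eta = X @ beta_std + z_dot(u_warm)
    mu = _logistic(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    XW = X * w[:, None]
    XtWX = X.T @ XW
    XtWZ = np.zeros((p, q))
    accp = np.zeros((P, p))
    np.add.at(accp, p_idx, XW)
    acci = np.zeros((I, p))
    np.add.at(acci, i_idx, XW)
    XtWZ[:, :P] = accp.T
    XtWZ[:, P:] = acci.T
    Hq = ztwz(w)
    Hq[np.diag_indices(q)] += 1.0 / d
    full = np.block([[XtWX, XtWZ], [XtWZ.T, Hq]])
    cov_std = np.linalg.inv(full)[:p, :p]
    cov = transform @ cov_std @ transform.T

    return MixedFitResult(
        kind="binomial",
        fe_params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        vc={group_names[0]: float(sp**2), group_names[1]: float(si**2)},
        scale=None,
        llf=float(llf),
        k=p + 2,  # fixed effects + two tau00
        n_obs=n,
        converged=bool(res.success),
        fitted_fixed_var=float(np.var(X @ beta_std)),
        optimizer_message=str(res.message),
    )
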