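"""Restricted maximum likelihood variance-component estimation.

Implements average-information (AI) REML with EM warm-up steps over an
arbitrary list of covariance structures, plus:

* univariate multi-GRM fits with per-component heritability and
  delta-method standard errors,
* an eigendecomposition fast path for the single-GRM case,
* boundary-aware likelihood-ratio tests (50:50 chi0/chi1 mixture),
* the bivariate between-sex fit in which males and females carry disjoint
  trait columns, the cross-group environmental covariance is structurally
  zero, and the genetic correlation ``r_g = C_G / sqrt(V_Gm V_Gf)`` is
  reported with a delta-method SE and an LRT against ``r_g = 1``.

The restricted log-likelihood convention (constants dropped) is::

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ]

with ``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve, eigh

from sexstrat.grm import GRM
from sexstrat.panel import FEMALE, MALE

_FLOOR_FRACTION = 1e-6  # non-negativity floor as a fraction of var(y)


class SingularDesignError(ValueError):
    """Fixed-effect design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# Covariance components: dense arrays or ("diag", vector)
# ---------------------------------------------------------------------------

def _comp_matmat(comp, B: np.ndarray) -> np.ndarray:
    if isinstance(comp, tuple):
        d = comp[1]
        return d[:, None] * B if B.ndim == 2 else d * B
    return comp @ B


def _comp_trace_prod(comp, M: np.ndarray) -> float:
    """tr(M @ comp) for symmetric dense M."""
    if isinstance(comp, tuple):
        return float(np.diag(M) @ comp[1])
    return float(np.sum(M * comp))


def _comp_add(V: np.ndarray, coef: float, comp) -> None:
    if isinstance(comp, tuple):
        idx = np.arange(V.shape[0])
        V[idx, idx] += coef * comp[1]
    else:
        V += coef * comp


def _build_v(n: int, theta: np.ndarray, comps) -> np.ndarray:
    V = np.zeros((n, n))
    for t, c in zip(theta, comps):
        _comp_add(V, t, c)
    return V


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _design(y: np.ndarray, covariates) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("fixed-effect design matrix is rank deficient")
    return y, X


def restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float | None:
    """Restricted log-likelihood at a fixed V; None if V is not PD."""
    try:
        c = cho_factor(V, lower=True)
    except LinAlgError:
        return None
    sol = cho_solve(c, np.column_stack([y, X]))
    Viy, ViX = sol[:, 0], sol[:, 1:]
    XtViX = X.T @ ViX
    try:
        cx = cho_factor(XtViX, lower=True)
    except LinAlgError:
        return None
    Xty = X.T @ Viy
    ypy = y @ Viy - Xty @ cho_solve(cx, Xty)
    logdet_v = 2 * np.sum(np.log(np.diag(c[0])))
    logdet_x = 2 * np.sum(np.log(np.diag(cx[0])))
    return float(-0.5 * (logdet_v + logdet_x + ypy))


def _chol_inverse(V: np.ndarray):
    """Cholesky factor, explicit inverse (via LAPACK potri), and log|V|."""
    from scipy.linalg import lapack

    c, info = lapack.dpotrf(V, lower=1)
    if info != 0:
        raise LinAlgError("matrix not positive definite")
    logdet = 2 * np.sum(np.log(np.diag(c)))
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise LinAlgError("inversion failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return (c, True), inv, logdet


def _reml_stats(y, X, theta, dv_fn):
    """logL, score vector, AI matrix, and EM ingredients at theta."""
    V, dVs = dv_fn(theta)
    n = len(y)
    c, Vinv, logdet_v = _chol_inverse(V)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cx = cho_factor(XtVinvX, lower=True)
    logdet_x = 2 * np.sum(np.log(np.diag(cx[0])))
    Viy = Vinv @ y
    XtViy = X.T @ Viy
    Py = Viy - VinvX @ cho_solve(cx, XtViy)
    ypy = float(y @ Py)
    logl = -0.5 * (logdet_v + logdet_x + ypy)

    k = len(dVs)
    T = np.column_stack([_comp_matmat(dv, Py) for dv in dVs])  # dV_k P y
    PT = Vinv @ T - VinvX @ cho_solve(cx, VinvX.T @ T)
    AI = 0.5 * (T.T @ PT)
    AI = (AI + AI.T) / 2

    quad = Py @ T  # y' P dV_k P y
    tr_pdv = np.empty(k)
    for i, dv in enumerate(dVs):
        W = _comp_matmat(dv, VinvX)
        tr_pdv[i] = _comp_trace_prod(dv, Vinv) - float(
            np.trace(cho_solve(cx, VinvX.T @ W))
        )
    score = -0.5 * (tr_pdv - quad)
    return logl, score, AI, quad, tr_pdv


def _clamp(theta: np.ndarray, floors: np.ndarray) -> np.ndarray:
    out = theta.copy()
    bounded = ~np.isnan(floors)
    out[bounded] = np.maximum(out[bounded], floors[bounded])
    return out


@dataclass
class _EngineResult:
    theta: np.ndarray
    logl: float
    cov: np.ndarray
    converged: bool
    n_iter: int


def _ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    dv_fn: Callable,
    theta0: np.ndarray,
    floors: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_em: int = 1,
) -> _EngineResult:
    """AI-REML with EM warm-up, step halving, and projected floors.

    ``dv_fn(theta) -> (V, [dV_k])`` supplies the covariance and its
    parameter derivatives; ``floors[k] = nan`` marks an unbounded
    parameter (e.g. a cross-group covariance).
    """
    n = len(y)
    theta = _clamp(np.asarray(theta0, dtype=float), floors)
    prev_theta = theta.copy()
    prev_logl = None
    converged = False
    it = 0
    n_updates = 0
    for it in range(1, max_iter + 1):
        try:
            logl, score, AI, quad, tr_pdv = _reml_stats(y, X, theta, dv_fn)
        except LinAlgError:
            # update left the PD cone; backtrack toward the last good point
            theta = (theta + prev_theta) / 2
            continue
        if prev_logl is not None and logl < prev_logl - 1e-8:
            # overshoot: halve the step (deferred line search)
            theta = (theta + prev_theta) / 2
            if np.max(np.abs(theta - prev_theta)) < 1e-12:
                theta = prev_theta
                converged = True
                break
            continue
        if prev_logl is not None and abs(logl - prev_logl) < tol and n_updates > n_em:
            converged = True
            break
        prev_theta = theta.copy()
        prev_logl = logl
        n_updates += 1
        if n_updates <= n_em:
            theta = _clamp(theta + theta**2 / n * (quad - tr_pdv), floors)
            continue
        try:
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(AI + 1e-6 * np.eye(len(score)), score)
        theta = _clamp(theta + delta, floors)
    logl, score, AI, _, _ = _reml_stats(y, X, theta, dv_fn)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    return _EngineResult(theta=theta, logl=logl, cov=cov, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# Univariate fits
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Univariate REML estimates for one or more GRMs plus residual."""

    vg: np.ndarray            # per-GRM genetic variance
    ve: float
    se: np.ndarray            # SEs in theta order [vg..., ve]
    cov: np.ndarray           # sampling covariance of [vg..., ve]
    logl: float
    converged: bool
    n_iter: int
    n: int
    sources: list = field(default_factory=list)

    @property
    def vp(self) -> float:
        return float(np.sum(self.vg) + self.ve)

    @property
    def h2(self) -> np.ndarray:
        return self.vg / self.vp

    @property
    def h2_total(self) -> float:
        return float(np.sum(self.vg) / self.vp)

    def _h2_grad(self, i: int | None) -> np.ndarray:
        """Gradient of per-component (or total, i=None) h2 wrt theta."""
        k = len(self.vg)
        s = self.vp
        grad = np.empty(k + 1)
        if i is None:
            vg_tot = float(np.sum(self.vg))
            grad[:k] = (s - vg_tot) / s**2
            grad[k] = -vg_tot / s**2
        else:
            grad[:] = -self.vg[i] / s**2
            grad[i] += 1.0 / s
        return grad

    def h2_se(self, i: int | None = None) -> float:
        """Delta-method SE of per-component (or total) heritability."""
        g = self._h2_grad(i)
        return float(np.sqrt(g @ self.cov @ g))


def fit_reml(
    y,
    covariates,
    grms: list,
    constrain: bool = True,
    method: str = "ai",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VarianceComponents:
    """Univariate REML fit of y on a set of GRMs plus residual.

    Fixed effects (intercept + covariates) are absorbed via the REML
    projection rather than pre-residualization.  ``method="eigen"`` is a
    single-GRM fast path through the eigendecomposition of the GRM;
    ``method="ai"`` is the general average-information engine.
    Non-convergence is flagged on the result, not raised.
    """
    y, X = _design(y, covariates)
    n = len(y)
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, float) for g in grms]
    k = len(mats)
    if k < 1:
        raise ValueError("at least one GRM is required")
    if n <= X.shape[1] + k:
        raise ValueError("too few samples for the requested model")
    vp0 = float(np.var(y))
    comps = [*mats, ("diag", np.ones(n))]

    def dv_fn(theta):
        return _build_v(n, theta, comps), comps

    theta0 = np.array([0.5 * vp0 / k] * k + [0.5 * vp0])
    floors = np.full(k + 1, _FLOOR_FRACTION * vp0 if constrain else np.nan)
    if not constrain:
        floors[:] = np.nan

    if method == "eigen":
        if k != 1:
            raise ValueError("eigen method supports exactly one GRM")
        theta_hat = _eigen_single_fit(y, X, mats[0], theta0, floors)
        res = _EngineResult(theta=theta_hat, logl=np.nan, cov=None, converged=True, n_iter=0)
        logl, _, AI, _, _ = _reml_stats(y, X, theta_hat, dv_fn)
        res.logl = logl
        try:
            res.cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            res.cov = np.linalg.pinv(AI)
    elif method == "ai":
        res = _ai_reml(y, X, dv_fn, theta0, floors, max_iter=max_iter, tol=tol)
    else:
        raise ValueError(f"unknown method: {method}")

    se = np.sqrt(np.clip(np.diag(res.cov), 0, None))
    return VarianceComponents(
        vg=res.theta[:k].copy(),
        ve=float(res.theta[k]),
        se=se,
        cov=res.cov,
        logl=res.logl,
        converged=res.converged,
        n_iter=res.n_iter,
        n=n,
        sources=[g.source if isinstance(g, GRM) else "matrix" for g in grms],
    )


def _eigen_single_fit(y, X, A, theta0, floors):
    """Single-GRM REML optimum through the rotated (diagonal) likelihood."""
    lam, U = eigh(A)
    yt = U.T @ y
    Xt = U.T @ X

    def neglogl(theta):
        vg, ve = theta
        d = vg * lam + ve
        if np.any(d <= 0):
            return np.inf
        Viy = yt / d
        ViX = Xt / d[:, None]
        XtViX = Xt.T @ ViX
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        Xty = Xt.T @ Viy
        ypy = yt @ Viy - Xty @ np.linalg.solve(XtViX, Xty)
        return 0.5 * (np.sum(np.log(d)) + logdet_x + ypy)

    lo = np.where(np.isnan(floors), 1e-12, floors)
    res = optimize.minimize(
        neglogl,
        theta0,
        method="L-BFGS-B",
        bounds=[(lo[0], None), (lo[1], None)],
    )
    return np.asarray(res.x)


def h2_summary(fit: VarianceComponents) -> pd.DataFrame:
    """Per-component and total heritability with delta-method SEs."""
    if fit.vp <= 0:
        raise ValueError("invalid fit: non-positive phenotypic variance")
    rows = []
    for i, src in enumerate(fit.sources):
        rows.append(
            {
                "component": src,
                "variance": fit.vg[i],
                "h2": fit.h2[i],
                "se": fit.h2_se(i),
            }
        )
    rows.append(
        {
            "component": "total",
            "variance": float(np.sum(fit.vg)),
            "h2": fit.h2_total,
            "se": fit.h2_se(None),
        }
    )
    rows.append(
        {
            "component": "residual",
            "variance": fit.ve,
            "h2": fit.ve / fit.vp,
            "se": np.nan,
        }
    )
    return pd.DataFrame(rows)


def fit_residual_only(y, covariates) -> tuple[float, float]:
    """Null (no-GRM) fit: returns (V_e estimate, restricted logL).

    Used as the reference model for heritability LRTs.  The optimum has
    a closed form: V_e = y' M y / (n - p) with M the projection off the
    fixed effects.
    """
    yv, X = _design(y, covariates)
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    resid = yv - Q @ (Q.T @ yv)
    ve = float(resid @ resid) / (n - p)
    logl = restricted_loglik(yv, X, ve * np.eye(n))
    return ve, logl


class LrtResult(NamedTuple):
    stat: float
    p: float


def lrt(logl_full: float, logl_null: float, mixture: bool = False) -> LrtResult:
    """Likelihood-ratio test, optionally with the 50:50 chi0/chi1 boundary mix.

    The statistic is clamped at zero.  With ``mixture=True`` (variance
    component tested at its zero boundary) the p-value is
    ``0.5 * P(chi2_1 >= stat)`` for a positive statistic and 1 otherwise.
    """
    stat = max(0.0, 2.0 * (logl_full - logl_null))
    if stat == 0.0:
        return LrtResult(0.0, 1.0)
    p = stats.chi2.sf(stat, df=1)
    if mixture:
        p = 0.5 * p
    return LrtResult(float(stat), float(p))


# ---------------------------------------------------------------------------
# Bivariate between-sex fit
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    """Between-sex bivariate REML fit on disjoint male/female samples."""

    v_gm: float
    v_gf: float
    c_g: float
    v_em: float
    v_ef: float
    rg_se: float
    cov: np.ndarray           # 5x5 sampling covariance, theta order
    logl: float
    logl_rg1: float
    converged: bool
    converged_rg1: bool
    n_male: int
    n_female: int
    unstable: bool = False

    @property
    def rg(self) -> float:
        return self.c_g / np.sqrt(self.v_gm * self.v_gf)

    @property
    def h2_male(self) -> float:
        return self.v_gm / (self.v_gm + self.v_em)

    @property
    def h2_female(self) -> float:
        return self.v_gf / (self.v_gf + self.v_ef)

    def lrt_rg1(self) -> LrtResult:
        """LRT of the r_g = 1 constraint (plain chi2_1)."""
        return lrt(self.logl, self.logl_rg1, mixture=False)


def _bivariate_components(A: np.ndarray, male: np.ndarray, female: np.ndarray):
    mm = np.outer(male, male)
    ff = np.outer(female, female)
    mf = np.outer(male, female)
    B_gm = A * mm
    B_gf = A * ff
    B_c = A * (mf + mf.T)
    B_em = ("diag", male.astype(float))
    B_ef = ("diag", female.astype(float))
    return [B_gm, B_gf, B_c, B_em, B_ef]


def fit_bivariate(
    y,
    sex,
    covariates,
    grm: GRM | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BivariateFit:
    """Bivariate REML treating the trait in each sex as a separate column.

    ``y`` holds one trait value per sample (aligned with the combined
    GRM); ``sex`` assigns each sample to the male (1) or female (2)
    column.  Because no individual carries both columns, the residual
    cross-covariance is structurally zero and is not estimated.  Fixed
    effects are fitted per column (sex-specific intercept + covariates).
    """
    y = np.asarray(y, dtype=float).ravel()
    sex = np.asarray(sex, dtype=int)
    A = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, float)
    n = len(y)
    if A.shape != (n, n):
        raise ValueError("GRM does not cover all samples")
    male = sex == MALE
    female = sex == FEMALE
    if not (male.any() and female.any()):
        raise ValueError("both sexes are required for a bivariate fit")

    # sex-specific fixed effects: per-column intercept + covariates
    blocks = [male.astype(float)[:, None], female.astype(float)[:, None]]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        blocks.insert(1, C * male[:, None])
        blocks.append(C * female[:, None])
    X = np.column_stack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("fixed-effect design matrix is rank deficient")

    comps = _bivariate_components(A, male, female)
    vm0 = float(np.var(y[male]))
    vf0 = float(np.var(y[female]))

    def dv_fn(theta):
        return _build_v(n, theta, comps), comps

    theta0 = np.array(
        [0.5 * vm0, 0.5 * vf0, 0.25 * np.sqrt(vm0 * vf0), 0.5 * vm0, 0.5 * vf0]
    )
    floor = _FLOOR_FRACTION * 0.5 * (vm0 + vf0)
    floors = np.array([floor, floor, np.nan, floor, floor])
    res = _ai_reml(y, X, dv_fn, theta0, floors, max_iter=max_iter, tol=tol)
    v_gm, v_gf, c_g, v_em, v_ef = res.theta
    unstable = bool(v_gm <= 2 * floor or v_gf <= 2 * floor)

    # r_g SE by the delta method on (V_Gm, V_Gf, C_G)
    rg = c_g / np.sqrt(v_gm * v_gf)
    grad = np.array(
        [-rg / (2 * v_gm), -rg / (2 * v_gf), 1.0 / np.sqrt(v_gm * v_gf), 0.0, 0.0]
    )
    rg_se = float(np.sqrt(max(0.0, grad @ res.cov @ grad)))

    # constrained refit with C_G = sqrt(V_Gm V_Gf)  (r_g = 1)
    B_gm, B_gf, B_c, B_em, B_ef = comps

    def dv_fn_rg1(theta):
        vgm, vgf, vem, vef = theta
        c = np.sqrt(vgm * vgf)
        V = _build_v(n, np.array([vgm, vgf, c, vem, vef]), comps)
        d_vgm = B_gm + 0.5 * np.sqrt(vgf / vgm) * B_c
        d_vgf = B_gf + 0.5 * np.sqrt(vgm / vgf) * B_c
        return V, [d_vgm, d_vgf, B_em, B_ef]

    theta0c = np.array(
        [max(v_gm, floor), max(v_gf, floor), max(v_em, floor), max(v_ef, floor)]
    )
    floors_c = np.full(4, floor)
    res_c = _ai_reml(y, X, dv_fn_rg1, theta0c, floors_c, max_iter=max_iter, tol=tol)

    return BivariateFit(
        v_gm=float(v_gm),
        v_gf=float(v_gf),
        c_g=float(c_g),
        v_em=float(v_em),
        v_ef=float(v_ef),
        rg_se=rg_se,
        cov=res.cov,
        logl=res.logl,
        logl_rg1=res_c.logl,
        converged=res.converged,
        converged_rg1=res_c.converged,
        n_male=int(male.sum()),
        n_female=int(female.sum()),
        unstable=unstable,
    )


def hsq_table(fit: VarianceComponents, lrt_p: float | None = None) -> pd.DataFrame:
    """GCTA ``.hsq``-style result table (Source/Variance/SE rows)."""
    rows = []
    for i, src in enumerate(fit.sources):
        rows.append({"Source": f"V(G{i + 1})_{src}", "Variance": fit.vg[i], "SE": fit.se[i]})
    rows.append({"Source": "V(e)", "Variance": fit.ve, "SE": fit.se[-1]})
    rows.append({"Source": "Vp", "Variance": fit.vp, "SE": np.nan})
    rows.append({"Source": "V(G)/Vp", "Variance": fit.h2_total, "SE": fit.h2_se(None)})
    rows.append({"Source": "logL", "Variance": fit.logl, "SE": np.nan})
    if lrt_p is not None:
        rows.append({"Source": "Pval", "Variance": lrt_p, "SE": np.nan})
    rows.append({"Source": "n", "Variance": fit.n, "SE": np.nan})
    return pd.DataFrame(rows)
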