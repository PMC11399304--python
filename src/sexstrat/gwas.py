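"""Phenotype residualization and sex-stratified per-variant linear association.

Association is ordinary least squares of the (adjusted) trait on allele
dosage plus intercept and covariates, run within one sex group.  Missing
dosages drop samples variant-wise (complete-case, the PLINK behavior).
Two-sided p-values use the t distribution with ``n - k - 2`` degrees of
freedom (k covariates, plus intercept and dosage).  Male X dosages are
coded 0/2 by default (the additive full-dosage-compensation coding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sexstrat.panel import FEMALE, MALE, GenotypePanel

GWAS_COLUMNS = [
    "CHROM", "POS", "ID", "REF", "ALT", "A1",
    "TEST", "OBS_CT", "BETA", "SE", "T_STAT", "P", "STATUS",
]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a maximal independent prefix via QR pivoting on columns
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad or names}"
        )


def residualize(
    pheno,
    covariates=None,
    global_measure=None,
    groups=None,
) -> np.ndarray:
    """Least-squares residuals of the trait on intercept + covariates.

    ``global_measure`` (e.g. total brain volume for a regional volume) is
    appended as one more covariate.  When ``groups`` is given (e.g. the
    sex vector) the regression is fitted within each group separately.
    """
    y = np.asarray(pheno, dtype=float).ravel()
    n = len(y)
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.append(C)
        names += [f"covar{j}" for j in range(C.shape[1])]
    if global_measure is not None:
        cols.append(np.asarray(global_measure, dtype=float).reshape(n, 1))
        names.append("global_measure")
    X = np.column_stack(cols)

    out = np.empty(n)
    if groups is None:
        group_ids = [None]
        masks = [np.ones(n, dtype=bool)]
    else:
        g = np.asarray(groups)
        group_ids = list(np.unique(g))
        masks = [g == gid for gid in group_ids]
    for mask in masks:
        Xg, yg = X[mask], y[mask]
        _check_rank(Xg, names)
        beta, *_ = np.linalg.lstsq(Xg, yg, rcond=None)
        out[mask] = yg - Xg @ beta
    return out


def run_stratified_gwas(
    panel: GenotypePanel,
    trait,
    covariates=None,
    sex_group: str | int = "male",
    male_x_coding: float = 2.0,
) -> pd.DataFrame:
    """Per-variant OLS association within one sex group.

    Returns a PLINK2-style table (one row per variant) with columns
    ``CHROM POS ID REF ALT A1 TEST OBS_CT BETA SE T_STAT P STATUS``.
    Zero-variance dosages are flagged ``untestable`` and perfect fits
    ``exact_fit`` rather than silently dropped.

    ``male_x_coding`` multiplies male raw X calls (0/1); the default 2.0
    matches the additive full-dosage-compensation model.
    """
    code = {"male": MALE, "female": FEMALE, MALE: MALE, FEMALE: FEMALE}[sex_group]
    mask = panel.sex == code
    if not mask.any():
        raise ValueError(f"no samples in sex group {sex_group!r}")
    sub = panel.subset(sample_mask=mask)
    y = np.asarray(trait, dtype=float).ravel()
    if len(y) == panel.n_samples:
        y = y[mask]
    if len(y) != sub.n_samples:
        raise ValueError("trait length matches neither panel nor sex group")

    n = sub.n_samples
    if covariates is None:
        C = np.ones((n, 1))
    else:
        Cc = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Cc.shape[0] == panel.n_samples:
            Cc = Cc[mask]
        elif Cc.shape[1] == panel.n_samples:
            Cc = Cc.T[mask]
        elif Cc.shape[0] != n:
            Cc = Cc.T
        C = np.column_stack([np.ones(n), Cc])
    _check_rank(C, [f"c{j}" for j in range(C.shape[1])])

    G = sub.dosages.copy()
    if code == MALE and sub.is_x.any():
        G[:, sub.is_x] *= male_x_coding

    df_resid = n - C.shape[1] - 1
    if df_resid < 1:
        raise ValueError("not enough samples for the covariate model")

    # residualize trait and complete-data dosage columns on covariates once
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    yy = float(y_res @ y_res)

    complete = ~np.isnan(G).any(axis=0)
    beta = np.full(panel.n_variants, np.nan)
    se = np.full(panel.n_variants, np.nan)
    tstat = np.full(panel.n_variants, np.nan)
    pval = np.full(panel.n_variants, np.nan)
    obs = np.full(panel.n_variants, n)
    status = np.array(["ok"] * panel.n_variants, dtype=object)

    from scipy import stats as sps

    if complete.any():
        Gc = G[:, complete]
        G_res = Gc - Q @ (Q.T @ Gc)
        gg = (G_res**2).sum(axis=0)
        gy = G_res.T @ y_res
        testable = gg > 1e-12
        b = np.divide(gy, gg, out=np.zeros_like(gy), where=testable)
        rss = np.maximum(yy - b * gy, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.sqrt(rss / df_resid / gg)
        idx = np.flatnonzero(complete)
        beta[idx] = np.where(testable, b, np.nan)
        se[idx] = np.where(testable, s, np.nan)
        exact = testable & (rss <= 1e-12 * np.maximum(yy, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b / s
        p = 2 * sps.t.sf(np.abs(t), df_resid)
        tstat[idx] = np.where(testable, t, np.nan)
        pval[idx] = np.where(testable, p, np.nan)
        status[idx[~testable]] = "untestable"
        status[idx[exact]] = "exact_fit"

    # complete-case loop for variants with missing dosages
    for j in np.flatnonzero(~complete):
        g = G[:, j]
        ok = ~np.isnan(g)
        n_j = int(ok.sum())
        obs[j] = n_j
        df_j = n_j - C.shape[1] - 1
        if df_j < 1 or np.nanstd(g) == 0:
            status[j] = "untestable"
            continue
        X = np.column_stack([C[ok], g[ok]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            status[j] = "untestable"
            continue
        coef, rss_arr, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ coef
        rss = float(resid @ resid)
        xtx_inv_last = np.linalg.inv(X.T @ X)[-1, -1]
        beta[j] = coef[-1]
        se[j] = np.sqrt(rss / df_j * xtx_inv_last)
        if rss <= 1e-12 * max(yy, 1.0):
            status[j] = "exact_fit"
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat[j] = beta[j] / se[j]
        pval[j] = 2 * sps.t.sf(abs(tstat[j]), df_j)

    v = panel.variants
    return pd.DataFrame(
        {
            "CHROM": v["chrom"].to_numpy(),
            "POS": v["pos"].to_numpy(),
            "ID": v["id"].to_numpy(),
            "REF": v["a2"].to_numpy(),
            "ALT": v["a1"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "TEST": "ADD",
            "OBS_CT": obs,
            "BETA": beta,
            "SE": se,
            "T_STAT": tstat,
            "P": pval,
            "STATUS": status,
        }
    )
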