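"""Sex-difference statistics.

The central statistic is the difference-of-estimates z score

    z = (est_m - est_f) / sqrt(se_m^2 + se_f^2),    p = 2 (1 - Phi(|z|)),

applied identically to heritability pairs and to per-variant GWAS effect
pairs.  The module also provides Bonferroni threshold arithmetic, paired
t / Wilcoxon tests across regions, the phenotypic sex-difference linear
model (sex coded 0 = female, 1 = male, so positive coefficients mean
higher in males), the V_G-on-V_P nested model comparison, Pearson map
correlation, and the two-tier (relaxed/strict) SNP screen.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from sexstrat.panel import FEMALE, MALE


class DegenerateInputError(ValueError):
    pass


def zdiff(est_m: float, est_f: float, se_m: float, se_f: float):
    """Difference-of-estimates z statistic and two-sided normal p."""
    est_m = np.asarray(est_m, dtype=float)
    est_f = np.asarray(est_f, dtype=float)
    se_m = np.asarray(se_m, dtype=float)
    se_f = np.asarray(se_f, dtype=float)
    if np.any(se_m <= 0) or np.any(se_f <= 0):
        raise ValueError("standard errors must be positive")
    z = (est_m - est_f) / np.sqrt(se_m**2 + se_f**2)
    p = 2 * stats.norm.sf(np.abs(z))
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def mtc_threshold(base_alpha: float, n_tests: int) -> float:
    """Bonferroni-divided significance threshold."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


def round_to_sig(x: float, n_sig: int) -> float:
    """Round to ``n_sig`` significant figures."""
    if x == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(x))))
    return float(round(x, n_sig - 1 - exp))


def trunc_to_sig(x: float, n_sig: int) -> float:
    """Truncate (round toward zero) to ``n_sig`` significant figures."""
    if x == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(x))))
    scale = 10.0 ** (n_sig - 1 - exp)
    return float(np.trunc(x * scale) / scale)


class PairedTestResult(NamedTuple):
    t: float
    df: int
    mean_diff: float
    ci_low: float
    ci_high: float
    p: float
    wilcoxon_p: float


def paired_region_tests(values_m, values_f) -> PairedTestResult:
    """Paired two-tailed t test of (male - female) across regions, with a
    Wilcoxon signed-rank companion and a 95% CI on the mean difference."""
    m = np.asarray(values_m, dtype=float)
    f = np.asarray(values_f, dtype=float)
    if m.shape != f.shape or m.ndim != 1 or len(m) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = m - f
    if np.all(d == 0):
        raise DegenerateInputError("all paired differences are zero")
    n = len(d)
    df = n - 1
    mean = d.mean()
    sem = d.std(ddof=1) / np.sqrt(n)
    t = mean / sem
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * sem
    # exact signed-rank for small n, normal approximation with correction above
    mode = "exact" if n <= 25 else "approx"
    wres = stats.wilcoxon(d[d != 0], mode=mode, correction=(mode == "approx"))
    return PairedTestResult(
        t=float(t),
        df=df,
        mean_diff=float(mean),
        ci_low=float(mean - half),
        ci_high=float(mean + half),
        p=float(p),
        wilcoxon_p=float(wres.pvalue),
    )


class OlsCoef(NamedTuple):
    coef: float
    se: float
    t: float
    p: float


def _ols(y: np.ndarray, X: np.ndarray, names: list) -> pd.DataFrame:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n, k = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"name": names, "coef": coef, "se": se, "t": t, "p": p})


def phenotypic_sexdiff(pheno, sex, age, covariates=None) -> OlsCoef:
    """t statistic of the sex coefficient in
    ``pheno ~ a + b*sex + c*age + d*age^2 + covariates``.

    Sex is recoded female = 0, male = 1, so positive values mean higher
    in males.
    """
    y = np.asarray(pheno, dtype=float).ravel()
    sexv = np.asarray(sex)
    s01 = np.where(sexv == MALE, 1.0, 0.0)
    a = np.asarray(age, dtype=float).ravel()
    cols = [np.ones(len(y)), s01, a, a**2]
    names = ["intercept", "sex", "age", "age2"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        cols.append(C)
        names += [f"covar{j}" for j in range(C.shape[1])]
    table = _ols(y, np.column_stack(cols), names)
    row = table.set_index("name").loc["sex"]
    return OlsCoef(float(row["coef"]), float(row["se"]), float(row["t"]), float(row["p"]))


class VgVpModelFit(NamedTuple):
    model: str                 # "model1" (quadratic) or "model2" (linear)
    coefficients: pd.DataFrame # chosen model's coefficient table
    d: OlsCoef                 # sex x V_P interaction from the chosen model
    f: OlsCoef                 # sex x V_P^2 interaction from model 1
    rss_model1: float
    rss_model2: float


def fit_vg_vp_models(table: pd.DataFrame, alpha: float = 0.05) -> VgVpModelFit:
    """Nested comparison of V_G on V_P with sex interactions.

    Model 1: ``V_G = a + b V_P + c sex + d sex*V_P + e V_P^2 + f sex*V_P^2``;
    Model 2 drops the quadratic terms.  Model 1 is fitted first; if its
    ``f`` coefficient is not significant at ``alpha`` the reported ``d``
    comes from the simpler Model 2.  Sex coded 0 = female, 1 = male.

    ``table`` needs columns ``sex`` (1/2 codes or 0/1), ``v_g``, ``v_p``.
    """
    vg = table["v_g"].to_numpy(dtype=float)
    vp = table["v_p"].to_numpy(dtype=float)
    sexv = table["sex"].to_numpy()
    s01 = np.where(sexv == MALE, 1.0, np.where(sexv == FEMALE, 0.0, sexv)).astype(float)
    if len(vg) < 4:
        raise ValueError("need at least two regions per sex")

    ones = np.ones(len(vg))
    X1 = np.column_stack([ones, vp, s01, s01 * vp, vp**2, s01 * vp**2])
    names1 = ["a", "b", "c", "d", "e", "f"]
    fit1 = _ols(vg, X1, names1)
    r1 = vg - X1 @ fit1["coef"].to_numpy()
    rss1 = float(r1 @ r1)

    X2 = X1[:, :4]
    fit2 = _ols(vg, X2, names1[:4])
    r2 = vg - X2 @ fit2["coef"].to_numpy()
    rss2 = float(r2 @ r2)

    frow = fit1.set_index("name").loc["f"]
    f = OlsCoef(float(frow["coef"]), float(frow["se"]), float(frow["t"]), float(frow["p"]))
    if np.isfinite(f.p) and f.p < alpha:
        chosen, tab = "model1", fit1
    else:
        chosen, tab = "model2", fit2
    drow = tab.set_index("name").loc["d"]
    d = OlsCoef(float(drow["coef"]), float(drow["se"]), float(drow["t"]), float(drow["p"]))
    return VgVpModelFit(
        model=chosen, coefficients=tab, d=d, f=f, rss_model1=rss1, rss_model2=rss2
    )


def correlate_maps(map_a, map_b) -> tuple[float, float]:
    """Pearson correlation of two per-region maps with t-based p."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero variance in one of the maps")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


TIER_NONE, TIER_RELAXED, TIER_STRICT = "none", "relaxed", "strict"


class ScreenReport(NamedTuple):
    records: pd.DataFrame
    n_only_one_sex: int
    n_allele_mismatch: int


def screen_snp_sexdiff(
    records_m: pd.DataFrame,
    records_f: pd.DataFrame,
    strict_n_tests: int,
    relaxed_alpha: float = 5e-8,
) -> ScreenReport:
    """Per-variant sex-difference z screen over two GWAS summary tables.

    Records are joined on ``ID``.  Effect alleles are harmonized: when
    the female record's effect allele (``A1``) equals the male record's
    other allele, the female beta sign is flipped; variants whose allele
    sets do not match are excluded and counted.  Tiers: ``relaxed``
    (p < ``relaxed_alpha``) and ``strict``
    (p < ``relaxed_alpha / strict_n_tests``).
    """
    need = {"ID", "A1", "BETA", "SE"}
    for df in (records_m, records_f):
        if not need.issubset(df.columns):
            raise ValueError(f"summary table needs columns {sorted(need)}")
    m = records_m.set_index("ID")
    f = records_f.set_index("ID")
    common = m.index.intersection(f.index)
    n_only = (len(m) - len(common)) + (len(f) - len(common))
    m = m.loc[common]
    f = f.loc[common]

    beta_f = f["BETA"].to_numpy(dtype=float).copy()
    same = (m["A1"].to_numpy() == f["A1"].to_numpy())
    other_m = m["REF"].to_numpy() if "REF" in m.columns else None
    flippable = np.zeros(len(common), dtype=bool)
    if other_m is not None and "REF" in f.columns:
        flippable = (~same) & (f["A1"].to_numpy() == other_m) & (
            f["REF"].to_numpy() == m["A1"].to_numpy()
        )
    beta_f[flippable] = -beta_f[flippable]
    usable = same | flippable
    n_mismatch = int((~usable).sum())

    sem = m["SE"].to_numpy(dtype=float)
    sef = f["SE"].to_numpy(dtype=float)
    betam = m["BETA"].to_numpy(dtype=float)
    ok = usable & (sem > 0) & (sef > 0) & np.isfinite(betam) & np.isfinite(beta_f)

    z = np.full(len(common), np.nan)
    p = np.full(len(common), np.nan)
    z[ok], p[ok] = zdiff(betam[ok], beta_f[ok], sem[ok], sef[ok])

    strict_alpha = mtc_threshold(relaxed_alpha, strict_n_tests)
    tier = np.where(
        p < strict_alpha, TIER_STRICT, np.where(p < relaxed_alpha, TIER_RELAXED, TIER_NONE)
    )
    tier = np.where(np.isnan(p), TIER_NONE, tier)

    out = pd.DataFrame(
        {
            "ID": common,
            "BETA_M": betam,
            "SE_M": sem,
            "BETA_F": beta_f,
            "SE_F": sef,
            "Z": z,
            "P": p,
            "TIER": tier,
        }
    )
    out = out.loc[usable].reset_index(drop=True)
    return ScreenReport(records=out, n_only_one_sex=int(n_only), n_allele_mismatch=n_mismatch)
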