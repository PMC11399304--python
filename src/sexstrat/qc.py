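"""Variant- and sample-level quality control.

Variant filters run in a fixed, recorded order: biallelic -> MAF -> HWE ->
variant missingness.  X-chromosome variants are evaluated in each sex
separately (HWE in females only, since males are hemizygous) and kept only
if they pass in both sexes.  Sample filters: Euler number, per-sex ICV
outliers (statistics computed on the post-Euler set), genotype missingness,
and a per-sex phenotype SD window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from sexstrat.panel import FEMALE, MALE, GenotypePanel


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds. Defaults follow the heritability-set conventions;
    use ``maf_min=0.001`` for the GWAS set."""

    maf_min: float = 0.0003
    hwe_p_min: float = 1e-6
    variant_missing_max: float = 0.05
    sample_missing_max: float = 0.1
    relatedness_max: float = 0.05
    icv_sd: float = 4.0
    euler_min: float = -217.0
    pheno_sd: float = 5.0
    biallelic_only: bool = True
    info_min: float | None = None  # applied only if an INFO column is supplied

    def __post_init__(self):
        for name in ("maf_min", "variant_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 <= self.hwe_p_min <= 1):
            raise ValueError("hwe_p_min must lie in [0, 1]")


@dataclass
class QcReport:
    """Ordered ledger of applied filters with per-filter removal counts."""

    order: list = field(default_factory=list)
    removed: dict = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def record(self, name: str, count: int) -> None:
        self.order.append(name)
        self.removed[name] = int(count)

    def to_dict(self) -> dict:
        return asdict(self)


def hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against HWE proportions.

    Expectations use the sample allele frequency.  Monomorphic input
    returns ``(0.0, 1.0)``.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Per-variant (n_AA, n_Aa, n_aa) counts, AA = two copies of a1."""
    out = np.zeros((dosages.shape[1], 3), dtype=int)
    out[:, 0] = (dosages == 2).sum(axis=0)
    out[:, 1] = (dosages == 1).sum(axis=0)
    out[:, 2] = (dosages == 0).sum(axis=0)
    return out


def _hwe_p_vector(dosages: np.ndarray) -> np.ndarray:
    """Vectorized per-variant HWE chi-square p (columns = variants)."""
    c = _genotype_counts(dosages).astype(float)
    n = c.sum(axis=1)
    p = np.divide(2 * c[:, 0] + c[:, 1], 2 * n, out=np.zeros_like(n), where=n > 0)
    out = np.ones(len(c))
    poly = (p > 0) & (p < 1)
    if poly.any():
        e = n[poly, None] * np.column_stack(
            [p[poly] ** 2, 2 * p[poly] * (1 - p[poly]), (1 - p[poly]) ** 2]
        )
        chi2 = ((c[poly] - e) ** 2 / e).sum(axis=1)
        out[poly] = stats.chi2.sf(chi2, df=1)
    return out


def _maf(panel: GenotypePanel, sample_mask=None) -> np.ndarray:
    p = panel.allele_freq(sample_mask)
    return np.minimum(p, 1 - p)


def filter_variants(
    panel: GenotypePanel,
    thresholds: QcThresholds = QcThresholds(),
    per_sex_x: bool = True,
) -> tuple[GenotypePanel, QcReport]:
    """Apply the variant filter ledger; returns the filtered panel and report.

    With ``per_sex_x`` the X-chromosome filters (MAF, HWE in females,
    missingness) are evaluated in each sex separately and a variant is
    kept only if it passes in both.
    """
    report = QcReport(n_in=panel.n_variants)
    keep = np.ones(panel.n_variants, dtype=bool)
    is_x = panel.is_x
    male = panel.is_male
    female = panel.is_female
    have_both = male.any() and female.any()

    # 1. biallelic
    if thresholds.biallelic_only and "n_alleles" in panel.variants.columns:
        fail = panel.variants["n_alleles"].to_numpy() > 2
        report.record("biallelic", np.sum(fail & keep))
        keep &= ~fail
    else:
        report.record("biallelic", 0)

    # optional imputation INFO pass-through (never computed)
    if thresholds.info_min is not None and "info" in panel.variants.columns:
        fail = panel.variants["info"].to_numpy(dtype=float) < thresholds.info_min
        report.record("info", np.sum(fail & keep))
        keep &= ~fail

    # 2. MAF (X: per sex when requested, pass required in both)
    maf_all = _maf(panel)
    fail = maf_all < thresholds.maf_min
    if per_sex_x and is_x.any() and have_both:
        maf_m = _maf(panel, male)
        maf_f = _maf(panel, female)
        fail_x = (maf_m < thresholds.maf_min) | (maf_f < thresholds.maf_min)
        fail = np.where(is_x, fail_x, fail)
    report.record("maf", np.sum(fail & keep))
    keep &= ~fail

    # 3. HWE (X: females only)
    hwe_p = np.ones(panel.n_variants)
    auto = ~is_x
    if auto.any():
        hwe_p[auto] = _hwe_p_vector(panel.dosages[:, auto])
    if is_x.any() and female.any():
        hwe_p[is_x] = _hwe_p_vector(panel.dosages[np.ix_(female, is_x)])
    fail = hwe_p < thresholds.hwe_p_min
    report.record("hwe", np.sum(fail & keep))
    keep &= ~fail

    # 4. variant missingness (X: per sex when requested)
    miss = panel.variant_missing_rate()
    fail = miss > thresholds.variant_missing_max
    if per_sex_x and is_x.any() and have_both:
        miss_m = panel.missing_mask[male].mean(axis=0)
        miss_f = panel.missing_mask[female].mean(axis=0)
        fail_x = (miss_m > thresholds.variant_missing_max) | (
            miss_f > thresholds.variant_missing_max
        )
        fail = np.where(is_x, fail_x, fail)
    report.record("variant_missingness", np.sum(fail & keep))
    keep &= ~fail

    report.n_out = int(keep.sum())
    return panel.subset(variant_mask=keep), report


def filter_samples(
    pheno: pd.DataFrame,
    panel: GenotypePanel | None,
    thresholds: QcThresholds = QcThresholds(),
    pheno_cols: list | None = None,
    icv_col: str = "icv",
    euler_col: str = "euler",
) -> tuple[list, QcReport]:
    """Sample-level filters; returns kept sample ids and a report.

    Order: Euler image-quality cut; per-sex ICV outliers (mean/SD on the
    post-Euler set); genotype missingness (if a panel is given); per-sex
    phenotype SD window over ``pheno_cols`` (a sample is dropped if *any*
    listed phenotype falls outside the window).
    """
    df = pheno.copy()
    if "IID" not in df.columns or "sex" not in df.columns:
        raise ValueError("phenotype table must have IID and sex columns")
    report = QcReport(n_in=len(df))
    keep = np.ones(len(df), dtype=bool)
    sex = df["sex"].to_numpy()

    if euler_col in df.columns:
        fail = df[euler_col].to_numpy(dtype=float) < thresholds.euler_min
        report.record("euler", np.sum(fail & keep))
        keep &= ~fail
    else:
        report.record("euler", 0)

    if icv_col in df.columns:
        icv = df[icv_col].to_numpy(dtype=float)
        fail = np.zeros(len(df), dtype=bool)
        for code in (MALE, FEMALE):
            grp = (sex == code) & keep
            if grp.sum() < 2:
                continue
            mu, sd = icv[grp].mean(), icv[grp].std()
            if sd > 0:
                fail |= (sex == code) & (np.abs(icv - mu) > thresholds.icv_sd * sd)
        report.record("icv", np.sum(fail & keep))
        keep &= ~fail
    else:
        report.record("icv", 0)

    if panel is not None:
        rate = dict(zip(panel.sample_ids, panel.sample_missing_rate()))
        miss = df["IID"].map(rate).to_numpy(dtype=float)
        fail = np.nan_to_num(miss) > thresholds.sample_missing_max
        report.record("sample_missingness", np.sum(fail & keep))
        keep &= ~fail
    else:
        report.record("sample_missingness", 0)

    if pheno_cols:
        missing = [c for c in pheno_cols if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype columns absent from table: {missing}")
        fail = np.zeros(len(df), dtype=bool)
        for col in pheno_cols:
            v = df[col].to_numpy(dtype=float)
            for code in (MALE, FEMALE):
                grp = (sex == code) & keep
                if grp.sum() < 2:
                    continue
                mu, sd = v[grp].mean(), v[grp].std()
                if sd > 0:
                    fail |= (sex == code) & (np.abs(v - mu) > thresholds.pheno_sd * sd)
        report.record("phenotype_sd", np.sum(fail & keep))
        keep &= ~fail
    else:
        report.record("phenotype_sd", 0)

    report.n_out = int(keep.sum())
    return df.loc[keep, "IID"].tolist(), report
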