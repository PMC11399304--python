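"""Simulation of genotypes, sex-stratified polygenic phenotypes, and
spherical multi-region phenotype panels with known ground truth.

Every downstream stage of the pipeline (QC, GRM construction, REML,
stratified GWAS, sex-difference screening, spatial enrichment) can be
exercised end-to-end on the output of this module, with the generating
architecture recorded in a :class:`SimulationTruth` for recovery tests.

Conventions
-----------
* Genotypes are sampled per variant under Hardy-Weinberg equilibrium at a
  frequency drawn uniformly from ``[maf_low, maf_high]``.
* Genetic values are computed on per-variant standardized dosages so the
  heritability target is exact in expectation at any allele frequency; the
  realized genetic value is then rescaled by its sample SD so the realized
  variance fraction matches the target exactly.
* Causal effect pairs (beta_m, beta_f) are i.i.d. bivariate normal with
  correlation ``rg`` — the additive infinitesimal model REML assumes.
* Male X genetic values use the dosage coding of the declared
  dosage-compensation model (recorded in the truth object).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexstrat.grm import DcModel
from sexstrat.panel import FEMALE, MALE, X_CHROM, GenotypePanel


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Genotype-simulation parameters."""

    n_male: int
    n_female: int
    m_auto: int
    m_x: int = 0
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise InvalidConfigError("sample counts must be non-negative")
        if self.n_male + self.n_female < 1:
            raise InvalidConfigError("at least one sample required")
        if self.m_auto + self.m_x < 1:
            raise InvalidConfigError("at least one variant required")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise InvalidConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise InvalidConfigError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Phenotype genetic-architecture targets.

    ``covariate_effects`` maps covariate name -> slope; covariates are
    generated as independent standard normals and added with the stated
    slopes.  ``mean_sex_gap`` is added to the male group.
    """

    h2_male: float = 0.4
    h2_female: float = 0.4
    rg: float = 1.0
    n_causal: int = 100
    mean_sex_gap: float = 0.0
    covariate_effects: tuple = ()
    noise_sd: float | None = None  # default sqrt(1 - h2) per sex
    dc_model: DcModel = DcModel.FDC

    def validate(self, n_variants: int) -> None:
        for h2 in (self.h2_male, self.h2_female):
            if not (0 <= h2 < 1) and not (h2 == 1 and self.noise_sd == 0):
                raise InvalidConfigError(
                    "heritability targets must lie in [0, 1); h2 = 1 is only "
                    "valid with an explicit zero noise request"
                )
        if not (-1 <= self.rg <= 1):
            raise InvalidConfigError("rg must lie in [-1, 1]")
        if self.n_causal < 1 or self.n_causal > n_variants:
            raise InvalidConfigError("n_causal must lie in [1, n_variants]")


@dataclass
class SimulationTruth:
    """Record of the generating architecture, sufficient to recompute the
    genetic values exactly."""

    causal_indices: np.ndarray
    beta_male: np.ndarray
    beta_female: np.ndarray
    h2_male: float
    h2_female: float
    rg: float
    seed: int
    dc_model: str = "fdc"
    scale_male: float = 1.0
    scale_female: float = 1.0
    injected: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "causal_indices": self.causal_indices.tolist(),
            "beta_male": self.beta_male.tolist(),
            "beta_female": self.beta_female.tolist(),
            "h2_male": self.h2_male,
            "h2_female": self.h2_female,
            "rg": self.rg,
            "seed": self.seed,
            "dc_model": self.dc_model,
            "scale_male": self.scale_male,
            "scale_female": self.scale_female,
            "injected": self.injected,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Sample a genotype panel under HWE.

    Autosomal and female-X dosages are binomial(2, p); male-X raw values
    are Bernoulli(p).  Missing entries are masked completely at random at
    ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_male + config.n_female
    m = config.m_auto + config.m_x
    sex = np.concatenate(
        [np.full(config.n_male, MALE), np.full(config.n_female, FEMALE)]
    )
    p = rng.uniform(config.maf_low, config.maf_high, size=m)

    dosages = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    if config.m_x > 0 and config.n_male > 0:
        x_cols = np.arange(config.m_auto, m)
        male_rows = np.arange(config.n_male)
        dosages[np.ix_(male_rows, x_cols)] = rng.binomial(
            1, p[x_cols][None, :], size=(config.n_male, config.m_x)
        )
    if config.missing_rate > 0:
        mask = rng.random(size=(n, m)) < config.missing_rate
        dosages[mask] = np.nan

    chrom = np.concatenate(
        [np.ones(config.m_auto, dtype=int), np.full(config.m_x, X_CHROM)]
    )
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
            "true_freq": p,
        }
    )
    sample_ids = [f"M{i}" for i in range(config.n_male)] + [
        f"F{i}" for i in range(config.n_female)
    ]
    return GenotypePanel(
        dosages=dosages, sex=sex, sample_ids=sample_ids, variants=variants
    )


def _standardized_dosages(panel: GenotypePanel, dc_model: DcModel) -> np.ndarray:
    """Per-variant standardized dosages with missing entries set to 0.

    Autosomes: empirical mean/SD standardization.  X variants: female
    dosages standardized on the female scale; male raw values coded per
    ``dc_model`` on the shared female-variance scale (see grm module).
    """
    from sexstrat.grm import _x_standardized

    Z = np.zeros_like(panel.dosages)
    is_x = panel.is_x
    auto = ~is_x
    if auto.any():
        d = panel.dosages[:, auto]
        mu = np.nanmean(d, axis=0)
        sd = np.nanstd(d, axis=0)
        sd[sd == 0] = np.inf  # monomorphic -> zero contribution
        Z[:, auto] = np.nan_to_num((d - mu) / sd)
    if is_x.any():
        Z[:, is_x] = _x_standardized(panel, dc_model)
    return Z


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: GenotypePanel,
    arch: ArchitectureSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate per-sex polygenic phenotypes with known architecture.

    Returns a phenotype table (``IID, sex, pheno`` + covariate columns)
    aligned with panel sample order, and the generating truth.
    """
    arch.validate(panel.n_variants)
    if (arch.h2_male != arch.h2_female or arch.rg < 1) and not (
        panel.is_male.any() and panel.is_female.any()
    ):
        raise InvalidConfigError(
            "sex-differentiated architecture requires both sexes in the panel"
        )
    rng = np.random.default_rng(seed)
    n = panel.n_samples

    causal = np.sort(
        rng.choice(panel.n_variants, size=arch.n_causal, replace=False)
    )
    cov = np.array([[1.0, arch.rg], [arch.rg, 1.0]])
    # sqrt-factor draw keeps rg = +/-1 exactly degenerate
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2)) if abs(arch.rg) < 1 else None
    raw = rng.standard_normal(size=(arch.n_causal, 2))
    if L is not None:
        betas = raw @ L.T
    else:
        b = raw[:, 0]
        betas = np.column_stack([b, np.sign(arch.rg) * b])
    beta_m, beta_f = betas[:, 0].copy(), betas[:, 1].copy()

    Z = _standardized_dosages(panel, arch.dc_model)[:, causal]
    g = np.zeros(n)
    scale = {MALE: 1.0, MALE + FEMALE: 1.0}
    scales = {}
    for sex_code, h2, beta in (
        (MALE, arch.h2_male, beta_m),
        (FEMALE, arch.h2_female, beta_f),
    ):
        grp = panel.sex == sex_code
        if not grp.any():
            scales[sex_code] = 0.0
            continue
        if h2 == 0:
            scales[sex_code] = 0.0
            continue
        gv = Z[grp] @ beta
        sd = gv.std()
        if sd == 0:
            scales[sex_code] = 0.0
            continue
        s = np.sqrt(h2) / sd
        g[grp] = gv * s
        scales[sex_code] = s

    noise_sd = np.zeros(n)
    for sex_code, h2 in ((MALE, arch.h2_male), (FEMALE, arch.h2_female)):
        grp = panel.sex == sex_code
        noise_sd[grp] = (
            arch.noise_sd if arch.noise_sd is not None else np.sqrt(1.0 - h2)
        )
    e = rng.standard_normal(n) * noise_sd

    y = g + e
    y[panel.is_male] += arch.mean_sex_gap

    table = pd.DataFrame(
        {"IID": panel.sample_ids, "sex": panel.sex, "pheno": y}
    )
    for name, slope in arch.covariate_effects:
        c = rng.standard_normal(n)
        table[name] = c
        table["pheno"] = table["pheno"] + slope * c

    truth = SimulationTruth(
        causal_indices=causal,
        beta_male=beta_m,
        beta_female=beta_f,
        h2_male=arch.h2_male,
        h2_female=arch.h2_female,
        rg=arch.rg,
        seed=seed,
        dc_model=arch.dc_model.value,
        scale_male=scales.get(MALE, 0.0),
        scale_female=scales.get(FEMALE, 0.0),
    )
    return table, truth


def inject_sexdiff_snp(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    variant_index: int,
    beta_m: float,
    beta_f: float,
    truth: SimulationTruth | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Add a sex-differentiated per-dosage effect of one variant.

    Adds ``beta_m * dosage`` to male phenotypes and ``beta_f * dosage``
    to female phenotypes (missing dosages imputed at the variant mean).
    A warning flag is recorded if the variant is monomorphic in either
    sex — the downstream screen then has no power.
    """
    if not (0 <= variant_index < panel.n_variants):
        raise IndexError("variant_index out of range")
    if not (np.isfinite(beta_m) and np.isfinite(beta_f)):
        raise ValueError("effects must be finite")
    if truth is None:
        truth = SimulationTruth(
            causal_indices=np.array([], dtype=int),
            beta_male=np.array([]),
            beta_female=np.array([]),
            h2_male=0.0,
            h2_female=0.0,
            rg=1.0,
            seed=-1,
        )
    d = panel.dosages[:, variant_index].copy()
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d), d)
    for sex_code, label in ((MALE, "male"), (FEMALE, "female")):
        grp = panel.sex == sex_code
        if grp.any() and np.nanstd(panel.dosages[grp, variant_index]) == 0:
            msg = f"variant {variant_index} is monomorphic in the {label} group"
            truth.warnings.append(msg)
            warnings.warn(msg)
    out = pheno.copy()
    y = out["pheno"].to_numpy(dtype=float)
    y = y + np.where(panel.sex == MALE, beta_m, 0.0) * d
    y = y + np.where(panel.sex == FEMALE, beta_f, 0.0) * d
    out["pheno"] = y
    truth.injected.append(
        {"variant_index": int(variant_index), "beta_m": beta_m, "beta_f": beta_f}
    )
    return out, truth


# ---------------------------------------------------------------------------
# Spherical region panels
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform lattice of ``n`` points on the unit sphere."""
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def simulate_region_panel(
    n_regions: int,
    n_networks: int,
    h2_profile,
    seed: int = 0,
    panel: GenotypePanel | None = None,
    arch_kwargs: dict | None = None,
):
    """Simulate a multi-region phenotype panel on mirrored hemisphere spheres.

    Each hemisphere is its own unit sphere (as in surface-based brain
    parcellations): left-hemisphere centroids come from a deterministic
    Fibonacci lattice and right-hemisphere centroids are their mirror
    images (x negated).  Network labels are assigned by nearest of
    ``n_networks`` seed directions (mirrored across hemispheres).

    Parameters
    ----------
    h2_profile
        Scalar or length-``n_regions`` sequence of per-region heritability
        targets (applied to both sexes).
    panel
        Optional genotype panel to simulate phenotypes from; a small
        default panel is generated when omitted.

    Returns
    -------
    (phenotypes, annotations)
        ``phenotypes`` is a list of phenotype tables, one per region;
        ``annotations`` is a data frame with columns
        ``region_id, hemi, x, y, z, network``.
    """
    if not (1 <= n_networks <= n_regions):
        raise InvalidConfigError("need n_regions >= n_networks >= 1")
    h2 = np.broadcast_to(np.asarray(h2_profile, dtype=float), (n_regions,))
    rng = np.random.default_rng(seed)

    n_left = (n_regions + 1) // 2
    n_right = n_regions - n_left
    left = _fibonacci_sphere(n_left)
    right = left[:n_right] * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemi = np.array(["L"] * n_left + ["R"] * n_right)

    seeds = rng.standard_normal((n_networks, 3))
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    labels = np.empty(n_regions, dtype=int)
    for h, flip in (("L", 1.0), ("R", -1.0)):
        mask = hemi == h
        s = seeds * np.array([flip, 1.0, 1.0])
        labels[mask] = np.argmax(centroids[mask] @ s.T, axis=1) + 1

    annotations = pd.DataFrame(
        {
            "region_id": [f"R{i}" for i in range(n_regions)],
            "hemi": hemi,
            "x": centroids[:, 0],
            "y": centroids[:, 1],
            "z": centroids[:, 2],
            "network": labels,
        }
    )

    if panel is None:
        panel = simulate_genotypes(
            SimulationConfig(
                n_male=200, n_female=200, m_auto=500, seed=rng.integers(2**31)
            )
        )
    kwargs = dict(arch_kwargs or {})
    kwargs.setdefault("n_causal", min(100, panel.n_variants))
    phenos = []
    for r in range(n_regions):
        arch = ArchitectureSpec(h2_male=h2[r], h2_female=h2[r], **kwargs)
        tab, _ = simulate_phenotypes(panel, arch, seed=int(rng.integers(2**31)))
        phenos.append(tab)
    return phenos, annotations
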