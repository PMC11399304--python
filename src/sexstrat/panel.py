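"""Genotype panel container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: chromosome code used for the X chromosome (PLINK convention)
X_CHROM = 23

MALE = 1
FEMALE = 2

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with sex codes and variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of counted-allele (a1)
        dosages.  Autosomal and female-X entries lie in ``{0, 1, 2}``;
        male X entries are raw hemizygous calls in ``{0, 1}``.  Missing
        genotypes are ``NaN``.
    sex
        ``(n_samples,)`` integer array, 1 = male, 2 = female.
    sample_ids
        Sample identifiers, one per row.
    variants
        Data frame with columns ``id, chrom, pos, a1, a2`` (and optionally
        ``n_alleles`` or ``info``), one row per dosage column.  X variants
        carry ``chrom == 23``.
    """

    dosages: np.ndarray
    sex: np.ndarray
    sample_ids: list = field(default_factory=list)
    variants: pd.DataFrame = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sex) != n:
            raise ValueError("sex vector length does not match sample count")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if self.variants is None:
            self.variants = pd.DataFrame(
                {
                    "id": [f"v{j}" for j in range(m)],
                    "chrom": np.ones(m, dtype=int),
                    "pos": np.arange(1, m + 1),
                    "a1": ["A"] * m,
                    "a2": ["G"] * m,
                }
            )
        if len(self.variants) != m:
            raise ValueError("variant table length does not match dosage columns")

    # -- basic shape helpers ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_x(self) -> np.ndarray:
        """Boolean mask over variants: True for X-chromosome variants."""
        return (self.variants["chrom"].to_numpy() == X_CHROM)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    # -- statistics ---------------------------------------------------------

    def allele_freq(self, sample_mask: np.ndarray | None = None) -> np.ndarray:
        """Counted-allele (a1) frequency per variant.

        Ploidy aware: male X genotypes contribute a single allele, all
        other genotypes two.  Computed over non-missing entries of the
        selected samples (all samples by default).
        """
        if sample_mask is None:
            sample_mask = np.ones(self.n_samples, dtype=bool)
        d = self.dosages[sample_mask]
        male = self.is_male[sample_mask]
        obs = ~np.isnan(d)
        # ploidy per (sample, variant): 1 for male x X, else 2
        ploidy = np.full(d.shape, 2.0)
        if self.is_x.any() and male.any():
            ploidy[np.ix_(male, self.is_x)] = 1.0
        counts = np.where(obs, np.nan_to_num(d), 0.0).sum(axis=0)
        denom = np.where(obs, ploidy, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / denom
        return p

    def variant_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    # -- subsetting ---------------------------------------------------------

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given sample/variant masks."""
        sm = (
            np.ones(self.n_samples, dtype=bool)
            if sample_mask is None
            else np.asarray(sample_mask)
        )
        vm = (
            np.ones(self.n_variants, dtype=bool)
            if variant_mask is None
            else np.asarray(variant_mask)
        )
        if sm.dtype != bool:
            tmp = np.zeros(self.n_samples, dtype=bool)
            tmp[sm] = True
            sm = tmp
        if vm.dtype != bool:
            tmp = np.zeros(self.n_variants, dtype=bool)
            tmp[vm] = True
            vm = tmp
        return GenotypePanel(
            dosages=self.dosages[np.ix_(sm, vm)].copy(),
            sex=self.sex[sm].copy(),
            sample_ids=[s for s, keep in zip(self.sample_ids, sm) if keep],
            variants=self.variants.loc[vm].reset_index(drop=True).copy(),
        )

    def select_samples(self, ids) -> "GenotypePanel":
        """Subset by an iterable of sample ids, preserving panel order."""
        wanted = set(ids)
        mask = np.array([s in wanted for s in self.sample_ids])
        return self.subset(sample_mask=mask)
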