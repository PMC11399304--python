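"""Genetic relationship matrices: autosomal, X-chromosome dosage-compensation
codings, and relatedness pruning.

The estimator is the per-variant-standardized average (the GCTA default):
entry (j, k) is the mean over usable variants of
``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))`` with ``p_i`` the sample
allele frequency.  Missing genotypes are excluded pairwise, with per-pair
variant counts kept alongside the matrix.

X-chromosome codings place male hemizygous calls on the female variance
scale so the relative male/female weighting differs by model:

========  ==========================  ======================
model     male coded value            male coded variance
========  ==========================  ======================
FDC       ``(2x - 2p)/s``             2
NDC       ``(x - p)/s``               1/2
EV        ``sqrt(2)(x - p)/s``        1
========  ==========================  ======================

with ``s = sqrt(2 p (1 - p))`` (the female per-variant SD under HWE) and
``x`` the raw hemizygous call in {0, 1}.  Female coded values are
``(x - 2p)/s`` under every model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sexstrat.panel import GenotypePanel


class DcModel(str, enum.Enum):
    """X-chromosome dosage-compensation coding."""

    FDC = "fdc"  # full dosage compensation: male allele effect doubled
    NDC = "ndc"  # no dosage compensation: male allele effect as-is
    EV = "ev"    # equal variance: male scaled to the female per-variant variance


#: deterministic preference order used to break likelihood ties
DC_PREFERENCE = (DcModel.FDC, DcModel.EV, DcModel.NDC)


class EmptyGrmError(ValueError):
    """No polymorphic variants available to build a GRM."""


@dataclass
class GRM:
    """Symmetric relatedness matrix with per-pair SNP counts."""

    sample_ids: list
    matrix: np.ndarray
    n_snps: np.ndarray
    source: str = "autosomal"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.n_snps = np.asarray(self.n_snps, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        if not np.isfinite(self.matrix).all():
            raise ValueError("GRM entries must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def align(self, ids) -> "GRM":
        """Return the GRM restricted/reordered to the given sample ids."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([index[s] for s in ids])
        return GRM(
            sample_ids=list(ids),
            matrix=self.matrix[np.ix_(idx, idx)].copy(),
            n_snps=self.n_snps[np.ix_(idx, idx)].copy(),
            source=self.source,
        )


def _pairwise_average(W: np.ndarray, observed: np.ndarray):
    """Mean of products over pairwise-complete variants.

    ``W`` holds standardized dosages with missing entries set to 0 so
    they contribute nothing to the numerator; ``observed`` is the 0/1
    non-missing indicator giving the per-pair denominators.
    """
    num = W @ W.T
    if observed.all():
        m = W.shape[1]
        counts = np.full(num.shape, float(m))
        mat = num / m
    else:
        counts = observed @ observed.T
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(counts > 0, num / np.maximum(counts, 1), 0.0)
    mat = (mat + mat.T) / 2  # enforce exact symmetry
    return mat, counts


def autosomal_grm(
    panel: GenotypePanel, sample_subset: np.ndarray | None = None
) -> GRM:
    """GCTA-style autosomal GRM on the given sample subset.

    Allele frequencies for standardization are computed on the analysis
    subset.  Monomorphic variants are excluded.
    """
    sub = panel if sample_subset is None else panel.subset(sample_mask=sample_subset)
    auto = ~sub.is_x
    sub = sub.subset(variant_mask=auto)
    if sub.n_samples < 2:
        raise ValueError("need at least 2 samples")
    p = sub.allele_freq()
    with np.errstate(all="ignore"):
        sd = np.nanstd(sub.dosages, axis=0)
    poly = np.isfinite(p) & (p > 0) & (p < 1) & (sd > 0)
    if not poly.any():
        raise EmptyGrmError("no polymorphic autosomal variants")
    sub = sub.subset(variant_mask=poly)
    p = p[poly]
    d = sub.dosages
    obs = (~np.isnan(d)).astype(float)
    W = np.nan_to_num((d - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :])
    W[obs == 0] = 0.0
    mat, counts = _pairwise_average(W, obs)
    return GRM(
        sample_ids=list(sub.sample_ids), matrix=mat, n_snps=counts, source="autosomal"
    )


def _x_standardized(panel: GenotypePanel, dc_model: DcModel) -> np.ndarray:
    """Standardized X dosages (missing -> 0) under a dosage-compensation model.

    Returns an array over X variants only; monomorphic variants come back
    as all-zero columns.
    """
    is_x = panel.is_x
    d = panel.dosages[:, is_x]
    p = panel.allele_freq()[is_x]
    ok = np.isfinite(p) & (p > 0) & (p < 1)
    s = np.where(ok, np.sqrt(2 * np.clip(p, 1e-12, None) * (1 - np.clip(p, None, 1 - 1e-12))), np.inf)
    male = panel.is_male
    Z = np.empty_like(d)
    Z[~male] = (d[~male] - 2 * p[None, :]) / s[None, :]
    if dc_model == DcModel.FDC:
        Z[male] = (2 * d[male] - 2 * p[None, :]) / s[None, :]
    elif dc_model == DcModel.NDC:
        Z[male] = (d[male] - p[None, :]) / s[None, :]
    elif dc_model == DcModel.EV:
        Z[male] = np.sqrt(2) * (d[male] - p[None, :]) / s[None, :]
    else:  # pragma: no cover
        raise ValueError(f"unknown dosage-compensation model: {dc_model}")
    Z[:, ~ok] = 0.0
    return np.nan_to_num(Z)


def x_grm(
    panel: GenotypePanel,
    dc_model: DcModel,
    sample_subset: np.ndarray | None = None,
) -> GRM:
    """X-chromosome GRM under the given dosage-compensation coding."""
    if dc_model is None:
        raise ValueError("a dosage-compensation model is required")
    dc_model = DcModel(dc_model)
    sub = panel if sample_subset is None else panel.subset(sample_mask=sample_subset)
    if not sub.is_x.any():
        raise EmptyGrmError("panel has no X variants")
    p = sub.allele_freq()[sub.is_x]
    with np.errstate(all="ignore"):
        sd = np.nanstd(sub.dosages[:, sub.is_x], axis=0)
    poly = np.isfinite(p) & (p > 0) & (p < 1) & (sd > 0)
    if not poly.any():
        raise EmptyGrmError("no polymorphic X variants")
    Z = _x_standardized(sub, dc_model)[:, poly]
    obs = (~np.isnan(sub.dosages[:, sub.is_x][:, poly])).astype(float)
    Z = np.where(obs > 0, Z, 0.0)
    mat, counts = _pairwise_average(Z, obs)
    return GRM(
        sample_ids=list(sub.sample_ids),
        matrix=mat,
        n_snps=counts,
        source=f"X:{dc_model.value}",
    )


def select_dc_model(
    y: np.ndarray,
    covariates: np.ndarray | None,
    auto_grm: GRM,
    x_grms: dict,
) -> tuple[DcModel, pd.DataFrame]:
    """Choose the X dosage-compensation coding by REML log-likelihood.

    Fits the joint autosome + X REML under each supplied coding and
    returns the model with the highest restricted log-likelihood; ties
    (within 1e-6) are broken by the declared order FDC > EV > NDC.
    """
    from sexstrat.reml import fit_reml

    rows = []
    fits = {}
    for model in DC_PREFERENCE:
        if model not in x_grms and model.value not in x_grms:
            continue
        xg = x_grms.get(model, x_grms.get(model.value))
        try:
            fit = fit_reml(y, covariates, [auto_grm, xg])
            rows.append(
                {
                    "dc_model": model.value,
                    "logL": fit.logl,
                    "converged": fit.converged,
                    "h2_x": fit.h2[1],
                }
            )
            if fit.converged:
                fits[model] = fit.logl
        except Exception as exc:  # non-convergence propagates as NaN row
            rows.append(
                {
                    "dc_model": model.value,
                    "logL": np.nan,
                    "converged": False,
                    "h2_x": np.nan,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    if not fits:
        raise RuntimeError("REML did not converge under any dosage-compensation model")
    best_logl = max(fits.values())
    for model in DC_PREFERENCE:
        if model in fits and fits[model] >= best_logl - 1e-6:
            return model, table
    raise AssertionError("unreachable")  # pragma: no cover


def prune_relatedness(grm: GRM, threshold: float = 0.05) -> list:
    """Greedy removal of one member of each pair above ``threshold``.

    Repeatedly removes the sample with the most remaining above-threshold
    partners (ties broken by sample-id sort order) until no off-diagonal
    entry among the kept samples exceeds the threshold.  Returns the kept
    sample ids in panel order.
    """
    n = grm.n_samples
    adj = grm.matrix > threshold
    np.fill_diagonal(adj, False)
    adj = adj.copy()
    removed = np.zeros(n, dtype=bool)
    order = np.argsort(np.asarray(grm.sample_ids, dtype=object))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    while True:
        deg = adj.sum(axis=1)
        deg[removed] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        victim = worst[np.argmin(rank[worst])]
        removed[victim] = True
        adj[victim, :] = False
        adj[:, victim] = False
    return [s for s, r in zip(grm.sample_ids, removed) if not r]
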