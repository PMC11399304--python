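"""Readers and writers for PLINK1 triplets, GCTA GRM triplets, and TSVs.

The binary formats are deliberately minimal re-implementations of the two
fixed layouts this pipeline needs to interoperate with:

* PLINK1 ``.bed/.bim/.fam`` — SNP-major 2-bit genotype codes.
* GCTA ``.grm.bin/.grm.N.bin/.grm.id`` — little-endian float32 lower
  triangle (diagonal included, row-major).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from sexstrat.panel import GenotypePanel, X_CHROM

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes for a1-allele dosage, SNP-major
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


# ---------------------------------------------------------------------------
# PLINK1 binary triplet
# ---------------------------------------------------------------------------

def write_plink(panel: GenotypePanel, prefix: str) -> None:
    """Write a panel as ``prefix.bed/.bim/.fam``.

    Male X hemizygous calls (raw 0/1) are stored as the corresponding
    homozygote (0/2), the PLINK convention; they are restored to 0/1 on
    read using the ``.fam`` sex column and ``chrom == 23``.
    """
    n, m = panel.n_samples, panel.n_variants
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": panel.sex,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "id": panel.variants["id"],
            "cm": 0,
            "pos": panel.variants["pos"],
            "a1": panel.variants["a1"],
            "a2": panel.variants["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    stored = panel.dosages.copy()
    hemi = np.ix_(panel.is_male, panel.is_x)
    stored[hemi] = stored[hemi] * 2.0  # hemizygous -> homozygote code

    n_bytes = (n + 3) // 4
    out = np.empty((m, n_bytes), dtype=np.uint8)
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing by default
    col = stored.T  # SNP-major
    for val, code in _DOSAGE_TO_CODE.items():
        codes[col == val] = code
    # pack 4 samples per byte, sample 0 in the lowest 2 bits
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    out[:] = packed
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_plink(prefix: str) -> GenotypePanel:
    """Read ``prefix.bed/.bim/.fam`` into a :class:`GenotypePanel`."""
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    unpacked = np.empty((m, n_bytes * 4), dtype=np.uint8)
    unpacked[:, 0::4] = raw & 0b11
    unpacked[:, 1::4] = (raw >> 2) & 0b11
    unpacked[:, 2::4] = (raw >> 4) & 0b11
    unpacked[:, 3::4] = (raw >> 6) & 0b11
    codes = unpacked[:, :n]
    dosages = np.empty((m, n), dtype=float)
    for code, val in _CODE_TO_DOSAGE.items():
        dosages[codes == code] = val
    dosages = dosages.T.copy()

    sex = fam["sex"].to_numpy(dtype=int)
    is_x = bim["chrom"].to_numpy() == X_CHROM
    if is_x.any():
        male = sex == 1
        block = dosages[np.ix_(male, is_x)]
        block[block == 1.0] = np.nan  # heterozygous male X is undefined
        dosages[np.ix_(male, is_x)] = block / 2.0

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    return GenotypePanel(
        dosages=dosages,
        sex=sex,
        sample_ids=fam["iid"].tolist(),
        variants=variants,
    )


# ---------------------------------------------------------------------------
# Dosage TSV (variants x samples)
# ---------------------------------------------------------------------------

def write_dosage_tsv(panel: GenotypePanel, path: str) -> None:
    """Write a variants-by-samples dosage TSV with metadata columns first."""
    meta = panel.variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str, sex: np.ndarray) -> GenotypePanel:
    """Read a dosage TSV; ``sex`` supplies the per-sample codes (1/2)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "a1": str, "a2": str})
    meta_cols = ["id", "chrom", "pos", "a1", "a2"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    return GenotypePanel(
        dosages=df[sample_ids].to_numpy(dtype=float).T,
        sex=np.asarray(sex, dtype=int),
        sample_ids=sample_ids,
        variants=df[meta_cols].copy(),
    )


# ---------------------------------------------------------------------------
# GCTA GRM binary triplet
# ---------------------------------------------------------------------------

def write_grm(grm, prefix: str) -> None:
    """Write a GRM as GCTA's ``.grm.bin/.grm.N.bin/.grm.id`` triplet."""
    n = len(grm.sample_ids)
    tri = np.tril_indices(n)
    grm.matrix[tri].astype("<f4").tofile(prefix + ".grm.bin")
    grm.n_snps[tri].astype("<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm(prefix: str):
    """Read a GCTA GRM triplet; returns a :class:`sexstrat.grm.GRM`."""
    from sexstrat.grm import GRM

    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
    tri = np.tril_indices(n)
    mat = np.zeros((n, n))
    mat[tri] = vals
    mat = mat + mat.T - np.diag(np.diag(mat))
    nmat = np.zeros((n, n))
    npath = prefix + ".grm.N.bin"
    if os.path.exists(npath):
        nvals = np.fromfile(npath, dtype="<f4").astype(float)
        nmat[tri] = nvals
        nmat = nmat + nmat.T - np.diag(np.diag(nmat))
    return GRM(sample_ids=list(ids), matrix=mat, n_snps=nmat, source="file")


# ---------------------------------------------------------------------------
# Phenotype / covariate TSVs and JSON sidecars
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    df = pheno.copy()
    if "FID" not in df.columns:
        df.insert(0, "FID", df["IID"])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})


def write_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
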