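"""Spin-permutation enrichment of binary cortical maps against network
partitions.

Each hemisphere's region centroids live on their own unit sphere.  A null
map is produced by applying a uniformly random 3D rotation to the left
hemisphere and its mirror image (reflection about the x-axis) to the
right, then reassigning each region the value of the nearest original
centroid by great-circle distance.  Enrichment per network is the sample
odds ratio of the 2x2 in-map x in-network table, compared against its
rotation null with the add-one permutation p estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

ANNOTATION_COLUMNS = ["region_id", "hemi", "x", "y", "z", "network"]

_MIRROR = np.diag([-1.0, 1.0, 1.0])


class DegenerateMapError(ValueError):
    pass


def _validate_annotations(annotations: pd.DataFrame) -> np.ndarray:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    xyz = annotations[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(xyz, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("region centroids must lie on the unit sphere")
    return xyz / norms[:, None]


def spin_rotations(
    annotations: pd.DataFrame, n_perm: int, seed: int = 0
) -> np.ndarray:
    """Random-rotation index maps.

    Returns an ``(n_perm, n_regions)`` integer array; row ``r`` maps each
    region to the index of the original centroid nearest its rotated
    position.  Left and right hemispheres receive mirrored rotations.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two regions")
    xyz = _validate_annotations(annotations)
    hemi = annotations["hemi"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(annotations)
    out = np.empty((n_perm, n), dtype=int)
    hemis = [(h, np.flatnonzero(hemi == h)) for h in pd.unique(hemi)]
    for r in range(n_perm):
        R = special_ortho_group.rvs(3, random_state=rng)
        for k, (h, idx) in enumerate(hemis):
            Rh = R if k == 0 else _MIRROR @ R @ _MIRROR
            rotated = xyz[idx] @ Rh.T
            # nearest original centroid within the same hemisphere by
            # great-circle distance == max cosine similarity
            nearest = np.argmax(rotated @ xyz[idx].T, axis=1)
            out[r, idx] = idx[nearest]
    return out


def odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Sample odds ratio ``ad/bc`` with Haldane-Anscombe +0.5 on zero cells."""
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    return float(cells[0] * cells[3] / (cells[1] * cells[2]))


def _network_ors(binary_map: np.ndarray, networks: np.ndarray, labels) -> dict:
    ors = {}
    tables = {}
    pos = binary_map.astype(bool)
    for lab in labels:
        in_net = networks == lab
        a = int(np.sum(pos & in_net))
        b = int(np.sum(pos & ~in_net))
        c = int(np.sum(~pos & in_net))
        d = int(np.sum(~pos & ~in_net))
        tables[lab] = (a, b, c, d)
        ors[lab] = odds_ratio(a, b, c, d)
    return ors, tables


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per network: counts, odds ratio, permutation p
    n_perm: int
    seed: int


def network_enrichment(
    binary_map,
    annotations: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Spin-test enrichment of a binary region map against each network.

    Permutation p per network is ``(1 + #{OR_perm >= OR_obs}) / (n_perm + 1)``
    (``<=`` under ``alternative="less"`` for depletion).  The same
    Haldane-corrected OR is used for observed and permuted tables.
    """
    bmap = np.asarray(binary_map).astype(bool)
    if len(bmap) != len(annotations):
        raise ValueError("map length does not match annotation table")
    if bmap.all() or not bmap.any():
        raise DegenerateMapError("binary map must contain both positive and negative regions")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")

    networks = annotations["network"].to_numpy()
    labels = sorted(pd.unique(networks))
    obs_or, tables = _network_ors(bmap, networks, labels)

    perms = spin_rotations(annotations, n_perm, seed=seed)
    exceed = {lab: 0 for lab in labels}
    for r in range(n_perm):
        perm_map = bmap[perms[r]]
        perm_or, _ = _network_ors(perm_map, networks, labels)
        for lab in labels:
            if alternative == "greater":
                exceed[lab] += perm_or[lab] >= obs_or[lab]
            else:
                exceed[lab] += perm_or[lab] <= obs_or[lab]

    rows = []
    for lab in labels:
        a, b, c, d = tables[lab]
        rows.append(
            {
                "network": lab,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": obs_or[lab],
                "perm_p": (1 + exceed[lab]) / (n_perm + 1),
            }
        )
    return EnrichmentResult(table=pd.DataFrame(rows), n_perm=n_perm, seed=seed)
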