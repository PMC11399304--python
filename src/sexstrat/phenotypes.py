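"""Phenotype registry for the brain-anatomy panel layout.

The default registry enumerates three regional cortical morphometric
classes (gray-matter volume, surface area, cortical thickness) over a
180-regions-per-hemisphere parcellation, a set of subcortical structure
volumes, and three global measures — 1106 phenotypes in all.
"""

from __future__ import annotations

import pandas as pd

CORTICAL_CLASSES = ("GMV", "SA", "CT")
GLOBAL_MEASURES = ("mean_cortical_thickness", "total_surface_area", "total_brain_volume")

#: global measure each cortical class is corrected for
GLOBAL_FOR_CLASS = {
    "GMV": "total_brain_volume",
    "SA": "total_surface_area",
    "CT": "mean_cortical_thickness",
}


def build_phenotype_registry(
    n_regions_per_hemi: int = 180,
    n_subcortical: int = 23,
    cortical_classes=CORTICAL_CLASSES,
    global_measures=GLOBAL_MEASURES,
) -> pd.DataFrame:
    """Enumerate the phenotype panel.

    Returns a data frame with columns ``name, category, hemi, region,
    corrected_for``; regional cortical rows are corrected for their
    class's global measure, subcortical volumes for total brain volume.
    """
    rows = []
    for cls in cortical_classes:
        for hemi in ("L", "R"):
            for r in range(1, n_regions_per_hemi + 1):
                rows.append(
                    {
                        "name": f"{cls}_{hemi}{r}",
                        "category": cls,
                        "hemi": hemi,
                        "region": r,
                        "corrected_for": GLOBAL_FOR_CLASS.get(cls),
                    }
                )
    for s in range(1, n_subcortical + 1):
        rows.append(
            {
                "name": f"subcortical_{s}",
                "category": "subcortical",
                "hemi": None,
                "region": s,
                "corrected_for": "total_brain_volume",
            }
        )
    for g in global_measures:
        rows.append(
            {"name": g, "category": "global", "hemi": None, "region": None,
             "corrected_for": None}
        )
    return pd.DataFrame(rows)
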