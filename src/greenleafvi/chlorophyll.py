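"""Ground-truth chlorophyll quantities from spectrophotometric absorbances.

Total chlorophyll in an 80% acetone extract follows the Arnon relation

    Chl_total [mg/L] = 20.2 * D645 + 8.02 * D663

where D645 and D663 are absorbances at 645 and 663 nm.  Leaf-area-based
content (mg/cm^2) divides the chlorophyll mass in the extraction volume by
the sampled leaf area, typically a few 5-mm punch disks per leaf.
"""

from __future__ import annotations

import math

import pandas as pd

ARNON_D645_COEF = 20.2
ARNON_D663_COEF = 8.02

#: Extraction volume in mL (200 uL buffer + 800 uL acetone).
DEFAULT_EXTRACTION_VOLUME_ML = 1.0


def arnon_total_chl(d645: float, d663: float) -> float:
    """Total chlorophyll concentration in mg/L from the two absorbances."""
    if d645 < 0 or d663 < 0:
        raise ValueError(f"absorbances must be >= 0, got D645={d645}, D663={d663}")
    return ARNON_D645_COEF * d645 + ARNON_D663_COEF * d663


def chl_per_area(chl_mg_per_l: float, extraction_volume_ml: float,
                 leaf_area_cm2: float) -> float:
    """Chlorophyll per leaf area in mg/cm^2.

    The mg of chlorophyll contained in the extraction volume is divided by
    the leaf area sampled for extraction.
    """
    if extraction_volume_ml <= 0:
        raise ValueError(f"extraction volume must be > 0 mL, got {extraction_volume_ml}")
    if leaf_area_cm2 <= 0:
        raise ValueError(f"leaf area must be > 0 cm^2, got {leaf_area_cm2}")
    return (chl_mg_per_l * extraction_volume_ml / 1000.0) / leaf_area_cm2


def disk_area(n_disks: int, diameter_mm: float) -> float:
    """Total area in cm^2 of ``n_disks`` round punch disks of the given diameter."""
    if n_disks < 1:
        raise ValueError(f"n_disks must be >= 1, got {n_disks}")
    if diameter_mm <= 0:
        raise ValueError(f"diameter must be > 0 mm, got {diameter_mm}")
    radius_cm = diameter_mm / 20.0
    return n_disks * math.pi * radius_cm**2


def process_absorbance_table(
    table: pd.DataFrame,
    extraction_volume_ml: float = DEFAULT_EXTRACTION_VOLUME_ML,
) -> pd.DataFrame:
    """Append chlorophyll columns to an absorbance table.

    Expects columns ``sample_id, d645, d663, n_disks, disk_diameter_mm``;
    returns a copy with ``chl_mg_per_l`` and ``chl_mg_per_cm2`` appended.
    """
    required = {"sample_id", "d645", "d663", "n_disks", "disk_diameter_mm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"absorbance table is missing columns: {sorted(missing)}")
    out = table.copy()
    out["chl_mg_per_l"] = [
        arnon_total_chl(r.d645, r.d663) for r in out.itertuples()
    ]
    out["chl_mg_per_cm2"] = [
        chl_per_area(
            c, extraction_volume_ml, disk_area(int(r.n_disks), r.disk_diameter_mm)
        )
        for c, r in zip(out["chl_mg_per_l"], out.itertuples())
    ]
    return out
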