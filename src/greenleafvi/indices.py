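"""Colorimetric visual indices (CVIs) from mean channel intensities.

Nine indices are computed from the per-object mean red, green, and blue
intensities (R, G, B):

==============  =================================
GR_ratio        G / R
RG_ratio        R / G
Kawashima       (R - B) / (R + B)
Red_norm (Rn)   R / (R + G + B)
Green_norm (Gn) G / (R + G + B)
Blue_norm (Bn)  B / (R + G + B)
NDI             (Rn - Gn) / (Rn + Gn + 0.01)
GLI             (2G - R - B) / (2G + R + B)
Woebbecke       (G - B) / (R - G)
==============  =================================

An index whose denominator is exactly zero is UNDEFINED (stored as NaN with
its validity flag cleared) rather than raising: the Woebbecke index in
particular blows up as R approaches G, as happens in senescent leaves, and
silent infinities would poison group means.  No clamping is applied to
defined values, so the raw outlier behavior can be studied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

NDI_STABILIZER = 0.01

#: Output column names, in results.csv order.
INDEX_COLUMNS = (
    "GR_ratio",
    "RG_ratio",
    "Kawashima",
    "Red_norm",
    "Green_norm",
    "Blue_norm",
    "NDI",
    "GLI",
    "Woebbecke",
)

_FIELD_TO_COLUMN = {
    "gr_ratio": "GR_ratio",
    "rg_ratio": "RG_ratio",
    "kawashima": "Kawashima",
    "red_norm": "Red_norm",
    "green_norm": "Green_norm",
    "blue_norm": "Blue_norm",
    "ndi": "NDI",
    "gli": "GLI",
    "woebbecke": "Woebbecke",
}


@dataclass(frozen=True)
class IndexSet:
    """The nine CVI values for one object; NaN marks an UNDEFINED index."""

    gr_ratio: float
    rg_ratio: float
    kawashima: float
    red_norm: float
    green_norm: float
    blue_norm: float
    ndi: float
    gli: float
    woebbecke: float
    flags: dict[str, bool] = field(default_factory=dict)

    def as_columns(self) -> dict[str, float]:
        """Values keyed by their results.csv column names."""
        return {
            _FIELD_TO_COLUMN[f.name]: getattr(self, f.name)
            for f in fields(self)
            if f.name != "flags"
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def compute_indices(mean_r: float, mean_g: float, mean_b: float) -> IndexSet:
    """Compute all nine CVIs from mean channel intensities.

    Inputs must be finite and non-negative (mean 8-bit intensities).  A zero
    denominator makes that index UNDEFINED; the others are still computed.
    """
    for name, v in (("mean_r", mean_r), ("mean_g", mean_g), ("mean_b", mean_b)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    r, g, b = float(mean_r), float(mean_g), float(mean_b)
    total = r + g + b

    rn = _safe_div(r, total)
    gn = _safe_div(g, total)
    bn = _safe_div(b, total)
    # Rn + Gn + stabilizer > 0 whenever the norms are defined
    ndi = (rn - gn) / (rn + gn + NDI_STABILIZER) if total != 0 else math.nan

    values = {
        "gr_ratio": _safe_div(g, r),
        "rg_ratio": _safe_div(r, g),
        "kawashima": _safe_div(r - b, r + b),
        "red_norm": rn,
        "green_norm": gn,
        "blue_norm": bn,
        "ndi": ndi,
        "gli": _safe_div(2 * g - r - b, 2 * g + r + b),
        "woebbecke": _safe_div(g - b, r - g),
    }
    flags = {name: not math.isnan(v) for name, v in values.items()}
    return IndexSet(flags=flags, **values)
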