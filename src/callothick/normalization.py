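"""Brain-size normalization of callosal measures.

Callosal area (mm^2) and thickness (mm) have lower dimensionality than the
forebrain volume FBV (mm^3) used as the brain-size measure, so FBV is
power-converted before use: FBV^(2/3) for area analyses and FBV^(1/3) for
thickness analyses.  Relative measures divide the callosal quantity by the
converted FBV; a global scale constant (default 100) puts the unitless
relative area into a convenient magnitude range (~6.5-7 at physiological
FBV around 1.0e6 mm^3).  The constant cancels from every test statistic and
standardized effect size downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCALE",
    "add_relative_columns",
    "convert_fbv",
    "relative_area",
    "relative_thickness",
]

DEFAULT_SCALE = 100.0

_EXPONENTS = {"area": 2.0 / 3.0, "thickness": 1.0 / 3.0}


def convert_fbv(fbv_mm3, kind: str):
    """Dimension-matching power conversion of forebrain volume.

    ``kind="area"`` returns FBV^(2/3) (mm^2 scale), ``kind="thickness"``
    returns FBV^(1/3) (mm scale).  Accepts scalars or arrays.
    """
    if kind not in _EXPONENTS:
        raise ValueError(f"kind must be 'area' or 'thickness', got {kind!r}")
    fbv = np.asarray(fbv_mm3, dtype=float)
    if np.any(fbv <= 0):
        raise ValueError("forebrain volume must be strictly positive")
    out = fbv ** _EXPONENTS[kind]
    return float(out) if np.isscalar(fbv_mm3) else out


def relative_area(area_mm2, fbv_mm3, scale: float = DEFAULT_SCALE):
    """Unitless relative callosal area: scale * area / FBV^(2/3)."""
    area = np.asarray(area_mm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    out = scale * area / convert_fbv(fbv_mm3, "area")
    return float(out) if np.isscalar(area_mm2) else out


def relative_thickness(thickness_mm, fbv_mm3, scale: float = DEFAULT_SCALE):
    """Elementwise relative thickness: scale * thickness / FBV^(1/3).

    ``thickness_mm`` may be a single profile (n,) or a participant-by-segment
    matrix with one FBV per row.
    """
    thick = np.asarray(thickness_mm, dtype=float)
    if np.any(thick < 0):
        raise ValueError("thickness must be non-negative")
    fbv13 = convert_fbv(fbv_mm3, "thickness")
    if thick.ndim == 2 and not np.isscalar(fbv_mm3):
        return scale * thick / np.asarray(fbv13)[:, None]
    return scale * thick / fbv13


def add_relative_columns(
    df: pd.DataFrame,
    scale: float = DEFAULT_SCALE,
    fbv_col: str = "fbv_mm3",
    area_col: str = "area_mm2",
    thickness_prefix: str = "thickness_",
    rel_prefix: str = "rel_thickness_",
) -> pd.DataFrame:
    """Append converted-FBV and relative-measure columns to a cohort table.

    Adds ``fbv_23``, ``fbv_13`` and ``rel_area``; for every
    ``thickness_NNN`` column a matching ``rel_thickness_NNN`` is added.
    """
    out = df.copy()
    fbv = out[fbv_col].to_numpy(float)
    out["fbv_23"] = convert_fbv(fbv, "area")
    out["fbv_13"] = convert_fbv(fbv, "thickness")
    out["rel_area"] = relative_area(out[area_col].to_numpy(float), fbv, scale)
    thick_cols = [c for c in out.columns if c.startswith(thickness_prefix)]
    if thick_cols:
        rel = relative_thickness(out[thick_cols].to_numpy(float), fbv, scale)
        rel_cols = [rel_prefix + c[len(thickness_prefix):] for c in thick_cols]
        out = pd.concat(
            [out, pd.DataFrame(rel, columns=rel_cols, index=out.index)], axis=1
        )
    return out
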