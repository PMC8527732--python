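"""Regional layer thickness measurement and the macular-edema exclusion."""

from __future__ import annotations

import math

import numpy as np

from .types import BoundarySet, BScan, ThicknessSet

#: Layer -> (upper surface, lower surface, averaging-circle diameter in mm).
#: Inner (neural) layers use the central 6-mm circle; nuclear/plexiform and
#: total thicknesses the central 1-mm circle.
DEFAULT_REGIONS: dict[str, tuple[str, str, float]] = {
    "rnfl_um": ("ilm", "rnfl_gcl", 6.0),
    "gcl_ipl_um": ("rnfl_gcl", "ipl_inl", 6.0),
    "inl_um": ("ipl_inl", "inl_opl", 1.0),
    "opl_um": ("inl_opl", "opl_onl", 1.0),
    "total_um": ("ilm", "outer_boundary", 1.0),
    "central_subfield_um": ("ilm", "outer_boundary", 1.0),
}

#: Central-subfield thickness at or above this value indicates clinically
#: significant macular edema and excludes the eye.
DME_THRESHOLD_UM = 275.0


def _window_columns(bscan: BScan, diameter_mm: float) -> slice:
    fovea = bscan.fovea_column
    if fovea is None:
        fovea = bscan.n_columns // 2
    half_px = diameter_mm * 1000.0 / 2.0 / bscan.lateral_pitch
    lo = math.ceil(fovea - half_px)
    hi = math.floor(fovea + half_px)
    if lo < 0 or hi > bscan.n_columns - 1:
        raise ValueError(
            f"{diameter_mm}-mm averaging window exceeds the scan width"
        )
    return slice(lo, hi + 1)


def compute_thicknesses(
    boundaries: BoundarySet,
    bscan: BScan,
    region_diameters: dict[str, float] | None = None,
) -> ThicknessSet:
    """Mean regional thickness of each layer in micrometres.

    Thickness per column is (lower - upper surface) x axial pitch; the mean
    is taken over the columns within the layer's averaging circle centred on
    the fovea column.  ``region_diameters`` overrides circle diameters (mm)
    per output key.
    """
    values: dict[str, float] = {}
    for key, (upper, lower, diameter) in DEFAULT_REGIONS.items():
        if region_diameters and key in region_diameters:
            diameter = region_diameters[key]
        window = _window_columns(bscan, diameter)
        sep = boundaries[lower][window] - boundaries[upper][window]
        values[key] = float(np.mean(sep) * bscan.axial_pitch)
    return ThicknessSet(**values)


def dme_exclusion_check(thicknesses: ThicknessSet) -> bool:
    """True (exclude the eye) iff the central subfield is thickened to at
    least the macular-edema threshold (inclusive)."""
    return thicknesses.central_subfield_um >= DME_THRESHOLD_UM
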