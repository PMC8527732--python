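"""Domain types for B-scan segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Surface names in anatomical order (shallow to deep).
SURFACE_NAMES: tuple[str, ...] = (
    "ilm",
    "rnfl_gcl",
    "ipl_inl",
    "inl_opl",
    "opl_onl",
    "outer_boundary",
)

#: Layer names, each bounded by SURFACE_NAMES[i] above and [i+1] below.
LAYER_NAMES: tuple[str, ...] = ("rnfl", "gcl_ipl", "inl", "opl", "outer")


class BoundaryOrderError(RuntimeError):
    """Raised when segmented surfaces violate the depth-ordering invariant."""


@dataclass
class BScan:
    """A single cross-sectional OCT image.

    Parameters
    ----------
    intensity
        2-D float array in [0, 1]; rows index depth, columns index
        lateral position.
    axial_pitch
        Depth sampling in micrometres per pixel.
    lateral_pitch
        Lateral sampling in micrometres per pixel.
    fovea_column
        Column index of the foveal centre; defaults to the image centre
        when ``None``.
    """

    intensity: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    fovea_column: int | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("B-scan intensity must be a 2-D array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("B-scan intensity contains non-finite values")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_columns(self) -> int:
        return self.intensity.shape[1]


@dataclass
class BoundarySet:
    """Ordered per-column depths (pixels, real-valued) of the six surfaces."""

    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    n_rows: int | None = None

    def __post_init__(self) -> None:
        for name in self.surfaces:
            if name not in SURFACE_NAMES:
                raise ValueError(f"unknown surface name {name!r}")
        self.surfaces = {
            name: np.asarray(self.surfaces[name], dtype=float)
            for name in SURFACE_NAMES
            if name in self.surfaces
        }
        self.validate()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def validate(self) -> None:
        """Check depth ordering and image bounds; raise loudly on violation."""
        names = list(self.surfaces)
        for upper, lower in zip(names, names[1:]):
            du, dl = self.surfaces[upper], self.surfaces[lower]
            bad = np.nonzero(du > dl)[0]
            if bad.size:
                raise BoundaryOrderError(
                    f"surface {upper!r} lies below {lower!r} at columns "
                    f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
                )
        for name, depth in self.surfaces.items():
            if np.any(depth < 0):
                raise BoundaryOrderError(f"surface {name!r} above image top")
            if self.n_rows is not None and np.any(depth > self.n_rows - 1):
                raise BoundaryOrderError(f"surface {name!r} below image bottom")


@dataclass
class ThicknessSet:
    """Regional mean layer thicknesses in micrometres.

    RNFL and GCL-IPL are averaged over the central 6-mm window; INL, OPL,
    total and the central subfield over the central 1-mm window.
    """

    rnfl_um: float
    gcl_ipl_um: float
    inl_um: float
    opl_um: float
    total_um: float
    central_subfield_um: float

    def as_dict(self) -> Mapping[str, float]:
        return {
            "rnfl_um": self.rnfl_um,
            "gcl_ipl_um": self.gcl_ipl_um,
            "inl_um": self.inl_um,
            "opl_um": self.opl_um,
            "total_um": self.total_um,
            "central_subfield_um": self.central_subfield_um,
        }
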