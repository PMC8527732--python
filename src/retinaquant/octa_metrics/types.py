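"""Domain types for en-face angiogram quantification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EnFaceAngiogram:
    """A 2-D en-face perfusion image.

    Parameters
    ----------
    intensity
        Square 2-D float array in [0, 1].
    scan_width_mm
        Physical width of the field of view.
    plexus
        "SRCP" or "DRCP".
    ssi
        Device signal strength index in [0, 100], if known.
    center
        (row, col) pixel coordinates of the fovea; defaults to the image
        centre when ``None``.
    slab_definition
        Free-text metadata describing the depth slab the image projects.
    """

    intensity: np.ndarray
    scan_width_mm: float = 3.0
    plexus: str = "DRCP"
    ssi: float | None = None
    center: tuple[float, float] | None = None
    slab_definition: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("angiogram must be a 2-D array")
        if self.intensity.shape[0] != self.intensity.shape[1]:
            raise ValueError("angiogram must be square")
        if self.scan_width_mm <= 0:
            raise ValueError("scan_width_mm must be positive")
        if self.plexus not in ("SRCP", "DRCP"):
            raise ValueError("plexus must be 'SRCP' or 'DRCP'")
        if self.ssi is not None and not (0 <= self.ssi <= 100):
            raise ValueError("ssi must lie in [0, 100]")

    @property
    def size(self) -> int:
        return self.intensity.shape[0]


@dataclass
class VesselMaps:
    """Derived maps: upsampled grayscale, vessel mask, centreline skeleton."""

    upsampled: np.ndarray
    binary: np.ndarray
    skeleton: np.ndarray

    def __post_init__(self) -> None:
        if not (self.upsampled.shape == self.binary.shape == self.skeleton.shape):
            raise ValueError("maps must share one shape")
        if np.any(self.skeleton & ~self.binary):
            raise ValueError("skeleton must be a subset of the vessel mask")


@dataclass
class AnnulusGeometry:
    """Measurement annulus: 2.5-mm outer diameter, 0.6-mm central exclusion."""

    pixel_size_mm: float
    outer_diameter_mm: float = 2.5
    inner_exclusion_diameter_mm: float = 0.6

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if not 0 < self.inner_exclusion_diameter_mm < self.outer_diameter_mm:
            raise ValueError("need 0 < inner exclusion < outer diameter")

    @property
    def inner_radius_px(self) -> float:
        return self.inner_exclusion_diameter_mm / 2 / self.pixel_size_mm

    @property
    def outer_radius_px(self) -> float:
        return self.outer_diameter_mm / 2 / self.pixel_size_mm
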