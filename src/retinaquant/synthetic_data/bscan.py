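"""Layered B-scan phantoms with known boundary ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..oct_layers.types import LAYER_NAMES, BScan
from .types import GroundTruth

#: Default layer thicknesses in micrometres (RNFL, GCL-IPL, INL, OPL, outer
#: retina).  The first four follow healthy-macula magnitudes; the outer value
#: tops the stack up to a ~239-μm total.
DEFAULT_THICKNESSES_UM: tuple[float, ...] = (28.46, 72.40, 17.52, 10.15, 110.93)

#: Mean grayscale per layer, chosen so that consecutive boundaries
#: alternate gradient polarity wherever layers are thin (bright RNFL, dark
#: INL, bright OPL, dimmer outer complex), which keeps the gradient
#: shoulders of neighbouring surfaces from competing in the sequential
#: segmentation schedule.
DEFAULT_INTENSITIES: tuple[float, ...] = (0.90, 0.50, 0.20, 0.70, 0.45)

MIN_CONTRAST = 0.05


@dataclass
class BScanPhantomSpec:
    """Parameters of a layered B-scan phantom.

    ``layer_thicknesses`` may be five scalars (uniform layers) or a
    (5, n_columns) array of per-column profiles in micrometres.
    """

    n_columns: int = 512
    n_rows: int = 160
    axial_pitch: float = 3.0
    lateral_pitch: float = 11.75
    layer_thicknesses: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_THICKNESSES_UM)
    )
    layer_intensities: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_INTENSITIES)
    )
    vitreous_intensity: float = 0.05
    sub_retinal_intensity: float = 0.10
    top_margin_um: float = 60.0
    foveal_pit: bool = False
    pit_depth_um: float = 80.0
    pit_width_um: float = 600.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_thicknesses = np.atleast_1d(
            np.asarray(self.layer_thicknesses, dtype=float)
        )
        self.layer_intensities = np.asarray(self.layer_intensities, dtype=float)
        if self.layer_thicknesses.ndim == 1:
            self.layer_thicknesses = np.repeat(
                self.layer_thicknesses[:, None], self.n_columns, axis=1
            )
        if self.layer_thicknesses.shape != (len(LAYER_NAMES), self.n_columns):
            raise ValueError(
                "layer_thicknesses must have 5 scalars or shape (5, n_columns)"
            )
        if np.any(self.layer_thicknesses <= 0):
            raise ValueError("layer thicknesses must be strictly positive")
        if self.layer_intensities.shape != (len(LAYER_NAMES),):
            raise ValueError("need exactly five layer intensities")
        if np.any(self.layer_intensities < 0) or np.any(self.layer_intensities > 1):
            raise ValueError("layer intensities must lie in [0, 1]")
        stack = np.concatenate(
            (
                [self.vitreous_intensity],
                self.layer_intensities,
                [self.sub_retinal_intensity],
            )
        )
        contrast = np.abs(np.diff(stack))
        if np.any(contrast < MIN_CONTRAST):
            raise ValueError(
                f"adjacent layers need contrast >= {MIN_CONTRAST}; got {contrast}"
            )
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _pit_factor(spec: BScanPhantomSpec) -> np.ndarray:
    """Per-column multiplicative shrink of the inner layers forming a pit."""
    cols = np.arange(spec.n_columns)
    x_um = (cols - spec.n_columns // 2) * spec.lateral_pitch
    inner_total = spec.layer_thicknesses[:4].sum(axis=0)
    depth = spec.pit_depth_um * np.exp(-0.5 * (x_um / spec.pit_width_um) ** 2)
    factor = 1.0 - depth / np.maximum(inner_total, 1e-9)
    return np.clip(factor, 0.05, 1.0)


def boundary_depths_px(spec: BScanPhantomSpec) -> np.ndarray:
    """(6, n_columns) surface depths in pixels implied by the spec."""
    thick = spec.layer_thicknesses.copy()
    if spec.foveal_pit:
        thick[:4] *= _pit_factor(spec)[None, :]
    top = np.full(spec.n_columns, spec.top_margin_um)
    depths_um = np.vstack([top, top + np.cumsum(thick, axis=0)])
    return depths_um / spec.axial_pitch


def _render(spec: BScanPhantomSpec, boundaries_px: np.ndarray) -> np.ndarray:
    """Area-weighted (anti-aliased) rendering of the piecewise-constant profile."""
    h, w = spec.n_rows, spec.n_columns
    # Region bounds in pixel units: vitreous, five layers, sub-retinal space.
    lows = np.vstack([np.zeros(w), boundaries_px])
    highs = np.vstack([boundaries_px, np.full(w, float(h))])
    values = np.concatenate(
        ([spec.vitreous_intensity], spec.layer_intensities, [spec.sub_retinal_intensity])
    )
    rows = np.arange(h, dtype=float)
    image = np.zeros((h, w))
    for lo, hi, val in zip(lows, highs, values):
        # coverage of [row, row+1) by [lo, hi), per column
        overlap = np.clip(
            np.minimum(rows[:, None] + 1.0, hi[None, :])
            - np.maximum(rows[:, None], lo[None, :]),
            0.0,
            1.0,
        )
        image += val * overlap
    return image


def generate_bscan(spec: BScanPhantomSpec) -> tuple[BScan, GroundTruth]:
    """Render a layered B-scan phantom and its boundary ground truth.

    Returns the image (values in [0, 1], additive Gaussian noise clipped to
    range) and a :class:`GroundTruth` whose ``true_boundaries`` row ``k``
    holds the per-column pixel depth of surface ``k``.  Identical specs
    (including seed) yield bit-identical images.
    """
    boundaries = boundary_depths_px(spec)
    if np.any(boundaries[-1] > spec.n_rows):
        raise ValueError(
            "cumulative layer depth exceeds image height; increase n_rows "
            "or reduce thicknesses/top margin"
        )
    image = _render(spec, boundaries)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    bscan = BScan(
        intensity=image,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        fovea_column=spec.n_columns // 2,
    )
    truth = GroundTruth(true_boundaries=boundaries)
    return bscan, truth
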