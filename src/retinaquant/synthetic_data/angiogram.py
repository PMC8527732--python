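"""En-face angiogram phantoms: random capillary meshes with a known
centreline density in the measurement annulus and a central avascular zone.

Vessels are grown as momentum random-walk strokes with spacing inhibition:
a stroke terminates when it runs into the clearance zone of an existing
vessel, anastomosing with it.  This keeps vessels resolvable after the
device-resolution round trip while producing a connected, space-filling
mesh whose centreline density can be driven to a target value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, label
from skimage.draw import line as draw_line
from skimage.morphology import disk, skeletonize
from skimage.transform import resize

from ..octa_metrics.types import EnFaceAngiogram
from .types import GroundTruth

#: Grid on which vessels are drawn and the ground-truth density is defined.
#: Matches the upsampled grid of the measurement pipeline so that drawn
#: centreline density and re-measured skeleton density are commensurable.
ANALYSIS_SIZE = 1024


class DensityUnreachableError(RuntimeError):
    """Raised when added strokes can no longer raise the annulus density."""


@dataclass
class AngiogramPhantomSpec:
    """Parameters of a capillary-mesh angiogram phantom."""

    image_size: int = 304
    scan_width_mm: float = 3.0
    target_skeleton_density: float = 0.072
    faz_radius_mm: float = 0.3
    vessel_width_px: int = 5
    #: Minimum centreline-to-centreline clearance while growing strokes.
    inhibit_radius_px: int = 3
    vessel_intensity: float = 0.85
    background_intensity: float = 0.08
    noise_sd: float = 0.0
    seed: int = 0
    plexus: str = "DRCP"
    ssi: float | None = None

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if not 0 <= self.target_skeleton_density < 0.2:
            raise ValueError("target_skeleton_density must lie in [0, 0.2)")
        if not 0 < self.faz_radius_mm < self.scan_width_mm / 2:
            raise ValueError("faz_radius_mm must lie in (0, scan_width/2)")
        if self.vessel_width_px < 1:
            raise ValueError("vessel_width_px must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def annulus_pixel_mask(
    size: int,
    pixel_size_mm: float,
    inner_radius_mm: float = 0.3,
    outer_radius_mm: float = 1.25,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of the measurement annulus on a ``size``-pixel grid."""
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    rr, cc = np.mgrid[0:size, 0:size]
    r_mm = np.hypot(rr - center[0], cc - center[1]) * pixel_size_mm
    return (r_mm >= inner_radius_mm) & (r_mm <= outer_radius_mm)


class _MeshGrower:
    """Incremental stroke drawing with clearance bookkeeping."""

    def __init__(self, size: int, inhibit_radius: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.centerline = np.zeros((size, size), dtype=bool)
        #: Dilated occupancy: pixels too close to an existing centreline.
        self.occupied = np.zeros((size, size), dtype=bool)
        self.footprint = disk(inhibit_radius)
        self.pad = inhibit_radius

    def _commit(self, rr: np.ndarray, cc: np.ndarray) -> None:
        self.centerline[rr, cc] = True
        lo_r = max(rr.min() - self.pad, 0)
        hi_r = min(rr.max() + self.pad + 1, self.size)
        lo_c = max(cc.min() - self.pad, 0)
        hi_c = min(cc.max() + self.pad + 1, self.size)
        box = np.zeros((hi_r - lo_r, hi_c - lo_c), dtype=bool)
        box[rr - lo_r, cc - lo_c] = True
        self.occupied[lo_r:hi_r, lo_c:hi_c] |= binary_dilation(
            box, structure=self.footprint
        )

    def stroke(self, max_steps: int, step_len: float) -> bool:
        """Grow one stroke; returns False if no free start site was found."""
        size, rng = self.size, self.rng
        for _ in range(20):
            start = rng.uniform(0, size - 1, size=2)
            if not self.occupied[int(round(start[0])), int(round(start[1]))]:
                break
        else:
            return False
        pos = start
        angle = rng.uniform(0, 2 * np.pi)
        seg_r: list[np.ndarray] = []
        seg_c: list[np.ndarray] = []
        for _ in range(max_steps):
            angle += rng.normal(0.0, 0.5)
            nxt = pos + step_len * np.array([np.sin(angle), np.cos(angle)])
            if not (0 <= nxt[0] < size and 0 <= nxt[1] < size):
                break
            r0, c0 = (min(int(round(v)), size - 1) for v in pos)
            r1, c1 = (min(int(round(v)), size - 1) for v in nxt)
            rr, cc = draw_line(r0, c0, r1, c1)
            seg_r.append(rr)
            seg_c.append(cc)
            pos = nxt
            # run into an existing vessel's clearance zone: anastomose & stop
            if self.occupied[r1, c1]:
                break
        if not seg_r:
            return True
        self._commit(np.concatenate(seg_r), np.concatenate(seg_c))
        return True


def _draw_faz_rim(
    grower: _MeshGrower, rng: np.random.Generator, center: float, radius_px: float
) -> None:
    """Closed, slightly irregular capillary ring bounding the avascular zone."""
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=True)
    n_lobes = rng.integers(3, 7)
    phase = rng.uniform(0, 2 * np.pi)
    # wobble only outward so clearing the avascular disc never cuts the rim
    wobble = 1.02 + 0.04 * (1.0 + np.sin(n_lobes * theta + phase)) / 2.0
    rr = np.round(center + radius_px * wobble * np.sin(theta)).astype(int)
    cc = np.round(center + radius_px * wobble * np.cos(theta)).astype(int)
    segs_r, segs_c = [], []
    for (r0, c0), (r1, c1) in zip(zip(rr, cc), zip(rr[1:], cc[1:])):
        lrr, lcc = draw_line(r0, c0, r1, c1)
        segs_r.append(lrr)
        segs_c.append(lcc)
    grower._commit(np.concatenate(segs_r), np.concatenate(segs_c))


def _skeleton_density(
    centerline: np.ndarray,
    faz_disc: np.ndarray,
    dilate_footprint: np.ndarray,
    annulus: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Density of the one-pixel-wide centreline of the rendered vessel mask."""
    vessel = binary_dilation(centerline, structure=dilate_footprint)
    vessel &= ~faz_disc
    skeleton = skeletonize(vessel)
    return float(skeleton[annulus].sum() / annulus.sum()), vessel, skeleton


def generate_angiogram(
    spec: AngiogramPhantomSpec, keep_masks: bool = False
) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Generate a capillary-mesh angiogram phantom.

    Strokes are added on the 1024-pixel analysis grid until the density of
    the one-pixel-wide centreline (skeleton of the drawn vessel mask)
    inside the 2.5-mm annulus reaches ``target_skeleton_density``; the
    exact drawn value is reported as ``true_skeleton_density``.  The mask
    is shaded and block-averaged down to ``image_size`` to emulate device
    resolution.  With ``keep_masks`` the ground truth also carries the
    internal skeleton/vessel/annulus masks for oracle counting.
    """
    n = ANALYSIS_SIZE
    px_mm = spec.scan_width_mm / n
    center = (n - 1) / 2.0
    rng = np.random.default_rng(spec.seed)
    annulus = annulus_pixel_mask(n, px_mm)
    faz_radius_px = spec.faz_radius_mm / px_mm
    rr, cc = np.mgrid[0:n, 0:n]
    faz_disc = np.hypot(rr - center, cc - center) < faz_radius_px
    dilate_footprint = disk(max(1, int(round((spec.vessel_width_px - 1) / 2))))

    grower = _MeshGrower(n, spec.inhibit_radius_px, rng)
    if spec.target_skeleton_density > 0:
        _draw_faz_rim(grower, rng, center, faz_radius_px)
        # phase 1: raw centreline count is an upper bound on the skeleton
        # count, so fill to the target cheaply before measuring exactly
        annulus_count = annulus.sum()
        stalled = 0
        # slight overfill: skeletonization trims ~1-2% of raw pixels
        raw_target = spec.target_skeleton_density * 1.02
        while grower.centerline[annulus].sum() / annulus_count < raw_target:
            before = int(grower.centerline[annulus].sum())
            ok = grower.stroke(
                max_steps=int(rng.integers(80, 160)), step_len=4.0
            )
            grower.centerline &= ~faz_disc
            gained = int(grower.centerline[annulus].sum()) - before
            stalled = stalled + 1 if (not ok or gained == 0) else 0
            if stalled > 300:
                raise DensityUnreachableError(
                    "stroke additions no longer increase annulus density; "
                    f"target {spec.target_skeleton_density:.4f} unreachable"
                )
        # phase 2: top up until the skeletonized mask reaches the target
        density, vessel, skeleton = _skeleton_density(
            grower.centerline, faz_disc, dilate_footprint, annulus
        )
        stalled = 0
        while density < spec.target_skeleton_density:
            for _ in range(5):
                grower.stroke(max_steps=int(rng.integers(80, 160)), step_len=4.0)
            grower.centerline &= ~faz_disc
            new_density, vessel, skeleton = _skeleton_density(
                grower.centerline, faz_disc, dilate_footprint, annulus
            )
            stalled = stalled + 1 if new_density <= density else 0
            if stalled > 60:
                raise DensityUnreachableError(
                    "skeleton density saturated at "
                    f"{new_density:.4f} below target {spec.target_skeleton_density:.4f}"
                )
            density = new_density
    else:
        density = 0.0
        vessel = np.zeros((n, n), dtype=bool)
        skeleton = np.zeros((n, n), dtype=bool)

    labels, _ = label(~vessel)
    faz_label = labels[int(round(center)), int(round(center))]
    true_faz_px = int((labels == faz_label).sum()) if faz_label else 0
    true_faz_mm2 = true_faz_px * px_mm**2

    hi_res = np.where(vessel, spec.vessel_intensity, spec.background_intensity)
    image = resize(
        hi_res.astype(float), (spec.image_size, spec.image_size),
        order=1, anti_aliasing=True, mode="reflect",
    )
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    angiogram = EnFaceAngiogram(
        intensity=image,
        scan_width_mm=spec.scan_width_mm,
        plexus=spec.plexus,
        ssi=spec.ssi,
    )
    truth = GroundTruth(
        true_skeleton_density=float(density), true_faz_area_mm2=float(true_faz_mm2)
    )
    if keep_masks:
        truth.arrays = {
            "skeleton": skeleton,
            "vessel": vessel,
            "annulus": annulus,
        }
    return angiogram, truth
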