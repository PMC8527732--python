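"""Sequential six-surface segmentation of a B-scan.

Surfaces are found most-prominent-first: the inner limiting membrane
(strongest dark-to-light transition) and the outer retinal boundary
(strongest light-to-dark transition at plausible retinal depth) delimit the
retina; interior surfaces are then searched top-down inside the enclosed
band, each new band clipped inside previously found surfaces so the
depth-ordering invariant holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import GradientGraph, build_gradient_graph, find_boundary
from .types import SURFACE_NAMES, BoundaryOrderError, BoundarySet, BScan


@dataclass
class SegmentationConfig:
    """Tunable parameters of the boundary search.

    Band clip margins are per pass: a freshly sought surface must keep a
    few rows clear of any already-found surface whose transition shares its
    gradient polarity, because axial smoothing spreads that surface's
    gradient shoulder into adjacent rows and would otherwise capture the
    path.  Opposite-polarity neighbours need only a single row.
    """

    smooth_sigma: float = 1.0
    #: Shallowest plausible total retinal depth; anchors the outer-boundary
    #: search below the inner-retina transitions.
    min_total_um: float = 150.0
    #: Parabolic subpixel refinement of each surface around the integer path.
    subpixel: bool = True

    #: (surface, polarity, clip below previous surface, clip above the
    #: outer boundary) for the interior top-down passes.
    interior_schedule: tuple[tuple[str, str, int, int], ...] = field(
        default=(
            ("rnfl_gcl", "light_to_dark", 1, 3),
            ("ipl_inl", "light_to_dark", 3, 3),
            ("inl_opl", "dark_to_light", 1, 1),
            ("opl_onl", "light_to_dark", 1, 3),
        )
    )


def _refine_subpixel(
    rows: np.ndarray, graph: GradientGraph, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Quadratic peak interpolation of the gradient around the integer path."""
    g = graph.node_gradient
    h, w = g.shape
    out = rows.astype(float)
    r = rows
    interior = (r >= 1) & (r <= h - 2)
    cols = np.nonzero(interior)[0]
    a = g[r[cols] - 1, cols]
    b = g[r[cols], cols]
    c = g[r[cols] + 1, cols]
    denom = a - 2 * b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < 0, 0.5 * (a - c) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    refined = r[cols] + delta
    out[cols] = np.clip(refined, lo[cols], hi[cols])
    return out


def segment_layers(
    bscan: BScan,
    config: SegmentationConfig | None = None,
    overrides: dict[str, np.ndarray] | None = None,
) -> BoundarySet:
    """Find the six intraretinal surfaces of a B-scan.

    ``overrides`` maps surface names to user-supplied per-column depths and
    replaces the automatic result for those surfaces (the manual-correction
    hook); the ordering invariant is still enforced on the final set and
    violations raise :class:`BoundaryOrderError` rather than being silently
    reordered.
    """
    config = config or SegmentationConfig()
    h, w = bscan.n_rows, bscan.n_columns
    graphs: dict[str, GradientGraph] = {
        pol: build_gradient_graph(bscan, pol, config.smooth_sigma)
        for pol in ("dark_to_light", "light_to_dark")
    }

    def search(name: str, polarity: str, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        hi = np.maximum(hi, lo)
        rows = find_boundary(graphs[polarity], (lo, hi))
        if config.subpixel:
            return _refine_subpixel(rows, graphs[polarity], lo, hi)
        return rows.astype(float)

    found: dict[str, np.ndarray] = {}
    full_lo, full_hi = np.zeros(w, dtype=int), np.full(w, h - 1)
    ilm = search("ilm", "dark_to_light", full_lo, full_hi)
    found["ilm"] = ilm

    min_total_px = int(round(config.min_total_um / bscan.axial_pitch))
    lo = np.clip(ilm.astype(int) + min_total_px, 0, h - 1)
    outer = search("outer_boundary", "light_to_dark", lo, full_hi)
    found["outer_boundary"] = outer

    upper = ilm
    for name, polarity, clip_top, clip_bottom in config.interior_schedule:
        lo = np.clip(np.ceil(upper).astype(int) + clip_top, 0, h - 1)
        hi = np.clip(np.floor(outer).astype(int) - clip_bottom, 0, h - 1)
        found[name] = search(name, polarity, lo, hi)
        upper = found[name]

    if overrides:
        for name, depths in overrides.items():
            if name not in SURFACE_NAMES:
                raise ValueError(f"unknown surface {name!r}")
            depths = np.asarray(depths, dtype=float)
            if depths.shape != (w,):
                raise ValueError(f"override for {name!r} must have one depth per column")
            found[name] = depths

    surfaces = {name: np.asarray(found[name], dtype=float) for name in SURFACE_NAMES}
    try:
        return BoundarySet(surfaces=surfaces, n_rows=h)
    except BoundaryOrderError as err:
        raise BoundaryOrderError(f"segmentation produced invalid ordering: {err}") from err
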