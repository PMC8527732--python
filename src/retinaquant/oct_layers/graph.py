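"""Gradient-weighted shortest-path search for layer boundaries.

A boundary is modelled as a minimum-cost left-to-right path through the
pixel grid.  Node affinity is the signed vertical intensity gradient under a
chosen polarity, normalised to [0, 1]; the cost of stepping from pixel ``a``
to pixel ``b`` is ``2 - (g_a + g_b) + eps``, so paths hugging strong
gradients of the requested polarity are cheap.  Two virtual zero-gradient
side columns let the path enter and leave at any row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import BScan

EDGE_EPS = 1e-5

POLARITIES = ("dark_to_light", "light_to_dark")


@dataclass
class GradientGraph:
    """Implicit weighted graph over the pixel grid of one B-scan.

    ``node_gradient[r, c]`` is the normalised polarity-signed gradient g in
    [0, 1].  Edges connect each pixel to its three right-hand 8-neighbours
    (left-to-right progress only) with weight ``2 - g_a - g_b + eps``.
    Virtual side columns have g = 1 so entry/exit costs are minimal and
    row-independent.
    """

    node_gradient: np.ndarray
    polarity: str
    eps: float = EDGE_EPS

    @property
    def shape(self) -> tuple[int, int]:
        return self.node_gradient.shape

    def edge_weight(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Weight of the directed edge a -> b (b one column right of a)."""
        if b[1] != a[1] + 1 or abs(b[0] - a[0]) > 1:
            raise ValueError("edges connect 8-neighbours one column to the right")
        g = self.node_gradient
        return 2.0 - (g[a] + g[b]) + self.eps

    def entry_weight(self, node: tuple[int, int]) -> float:
        """Weight of the edge from a virtual side column (g = 1) to a node."""
        return 2.0 - (1.0 + self.node_gradient[node]) + self.eps


def build_gradient_graph(
    bscan: BScan, polarity: str, smooth_sigma: float = 1.0
) -> GradientGraph:
    """Build the boundary-search graph for one gradient polarity.

    The image is smoothed axially with a Gaussian (``smooth_sigma`` pixels)
    before the vertical central-difference gradient is taken; the gradient
    is signed by polarity ("dark_to_light": intensity increasing with depth
    scores high) and min-max normalised to [0, 1].
    """
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    if bscan.n_rows < 3:
        raise ValueError("image must have at least 3 rows")
    image = bscan.intensity
    if smooth_sigma > 0:
        image = gaussian_filter1d(image, smooth_sigma, axis=0, mode="nearest")
    grad = np.gradient(image, axis=0)
    if polarity == "light_to_dark":
        grad = -grad
    lo, hi = grad.min(), grad.max()
    if hi > lo:
        g = (grad - lo) / (hi - lo)
    else:
        g = np.zeros_like(grad)
    return GradientGraph(node_gradient=g, polarity=polarity)


def _band_arrays(
    graph: GradientGraph, search_band: tuple[np.ndarray, np.ndarray] | None
) -> tuple[np.ndarray, np.ndarray]:
    h, w = graph.shape
    if search_band is None:
        return np.zeros(w, dtype=int), np.full(w, h - 1, dtype=int)
    lo = np.clip(np.asarray(search_band[0], dtype=int), 0, h - 1)
    hi = np.clip(np.asarray(search_band[1], dtype=int), 0, h - 1)
    if lo.shape != (w,) or hi.shape != (w,):
        raise ValueError("band arrays must have one entry per column")
    if np.any(lo > hi):
        bad = np.nonzero(lo > hi)[0]
        raise ValueError(f"search band empty at columns {bad[:10].tolist()}")
    return lo, hi


def shortest_path(
    graph: GradientGraph,
    search_band: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Minimum-cost left-to-right path; returns (row per column, total cost).

    The cost includes the two virtual entry/exit edges.  Ties are broken
    deterministically in favour of the shallower (smaller) row, then the
    smaller column, by candidate ordering.
    """
    g = graph.node_gradient
    h, w = g.shape
    lo, hi = _band_arrays(graph, search_band)
    rows = np.arange(h)
    inf = np.inf

    banned = (rows[:, None] < lo[None, :]) | (rows[:, None] > hi[None, :])
    dist = np.where(banned[:, 0], inf, 1.0 - g[:, 0] + graph.eps)
    parent = np.full((h, w), -1, dtype=np.int32)
    for c in range(1, w):
        prev = dist
        # candidate predecessors ordered r-1, r, r+1 so argmin's first-hit
        # rule prefers the shallower row on ties
        cand = np.full((3, h), inf)
        cand[0, 1:] = prev[:-1] + (2.0 - g[:-1, c - 1] - g[1:, c] + graph.eps)
        cand[1, :] = prev + (2.0 - g[:, c - 1] - g[:, c] + graph.eps)
        cand[2, :-1] = prev[1:] + (2.0 - g[1:, c - 1] - g[:-1, c] + graph.eps)
        choice = np.argmin(cand, axis=0)
        dist = cand[choice, rows]
        parent[:, c] = rows + choice - 1
        dist = np.where(banned[:, c], inf, dist)
    dist = dist + (1.0 - g[:, -1] + graph.eps)
    end = int(np.argmin(dist))
    total = float(dist[end])
    if not np.isfinite(total):
        raise ValueError("no admissible path through the search band")
    path = np.empty(w, dtype=int)
    r = end
    for c in range(w - 1, -1, -1):
        path[c] = r
        if c:
            r = int(parent[r, c])
    return path, total


def find_boundary(
    graph: GradientGraph,
    search_band: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-column depth of the minimum-cost boundary within the band."""
    path, _ = shortest_path(graph, search_band)
    return path
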