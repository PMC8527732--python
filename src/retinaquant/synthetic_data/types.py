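"""Shared ground-truth container for the phantom generators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GroundTruth:
    """What a phantom generator knows to be true about its output.

    Only the fields relevant to the producing generator are populated.
    """

    true_boundaries: np.ndarray | None = None
    true_skeleton_density: float | None = None
    true_faz_area_mm2: float | None = None
    true_coefficients: dict = field(default_factory=dict)
    #: Optional generator-internal arrays (masks etc.) for oracle checks.
    arrays: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_boundaries is not None:
            b = np.asarray(self.true_boundaries, dtype=float)
            if np.any(np.diff(b, axis=0) < 0):
                raise ValueError("true boundaries must be ordered in depth")
            self.true_boundaries = b
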