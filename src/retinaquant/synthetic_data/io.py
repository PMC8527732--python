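"""File-boundary helpers: 8-bit PNG / float TIFF images, JSON sidecars, CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import GroundTruth


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write a [0, 1] float image as 8-bit PNG or 32-bit float TIFF by suffix."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    elif path.suffix.lower() == ".png":
        eight_bit = np.clip(np.round(image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(eight_bit, mode="L").save(path)
    else:
        raise ValueError(f"unsupported image suffix {path.suffix!r}")
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF to a [0, 1] float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
        if arr.max() > 1.0:
            arr = arr / 255.0
        return np.clip(arr, 0.0, 1.0)
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return arr / 255.0


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    payload: dict = {"true_coefficients": truth.true_coefficients}
    if truth.true_boundaries is not None:
        payload["true_boundaries"] = np.asarray(truth.true_boundaries).tolist()
    if truth.true_skeleton_density is not None:
        payload["true_skeleton_density"] = truth.true_skeleton_density
    if truth.true_faz_area_mm2 is not None:
        payload["true_faz_area_mm2"] = truth.true_faz_area_mm2
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    return path
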