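"""Versioned fixture bundles for tests and demos."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..synthetic_data import (
    AngiogramPhantomSpec,
    BScanPhantomSpec,
    CohortSpec,
    generate_angiogram,
    generate_bscan,
    generate_cohort,
    write_cohort_csv,
    write_ground_truth_json,
    write_image,
)

FIXTURE_VERSION = 1


def make_fixtures(out_dir: str | Path, seed: int = 0) -> Path:
    """Write a small phantom + cohort fixture set with a manifest.

    Contents: three B-scans (noise-free, noisy, foveal pit), three
    angiograms spanning the published density range, one cohort CSV, and
    JSON ground-truth sidecars.  Regeneration from the recorded seed is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": FIXTURE_VERSION, "seed": seed,
                      "bscans": [], "angiograms": [], "cohorts": []}

    bscan_specs = [
        ("bscan_clean", BScanPhantomSpec(noise_sd=0.0, seed=seed)),
        ("bscan_noisy", BScanPhantomSpec(noise_sd=0.05, seed=seed + 1)),
        ("bscan_pit", BScanPhantomSpec(foveal_pit=True, noise_sd=0.02, seed=seed + 2)),
    ]
    for name, spec in bscan_specs:
        bscan, truth = generate_bscan(spec)
        write_image(out_dir / f"{name}.tif", bscan.intensity)
        write_ground_truth_json(out_dir / f"{name}.json", truth)
        manifest["bscans"].append(
            {"name": name, "image": f"{name}.tif", "truth": f"{name}.json",
             "axial_pitch": spec.axial_pitch, "lateral_pitch": spec.lateral_pitch}
        )

    for i, density in enumerate((0.052, 0.062, 0.072)):
        name = f"angiogram_{int(density * 1000):03d}"
        spec = AngiogramPhantomSpec(
            target_skeleton_density=density, seed=seed + 10 + i, ssi=55.0
        )
        angiogram, truth = generate_angiogram(spec)
        write_image(out_dir / f"{name}.png", angiogram.intensity)
        write_ground_truth_json(out_dir / f"{name}.json", truth)
        manifest["angiograms"].append(
            {"name": name, "image": f"{name}.png", "truth": f"{name}.json",
             "scan_width_mm": spec.scan_width_mm, "ssi": spec.ssi}
        )

    cohort, truth = generate_cohort(CohortSpec(seed=seed))
    write_cohort_csv(out_dir / "cohort.csv", cohort)
    write_ground_truth_json(out_dir / "cohort_truth.json", truth)
    manifest["cohorts"].append({"name": "cohort", "table": "cohort.csv",
                                "truth": "cohort_truth.json"})

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path
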