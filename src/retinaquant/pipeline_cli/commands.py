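"""Click commands shared between the umbrella CLI and per-module entry points."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd


def setup_logging(log_file: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s [%(name)s] %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@click.command("segment")
@click.option("--in", "in_path", required=True, type=click.Path(exists=True))
@click.option("--axial-pitch", type=float, default=3.0, show_default=True,
              help="axial sampling, um/pixel")
@click.option("--lateral-pitch", type=float, default=11.75, show_default=True,
              help="lateral sampling, um/pixel")
@click.option("--fovea-column", type=int, default=None)
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--thickness-out", type=click.Path(), default=None)
def segment_cmd(in_path, axial_pitch, lateral_pitch, fovea_column, out_path,
                thickness_out):
    """Segment a B-scan image into six surfaces (CSV: one depth column per
    surface) and optionally write regional thicknesses as JSON."""
    from ..oct_layers import BScan, compute_thicknesses, segment_layers
    from ..synthetic_data.io import read_image

    image = read_image(in_path)
    bscan = BScan(image, axial_pitch, lateral_pitch, fovea_column)
    boundaries = segment_layers(bscan)
    frame = pd.DataFrame(
        {"column_index": np.arange(bscan.n_columns),
         **{name: depths for name, depths in boundaries.surfaces.items()}}
    )
    frame.to_csv(out_path, index=False, float_format="%.10g")
    click.echo(f"wrote {out_path}", err=True)
    if thickness_out:
        thicknesses = compute_thicknesses(boundaries, bscan)
        Path(thickness_out).write_text(
            json.dumps(thicknesses.as_dict(), indent=1, sort_keys=True)
        )
        click.echo(f"wrote {thickness_out}", err=True)


@click.command("quantify")
@click.option("--in", "in_path", required=True, type=click.Path(exists=True))
@click.option("--scan-width-mm", type=float, default=3.0, show_default=True)
@click.option("--plexus", type=click.Choice(["SRCP", "DRCP"]), default="DRCP",
              show_default=True)
@click.option("--ssi", type=float, default=None)
@click.option("--binarize-method", type=click.Choice(["otsu", "frangi_otsu"]),
              default="otsu", show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def quantify_cmd(in_path, scan_width_mm, plexus, ssi, binarize_method, out_path):
    """Quantify annular vessel density and FAZ area of an en-face angiogram."""
    from ..octa_metrics import EnFaceAngiogram, QuantifyConfig, quantify
    from ..synthetic_data.io import read_image

    image = read_image(in_path)
    angiogram = EnFaceAngiogram(image, scan_width_mm, plexus, ssi)
    result = quantify(angiogram, QuantifyConfig(binarize_method=binarize_method))
    Path(out_path).write_text(json.dumps(result, indent=1, sort_keys=True))
    click.echo(f"wrote {out_path}", err=True)


@click.command("classify")
@click.option("--cohort", "cohort_path", required=True, type=click.Path(exists=True))
@click.option("--controls-group", default="control", show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--summary", "summary_path", type=click.Path(), default=None)
def classify_cmd(cohort_path, controls_group, out_path, summary_path):
    """Classify eyes against the control normative reference; write per-eye
    flags and optionally a prevalence summary by acuity group."""
    from ..phenotyping import classify_cohort, fit_normative_reference, prevalence_table

    cohort = pd.read_csv(cohort_path, dtype={"etdrs_level": str})
    controls = cohort[cohort["group"] == controls_group]
    reference = fit_normative_reference(controls)
    others = cohort[cohort["group"] != controls_group].reset_index(drop=True)
    flags = classify_cohort(others, reference)
    pd.concat([others[["subject_id", "eye"]], flags], axis=1).to_csv(
        out_path, index=False
    )
    click.echo(f"wrote {out_path}", err=True)
    if summary_path:
        groups = pd.Series(
            np.where(others["bcva_logmar"] > 0, "decreased_bcva", "normal_bcva")
        )
        prevalence_table(flags, groups).to_csv(summary_path)
        click.echo(f"wrote {summary_path}", err=True)


@click.command("stats")
@click.option("--cohort", "cohort_path", required=True, type=click.Path(exists=True))
@click.option("--flags", "flags_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
def stats_cmd(cohort_path, flags_path, out_dir):
    """Run the statistical chain on an existing eye-level table."""
    from .config import PipelineConfig
    from .run import run_pipeline

    config = PipelineConfig(cohort_csv=cohort_path, output_dir=out_dir)
    config.imaging.n_imaged_eyes = 0
    run_pipeline(config)
    click.echo(f"wrote statistics bundle to {out_dir}", err=True)


@click.command("simulate")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--n-control", type=int, default=33, show_default=True)
@click.option("--n-dr-normal", type=int, default=53, show_default=True)
@click.option("--n-dr-decreased", type=int, default=36, show_default=True)
def simulate_cmd(seed, out_dir, n_control, n_dr_normal, n_dr_decreased):
    """Generate a phantom/cohort bundle (one B-scan, one angiogram, a table)."""
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

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bscan, btruth = generate_bscan(BScanPhantomSpec(seed=seed))
    write_image(out / "bscan.tif", bscan.intensity)
    write_ground_truth_json(out / "bscan.json", btruth)
    angiogram, atruth = generate_angiogram(AngiogramPhantomSpec(seed=seed))
    write_image(out / "angiogram.png", angiogram.intensity)
    write_ground_truth_json(out / "angiogram.json", atruth)
    cohort, ctruth = generate_cohort(
        CohortSpec(n_control=n_control, n_dr_normal=n_dr_normal,
                   n_dr_decreased=n_dr_decreased, seed=seed)
    )
    write_cohort_csv(out / "cohort.csv", cohort)
    write_ground_truth_json(out / "cohort_truth.json", ctruth)
    click.echo(f"wrote simulation bundle to {out_dir}", err=True)


@click.command("run-all")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None, help="override the config seed")
@click.option("--out", "out_dir", type=click.Path(), default=None,
              help="override the config output directory")
@click.option("--log-file", type=click.Path(), default=None)
def run_all_cmd(config_path, seed, out_dir, log_file):
    """Run the full pipeline (simulate -> image -> classify -> stats)."""
    from .config import PipelineConfig, load_config
    from .run import run_pipeline

    setup_logging(log_file)
    config = load_config(config_path) if config_path else PipelineConfig()
    if seed is not None:
        config.seed = seed
    if out_dir is not None:
        config.output_dir = out_dir
    result = run_pipeline(config)
    click.echo(json.dumps(result["outputs"], indent=1, sort_keys=True))


@click.command("fixtures")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def fixtures_cmd(seed, out_dir):
    """Write the versioned fixture bundle used by the test suite."""
    from .fixtures import make_fixtures

    manifest = make_fixtures(out_dir, seed)
    click.echo(f"wrote {manifest}", err=True)
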