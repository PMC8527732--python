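"""End-to-end pipeline: simulate/load -> image -> gate -> classify -> stats.

Seed fan-out: the global seed spawns one child seed per stage, in the fixed
order (cohort, bscans, angiograms), via ``numpy.random.SeedSequence``; each
imaged eye then takes consecutive sub-seeds from its stage sequence.  This
makes every stage individually reproducible from the provenance record.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..cohort_stats import (
    adjusted_group_compare,
    group_compare,
    interaction_model,
    multivariate_model,
    roc_cutoff,
    univariate_screen,
)
from ..oct_layers import compute_thicknesses, dme_exclusion_check, segment_layers
from ..octa_metrics import QuantifyConfig, quality_gate, quantify
from ..phenotyping import (
    REFERENCE_PARAMETERS,
    classify_cohort,
    fit_normative_reference,
    prevalence_table,
)
from ..synthetic_data import (
    AngiogramPhantomSpec,
    BScanPhantomSpec,
    CohortSpec,
    generate_angiogram,
    generate_bscan,
    generate_cohort,
)
from .config import PipelineConfig

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("cohort", "bscans", "angiograms")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _image_eye(
    row: pd.Series, config: PipelineConfig, bscan_seed: int, angio_seed: int
) -> dict[str, float]:
    """Re-derive one eye's imaging parameters through the phantom chain."""
    img = config.imaging
    thicknesses = np.array(
        [
            row["rnfl_um"],
            row["gcl_ipl_um"],
            row["inl_um"],
            row["opl_um"],
            max(row["total_um"] - (row["rnfl_um"] + row["gcl_ipl_um"]
                                   + row["inl_um"] + row["opl_um"]), 20.0),
        ]
    )
    bspec = BScanPhantomSpec(
        axial_pitch=img.axial_pitch_um,
        lateral_pitch=img.lateral_pitch_um,
        layer_thicknesses=thicknesses,
        noise_sd=img.bscan_noise_sd,
        seed=bscan_seed,
    )
    bscan, _ = generate_bscan(bspec)
    thick = compute_thicknesses(segment_layers(bscan), bscan)

    qconf = QuantifyConfig(
        min_ssi=config.analysis.min_ssi,
        binarize_method=config.analysis.binarize_method,
    )
    measured: dict[str, float] = thick.as_dict()
    for plexus, vd_key in (("SRCP", "vd_srcp"), ("DRCP", "vd_drcp")):
        target = float(np.clip(row[vd_key], 0.02, 0.12))
        aspec = AngiogramPhantomSpec(
            target_skeleton_density=target,
            faz_radius_mm=float(np.sqrt(max(row["faz_area_mm2"], 0.05) / np.pi)),
            noise_sd=img.angiogram_noise_sd,
            seed=angio_seed + (0 if plexus == "SRCP" else 1),
            plexus=plexus,
            ssi=img.default_ssi,
        )
        angiogram, _ = generate_angiogram(aspec)
        if not quality_gate(angiogram, config.analysis.min_ssi):
            raise PipelineStageError(
                "quality_gate", f"eye {row['subject_id']}/{row['eye']} failed SSI gate"
            )
        result = quantify(angiogram, qconf)
        measured[vd_key] = result["vd"]
        if plexus == config.imaging.faz_plexus:
            measured["faz_area_mm2"] = result["faz_area_mm2"]
    return measured


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write the result bundle.

    Returns a dict of output paths and key in-memory tables.  Any stage
    failure raises :class:`PipelineStageError` naming the stage.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    # --- cohort ---------------------------------------------------------
    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv, dtype={"etdrs_level": str})
        log.info("loaded cohort: %d eyes from %s", len(cohort), config.cohort_csv)
    else:
        sim = config.simulate
        spec = CohortSpec(
            n_control=sim.n_control,
            n_dr_normal=sim.n_dr_normal,
            n_dr_decreased=sim.n_dr_decreased,
            prob_both_eyes=sim.prob_both_eyes,
            subject_effect_sd=sim.subject_effect_sd,
            eye_effect_sd=sim.eye_effect_sd,
            residual_sd=sim.residual_sd,
            interaction_coefficient=sim.interaction_coefficient,
            seed=seeds["cohort"],
        )
        cohort, _ = generate_cohort(spec)
        log.info("simulated cohort: %d eyes", len(cohort))

    # --- imaging chain for a subset of eyes -----------------------------
    imaged_rows = []
    n_image = min(config.imaging.n_imaged_eyes, len(cohort))
    for k in range(n_image):
        row = cohort.iloc[k]
        try:
            measured = _image_eye(
                row, config, seeds["bscans"] + k, seeds["angiograms"] + 2 * k
            )
        except PipelineStageError:
            raise
        except Exception as err:  # noqa: BLE001 - stage attribution
            raise PipelineStageError(
                "imaging", f"eye {row['subject_id']}/{row['eye']}: {err}"
            ) from err
        for key in ("rnfl_um", "gcl_ipl_um", "inl_um", "opl_um", "total_um",
                    "vd_srcp", "vd_drcp", "faz_area_mm2"):
            cohort.iloc[k, cohort.columns.get_loc(key)] = measured[key]
        imaged_rows.append(
            {"subject_id": row["subject_id"], "eye": row["eye"], **measured}
        )

    # --- exclusion: clinically significant macular edema ----------------
    dme = cohort["total_um"] >= config.analysis.dme_threshold_um
    if dme.any():
        log.info("excluding %d eyes at the edema threshold", int(dme.sum()))
    cohort = cohort.loc[~dme].reset_index(drop=True)

    # --- phenotyping ----------------------------------------------------
    controls = cohort[cohort["group"] == "control"]
    if len(controls) < 2:
        raise PipelineStageError("phenotyping", "need >= 2 control eyes")
    reference = fit_normative_reference(controls)
    dr = cohort[cohort["group"] != "control"].reset_index(drop=True)
    if dr.empty:
        raise PipelineStageError("phenotyping", "no diabetic eyes to classify")
    flags = classify_cohort(dr, reference)
    bcva_group = np.where(dr["bcva_logmar"] > 0, "decreased_bcva", "normal_bcva")
    table2_bcva = prevalence_table(flags, pd.Series(bcva_group))
    table2_etdrs = prevalence_table(flags, dr["etdrs_level"].astype(str))

    # --- statistics -----------------------------------------------------
    table1_rows = []
    for param in ("age", "dm_duration", "bcva_logmar"):
        cmp_ = group_compare(cohort, param, "group")
        for g, (m, sd, n) in cmp_.summaries.items():
            table1_rows.append(
                {"parameter": param, "group": g, "mean": m, "sd": sd, "n": n,
                 "test": cmp_.test, "p_value": cmp_.p_value}
            )
    table1 = pd.DataFrame(table1_rows)

    table3_rows = []
    for param in REFERENCE_PARAMETERS:
        raw = group_compare(cohort, param, "group")
        adj = adjusted_group_compare(cohort, param, "group")
        row = {"parameter": param, "p_raw": raw.p_value, "p_adjusted": adj.overall_p}
        for g, (m, sd, n) in raw.summaries.items():
            row[f"{g}_mean"] = m
            row[f"{g}_sd"] = sd
        for (gi, gj), p in adj.pairwise_p.items():
            row[f"p_{gi}_vs_{gj}"] = p
        table3_rows.append(row)
    table3 = pd.DataFrame(table3_rows)

    dr_stats = dr.copy()
    uni = univariate_screen(dr_stats, alpha=config.analysis.alpha)
    table4_uni = pd.concat(
        [r.to_frame().assign(predictor_set=r.predictors[0]) for r in uni]
    )
    selected = [r.predictors[0] for r in uni if r.notes["significant"]]
    if not selected:
        selected = ["age"]
    multi = multivariate_model(dr_stats, selected, alpha=config.analysis.alpha)
    table4_multi = multi.to_frame()
    inter = interaction_model(dr_stats)
    table5 = inter.to_frame()

    dr_stats["bcva_decreased"] = (dr_stats["bcva_logmar"] > 0).astype(int)
    roc_rows = []
    if dr_stats["bcva_decreased"].nunique() == 2:
        for param in REFERENCE_PARAMETERS:
            r = roc_cutoff(dr_stats, param)
            roc_rows.append(
                {"parameter": param, "auc": r.auc, "cutoff": r.cutoff,
                 "sensitivity": r.sensitivity, "specificity": r.specificity,
                 "lower_is_abnormal": r.lower_is_abnormal}
            )
    roc = pd.DataFrame(roc_rows)

    # --- outputs --------------------------------------------------------
    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> str:
        path = out_dir / name
        frame.to_csv(path, index=index, float_format="%.10g")
        return str(path)

    outputs = {
        "cohort": _write("cohort.csv", cohort),
        "flags": _write("flags.csv", pd.concat([dr[["subject_id", "eye"]], flags], axis=1)),
        "table2_by_bcva": _write("table2_by_bcva.csv", table2_bcva, index=True),
        "table2_by_etdrs": _write("table2_by_etdrs.csv", table2_etdrs, index=True),
        "table1": _write("table1.csv", table1),
        "table3": _write("table3.csv", table3),
        "table4_univariate": _write("table4_univariate.csv", table4_uni, index=True),
        "table4_multivariate": _write("table4_multivariate.csv", table4_multi, index=True),
        "table5": _write("table5.csv", table5, index=True),
        "roc": _write("roc.csv", roc),
    }
    if imaged_rows:
        outputs["imaging_records"] = _write(
            "imaging_records.csv", pd.DataFrame(imaged_rows)
        )
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "n_eyes_analyzed": int(len(cohort)),
        "n_eyes_imaged": n_image,
        "n_eyes_excluded_dme": int(dme.sum()),
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=1, sort_keys=True))
    outputs["provenance"] = str(prov_path)
    return {
        "outputs": outputs,
        "cohort": cohort,
        "flags": flags,
        "reference": reference,
        "multivariate": multi,
        "interaction": inter,
    }
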