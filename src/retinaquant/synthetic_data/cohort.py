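"""Synthetic eye-level cohorts with a shared per-participant random effect
and a linear visual-acuity data-generating model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GroundTruth

GROUPS: tuple[str, ...] = ("control", "dr_normal_bcva", "dr_decreased_bcva")

#: Imaging parameters generated per eye.
PARAM_COLUMNS: tuple[str, ...] = (
    "vd_srcp",
    "vd_drcp",
    "faz_area_mm2",
    "rnfl_um",
    "gcl_ipl_um",
    "inl_um",
    "opl_um",
    "total_um",
)

#: Group-conditional means of the imaging parameters plus age and diabetes
#: duration (years).  Values mirror published normative/diabetic macular
#: magnitudes for a 3x3-mm scan.
DEFAULT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "control": {
        "vd_srcp": 0.056, "vd_drcp": 0.072, "faz_area_mm2": 0.325,
        "rnfl_um": 28.46, "gcl_ipl_um": 72.40, "inl_um": 17.52,
        "opl_um": 10.15, "total_um": 239.46, "age": 56.94, "dm_duration": 0.0,
    },
    "dr_normal_bcva": {
        "vd_srcp": 0.054, "vd_drcp": 0.069, "faz_area_mm2": 0.342,
        "rnfl_um": 30.04, "gcl_ipl_um": 73.62, "inl_um": 17.10,
        "opl_um": 10.89, "total_um": 240.69, "age": 50.72, "dm_duration": 7.62,
    },
    "dr_decreased_bcva": {
        "vd_srcp": 0.052, "vd_drcp": 0.062, "faz_area_mm2": 0.401,
        "rnfl_um": 29.04, "gcl_ipl_um": 70.24, "inl_um": 17.10,
        "opl_um": 10.60, "total_um": 236.31, "age": 60.47, "dm_duration": 11.19,
    },
}

DEFAULT_GROUP_SDS: dict[str, dict[str, float]] = {
    "control": {
        "vd_srcp": 0.004, "vd_drcp": 0.005, "faz_area_mm2": 0.132,
        "rnfl_um": 2.88, "gcl_ipl_um": 5.59, "inl_um": 3.66,
        "opl_um": 1.49, "total_um": 21.01, "age": 7.32, "dm_duration": 0.0,
    },
    "dr_normal_bcva": {
        "vd_srcp": 0.005, "vd_drcp": 0.006, "faz_area_mm2": 0.117,
        "rnfl_um": 3.14, "gcl_ipl_um": 4.82, "inl_um": 3.41,
        "opl_um": 2.51, "total_um": 16.13, "age": 9.43, "dm_duration": 5.27,
    },
    "dr_decreased_bcva": {
        "vd_srcp": 0.006, "vd_drcp": 0.007, "faz_area_mm2": 0.097,
        "rnfl_um": 3.64, "gcl_ipl_um": 6.21, "inl_um": 3.82,
        "opl_um": 2.36, "total_um": 19.14, "age": 10.55, "dm_duration": 7.21,
    },
}

#: Per-group probabilities of retinopathy-severity levels (20, 35, 43-53).
DEFAULT_ETDRS_PROBS: dict[str, tuple[float, float, float]] = {
    "control": (1.0, 0.0, 0.0),
    "dr_normal_bcva": (39 / 88, 33 / 88, 16 / 88),
    "dr_decreased_bcva": (17 / 44, 19 / 44, 8 / 44),
}
ETDRS_LEVELS: tuple[str, ...] = ("20", "35", "43-53")

#: Visual-acuity linear predictor (logMAR): intercept, age, deep-plexus
#: vessel density and GCL-IPL thickness terms.
DEFAULT_BCVA_COEFFICIENTS: dict[str, float] = {
    "intercept": 0.575,
    "age": 0.002,
    "vd_drcp": -6.194,
    "gcl_ipl_um": -0.004,
}

#: Coefficient of the centred GCL-IPL x deep-plexus-density product term in
#: the published interaction fit; pass as ``interaction_coefficient`` to
#: generate cohorts with an interactive effect (default generator omits it).
PUBLISHED_INTERACTION_COEFFICIENT = -0.083

#: Centres used when forming the interaction product (control means).
INTERACTION_CENTERS: dict[str, float] = {"gcl_ipl_um": 72.40, "vd_drcp": 0.072}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``subject_effect_sd`` and ``eye_effect_sd`` act on the standardised
    scale: each parameter is ``mean + sd * (u_i + e_ij) / sqrt(su^2 + se^2)``
    with a per-subject ``u_i`` shared by both eyes, so the intraclass
    correlation is ``su^2 / (su^2 + se^2)`` while marginal SDs match the
    group tables.  ``residual_sd`` is a free choice calibrated so that
    simulated visual-acuity SDs land in the 0.06-0.14 logMAR range.
    """

    n_control: int = 33
    n_dr_normal: int = 53
    n_dr_decreased: int = 36
    prob_both_eyes: float = 0.5
    group_means: dict = field(default_factory=lambda: DEFAULT_GROUP_MEANS)
    group_sds: dict = field(default_factory=lambda: DEFAULT_GROUP_SDS)
    etdrs_probs: dict = field(default_factory=lambda: DEFAULT_ETDRS_PROBS)
    bcva_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_BCVA_COEFFICIENTS)
    )
    interaction_coefficient: float = 0.0
    subject_effect_sd: float = 0.7
    eye_effect_sd: float = 1.0
    residual_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_dr_normal, self.n_dr_decreased) < 0:
            raise ValueError("subject counts must be non-negative")
        if self.n_control + self.n_dr_normal + self.n_dr_decreased <= 0:
            raise ValueError("need at least one subject in some group")
        if not 0 <= self.prob_both_eyes <= 1:
            raise ValueError("prob_both_eyes must lie in [0, 1]")
        for d in (self.group_sds,):
            for g in GROUPS:
                if any(v < 0 for v in d[g].values()):
                    raise ValueError("SDs must be non-negative")
        if self.subject_effect_sd < 0 or self.eye_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError("effect SDs must be non-negative")
        if self.subject_effect_sd == 0 and self.eye_effect_sd == 0:
            raise ValueError("subject and eye effect SDs cannot both be zero")

    @property
    def intraclass_correlation(self) -> float:
        su2 = self.subject_effect_sd**2
        return su2 / (su2 + self.eye_effect_sd**2)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw an eye-level cohort table.

    Columns: subject_id, eye (OD/OS), group, age, dm_duration, etdrs_level,
    the eight imaging parameters, bcva_logmar, and a derived
    ``bcva_decreased`` indicator (logMAR > 0).  Age and diabetes duration
    are subject-level draws; imaging parameters and the acuity residual mix
    the shared subject effect with eye-level noise as described on
    :class:`CohortSpec`.
    """
    rng = np.random.default_rng(spec.seed)
    norm = np.sqrt(spec.subject_effect_sd**2 + spec.eye_effect_sd**2)
    group_sizes = {
        "control": spec.n_control,
        "dr_normal_bcva": spec.n_dr_normal,
        "dr_decreased_bcva": spec.n_dr_decreased,
    }
    coef = spec.bcva_coefficients
    frames: list[pd.DataFrame] = []
    subject_offset = 0
    for group in GROUPS:
        ns = group_sizes[group]
        if ns == 0:
            continue
        means, sds = spec.group_means[group], spec.group_sds[group]
        probs = spec.etdrs_probs[group]

        n_eyes = 1 + (rng.random(ns) < spec.prob_both_eyes).astype(int)
        age = means["age"] + sds["age"] * rng.standard_normal(ns)
        dm = np.maximum(
            means["dm_duration"] + sds["dm_duration"] * rng.standard_normal(ns), 0.0
        )
        u = spec.subject_effect_sd * rng.standard_normal(ns)
        u_bcva = spec.subject_effect_sd * rng.standard_normal(ns)

        idx = np.repeat(np.arange(ns), n_eyes)
        m = idx.size
        # eye index within subject: 0 = right (OD), 1 = left (OS)
        eye_rank = np.arange(m) - np.repeat(np.cumsum(n_eyes) - n_eyes, n_eyes)

        e = spec.eye_effect_sd * rng.standard_normal((m, len(PARAM_COLUMNS)))
        z = (u[idx, None] + e) / norm
        data = {
            p: means[p] + sds[p] * z[:, i] for i, p in enumerate(PARAM_COLUMNS)
        }
        lp = (
            coef["intercept"]
            + coef["age"] * age[idx]
            + coef["vd_drcp"] * data["vd_drcp"]
            + coef["gcl_ipl_um"] * data["gcl_ipl_um"]
        )
        if spec.interaction_coefficient != 0.0:
            lp = lp + spec.interaction_coefficient * (
                (data["gcl_ipl_um"] - INTERACTION_CENTERS["gcl_ipl_um"])
                * (data["vd_drcp"] - INTERACTION_CENTERS["vd_drcp"])
            )
        e_bcva = spec.eye_effect_sd * rng.standard_normal(m)
        bcva = lp + spec.residual_sd * (u_bcva[idx] + e_bcva) / norm

        subject_ids = np.array(
            [f"S{subject_offset + i + 1:05d}" for i in range(ns)]
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[idx],
                    "eye": np.where(eye_rank == 0, "OD", "OS"),
                    "group": group,
                    "age": age[idx],
                    "dm_duration": dm[idx],
                    "etdrs_level": np.array(ETDRS_LEVELS)[
                        rng.choice(len(ETDRS_LEVELS), size=m, p=probs)
                    ],
                    **data,
                    "bcva_logmar": bcva,
                }
            )
        )
        subject_offset += ns
    df = pd.concat(frames, ignore_index=True)
    df["bcva_decreased"] = (df["bcva_logmar"] > 0).astype(int)
    truth = GroundTruth(
        true_coefficients={
            **coef,
            "interaction": spec.interaction_coefficient,
            "residual_sd": spec.residual_sd,
            "subject_effect_sd": spec.subject_effect_sd,
            "eye_effect_sd": spec.eye_effect_sd,
        }
    )
    return df, truth
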