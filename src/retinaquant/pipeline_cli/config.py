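"""Pipeline configuration: nested key/value file with strict key checking."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulateSection:
    n_control: int = 33
    n_dr_normal: int = 53
    n_dr_decreased: int = 36
    prob_both_eyes: float = 0.5
    subject_effect_sd: float = 0.7
    eye_effect_sd: float = 1.0
    residual_sd: float = 0.08
    interaction_coefficient: float = 0.0


@dataclass
class ImagingSection:
    #: Eyes whose record is derived through the full phantom-imaging chain
    #: (B-scan segmentation + angiogram quantification); the rest keep
    #: their generated table values.  Imaging is the slow path.
    n_imaged_eyes: int = 2
    axial_pitch_um: float = 3.0
    lateral_pitch_um: float = 11.75
    bscan_noise_sd: float = 0.02
    angiogram_noise_sd: float = 0.02
    default_ssi: float = 55.0
    faz_plexus: str = "SRCP"


@dataclass
class AnalysisSection:
    annulus_outer_diameter_mm: float = 2.5
    annulus_inner_exclusion_diameter_mm: float = 0.6
    z_threshold: float = 1.96
    min_ssi: float = 40.0
    dme_threshold_um: float = 275.0
    alpha: float = 0.05
    binarize_method: str = "otsu"


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results"
    cohort_csv: str | None = None  # use an existing table instead of simulating
    simulate: SimulateSection = field(default_factory=SimulateSection)
    imaging: ImagingSection = field(default_factory=ImagingSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {"simulate": SimulateSection, "imaging": ImagingSection,
             "analysis": AnalysisSection}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from nested dicts; unknown keys are errors."""
    data = dict(data or {})
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in list(data):
        if key not in top_fields:
            raise ValueError(f"unknown configuration key {key!r}")
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"section {name!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
        kwargs[name] = cls(**section)
    kwargs.update(data)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
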