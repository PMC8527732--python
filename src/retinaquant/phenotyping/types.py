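"""Domain types for normative-reference phenotype classification."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

#: Eye-level parameters entering the normative reference.
REFERENCE_PARAMETERS: tuple[str, ...] = (
    "vd_srcp",
    "vd_drcp",
    "faz_area_mm2",
    "rnfl_um",
    "gcl_ipl_um",
    "inl_um",
    "opl_um",
    "total_um",
)

#: Component flag -> (parameter, abnormal direction).
COMPONENT_DEFINITIONS: dict[str, tuple[str, str]] = {
    "vd_srcp_decrease": ("vd_srcp", "below"),
    "vd_drcp_decrease": ("vd_drcp", "below"),
    "faz_increase": ("faz_area_mm2", "above"),
    "rnfl_thinning": ("rnfl_um", "below"),
    "gcl_ipl_thinning": ("gcl_ipl_um", "below"),
    "inl_thickening": ("inl_um", "above"),
    "opl_thickening": ("opl_um", "above"),
    "total_thickening": ("total_um", "above"),
}

#: Composite phenotype -> component flags combined by OR.
COMPOSITE_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "ischemia": ("vd_srcp_decrease", "vd_drcp_decrease", "faz_increase"),
    "neurodegeneration": ("rnfl_thinning", "gcl_ipl_thinning"),
    "subclinical_edema": ("inl_thickening", "opl_thickening", "total_thickening"),
}

#: Number of control SDs beyond which a value is called abnormal (strict).
Z_THRESHOLD = 1.96

VALID_GROUPS = ("control", "dr_normal_bcva", "dr_decreased_bcva")
VALID_ETDRS_LEVELS = ("20", "35", "43-53")


@dataclass
class NormativeReference:
    """Per-parameter control mean and SD driving the abnormality rule."""

    means: dict[str, float]
    sds: dict[str, float]
    n_eyes: int = 0

    def __post_init__(self) -> None:
        for p in REFERENCE_PARAMETERS:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"reference missing parameter {p!r}")
            if not self.sds[p] > 0:
                raise ValueError(f"reference SD for {p!r} must be positive")

    def threshold(self, component: str) -> float:
        """Abnormality cut point for one component flag."""
        param, direction = COMPONENT_DEFINITIONS[component]
        offset = Z_THRESHOLD * self.sds[param]
        return self.means[param] - offset if direction == "below" else self.means[param] + offset


@dataclass
class PhenotypeFlags:
    """Component and composite abnormality indicators for one eye."""

    vd_srcp_decrease: bool
    vd_drcp_decrease: bool
    faz_increase: bool
    rnfl_thinning: bool
    gcl_ipl_thinning: bool
    inl_thickening: bool
    opl_thickening: bool
    total_thickening: bool
    ischemia: bool = field(init=False)
    neurodegeneration: bool = field(init=False)
    subclinical_edema: bool = field(init=False)

    def __post_init__(self) -> None:
        self.ischemia = (
            self.vd_srcp_decrease or self.vd_drcp_decrease or self.faz_increase
        )
        self.neurodegeneration = self.rnfl_thinning or self.gcl_ipl_thinning
        self.subclinical_edema = (
            self.inl_thickening or self.opl_thickening or self.total_thickening
        )

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ProportionCI:
    """A printed-table proportion: count/n with a 95% interval in percent."""

    count: int
    n: int
    percent: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.n:
            raise ValueError("need 0 <= count <= n")
        if not (0 <= self.lower <= self.percent + 1e-9 and
                self.percent <= self.upper + 1e-9 and self.upper <= 100):
            raise ValueError("interval must satisfy 0 <= lower <= percent <= upper <= 100")
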