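"""Fit the normative reference and apply the SD-band abnormality rule."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    COMPONENT_DEFINITIONS,
    COMPOSITE_DEFINITIONS,
    REFERENCE_PARAMETERS,
    Z_THRESHOLD,
    NormativeReference,
    PhenotypeFlags,
)


def fit_normative_reference(control_records: pd.DataFrame) -> NormativeReference:
    """Sample mean and SD of each reference parameter over control eyes.

    Requires at least two eyes and complete, non-degenerate parameters.
    """
    if len(control_records) < 2:
        raise ValueError("need at least two control eyes to fit a reference")
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for p in REFERENCE_PARAMETERS:
        if p not in control_records.columns:
            raise ValueError(f"control table lacks column {p!r}")
        values = np.asarray(control_records[p], dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValueError(f"missing/non-finite values in control column {p!r}")
        means[p] = float(values.mean())
        sds[p] = float(values.std(ddof=1))
        if sds[p] == 0:
            raise ValueError(f"control parameter {p!r} has zero variance")
    return NormativeReference(means=means, sds=sds, n_eyes=len(control_records))


def classify_eye(
    record: Mapping[str, float], reference: NormativeReference
) -> PhenotypeFlags:
    """Flag each component strictly beyond mean +/- 1.96 SD in its abnormal
    direction, and derive the composite phenotypes.

    A missing or non-finite parameter raises, because every composite uses
    each of its components.
    """
    flags: dict[str, bool] = {}
    for component, (param, direction) in COMPONENT_DEFINITIONS.items():
        if param not in record or not np.isfinite(record[param]):
            raise ValueError(
                f"parameter {param!r} missing for component {component!r}; "
                "composite phenotypes would be undefined"
            )
        value = float(record[param])
        cut = reference.threshold(component)
        flags[component] = value < cut if direction == "below" else value > cut
    return PhenotypeFlags(**flags)


def classify_cohort(
    records: pd.DataFrame, reference: NormativeReference
) -> pd.DataFrame:
    """Vectorised :func:`classify_eye` over an eye-level table.

    Returns a DataFrame aligned with ``records`` holding the eight
    component flags and the three composites as integers (0/1).
    """
    out = pd.DataFrame(index=records.index)
    for component, (param, direction) in COMPONENT_DEFINITIONS.items():
        values = np.asarray(records[param], dtype=float)
        if np.any(~np.isfinite(values)):
            raise ValueError(f"missing/non-finite values in column {param!r}")
        mean, sd = reference.means[param], reference.sds[param]
        if direction == "below":
            out[component] = values < mean - Z_THRESHOLD * sd
        else:
            out[component] = values > mean + Z_THRESHOLD * sd
    for composite, components in COMPOSITE_DEFINITIONS.items():
        out[composite] = out[list(components)].any(axis=1)
    return out.astype(int)
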