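"""Proportion summaries with normal-approximation confidence intervals."""

from __future__ import annotations

import math

from .types import ProportionCI

Z_95 = 1.96


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching printed-table formatting."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def prevalence_with_ci(count: int, n: int) -> ProportionCI:
    """Percentage with a 95% Wald interval, clipped to [0, 100] and rounded
    half-up to one decimal (the printed-table convention)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError("need 0 <= count <= n")
    p = count / n
    half_width = Z_95 * math.sqrt(p * (1.0 - p) / n)
    return ProportionCI(
        count=count,
        n=n,
        percent=round_half_up(100.0 * p),
        lower=round_half_up(max(100.0 * (p - half_width), 0.0)),
        upper=round_half_up(min(100.0 * (p + half_width), 100.0)),
    )
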