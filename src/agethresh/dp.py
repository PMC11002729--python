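"""Conservative adjustment of noisy (differentially-private) counts.

Modern census releases publish counts with calibrated random noise.  A
noisy count used as an equivalence-class size can overstate how many
people actually share a value, so before deriving an age threshold each
reported count is replaced by the lower end of a one-sided confidence
interval: the largest value L such that, under the noise model, the true
count exceeds L with at least the stated probability.

The reported count is modeled as true count plus additive zero-centred
noise of known scale (Gaussian or Laplace).  The one-sided offset at
confidence level c is the noise distribution's c-quantile:

    gaussian:  q = z_c * sigma
    laplace:   q = b * ln(1 / (2 * (1 - c)))        for c > 1/2

and the adjusted count is ``floor(reported - q)`` clamped at zero — both
flooring and clamping err on the side of a smaller, safer group size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .census import CensusCell, CensusTable

MECHANISMS = ("gaussian", "laplace", "none")


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise mechanism, scale (sigma or b, in persons), and confidence."""

    mechanism: str
    scale: float = 0.0
    confidence: float = 0.99

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.mechanism != "none" and not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not 0.5 < self.confidence < 1:
            raise ValueError(
                f"confidence must lie in (0.5, 1), got {self.confidence}"
            )


def one_sided_offset(model: NoiseModel) -> float:
    """The c-quantile of the noise distribution, subtracted from reported counts."""
    if model.mechanism == "none":
        return 0.0
    if model.mechanism == "gaussian":
        return stats.norm.ppf(model.confidence) * model.scale
    return stats.laplace.ppf(model.confidence, scale=model.scale)


def noise_lower_bound(reported_count: float, model: NoiseModel) -> int:
    """One-sided confidence lower bound for the true count behind a noisy one."""
    adjusted = math.floor(reported_count - one_sided_offset(model))
    return max(0, adjusted)


def adjust_table(table: CensusTable, model: NoiseModel) -> CensusTable:
    """Apply :func:`noise_lower_bound` to every cell; structure is unchanged.

    Per-cell adjustment before any summing is deliberate: a tail count
    assembled from individually lower-bounded cells is smaller than a
    lower bound on the summed tail, which is the more conservative of the
    two readings for threshold derivation.
    """
    cells = [
        CensusCell(c.year, c.state, c.sex, c.age_bin, noise_lower_bound(c.count, model))
        for c in table.cells
    ]
    note = (
        f"{table.metadata} [dp-adjusted: {model.mechanism}, scale={model.scale}, "
        f"confidence={model.confidence}]"
    ).strip()
    return CensusTable(cells, metadata=note)
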