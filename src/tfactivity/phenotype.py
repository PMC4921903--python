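"""Closed-form phenotype readout calculations.

Three small formulas used for the wet-lab readouts that accompany the
transcriptomic analysis: growth inhibition by a gas atmosphere, the
siderophore halo statistic from a chelating-dye plate assay, and the
phosphorylated fraction of a response regulator from band intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GrowthPair:
    """Optical densities with (x) and without (y) the test atmosphere."""

    x: float  # OD600 in the CO atmosphere
    y: float  # OD600 in the matched atmosphere without CO

    def __post_init__(self) -> None:
        if self.y <= 0:
            raise ValueError("reference growth y must be positive")
        if self.x < 0:
            raise ValueError("growth x must be non-negative")


def percent_inhibition(pair: GrowthPair) -> float:
    """Percentage inhibition of growth: 100 - (x/y * 100).

    Negative values mean growth stimulation by the test atmosphere and are
    reported as-is, never clipped.
    """
    return 100.0 - (pair.x / pair.y * 100.0)


def halo_statistic(halo_diameter: float, colony_diameter: float) -> float:
    """Siderophore halo size: (colony + halo diameter) minus colony diameter, mm."""
    if colony_diameter < 0:
        raise ValueError("colony diameter must be non-negative")
    if halo_diameter < colony_diameter:
        raise ValueError(
            f"halo diameter {halo_diameter} smaller than colony diameter "
            f"{colony_diameter}: measurement inconsistency"
        )
    return halo_diameter - colony_diameter


def halo_batch(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Mean and sample sd of the halo statistic over replicate measurements."""
    stats = np.array([halo_statistic(h, c) for h, c in pairs])
    sd = float(stats.std(ddof=1)) if stats.size > 1 else 0.0
    return float(stats.mean()), sd


def arcap_fraction(intensity_phosphorylated: float, intensity_unphosphorylated: float) -> float:
    """Phosphorylated ArcA as a percent of total ArcA: 100 * P / (P + U)."""
    p, u = intensity_phosphorylated, intensity_unphosphorylated
    if p < 0 or u < 0:
        raise ValueError("band intensities must be non-negative")
    if p + u == 0:
        raise ValueError("both band intensities are zero")
    return 100.0 * p / (p + u)
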