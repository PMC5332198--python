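"""The health-impact equation and its concentration–response functions.

Premature-mortality change attributable to a sensitivity surface is the
linear rate-difference sum over grid cells

    Δy = Σ_i Σ_j  y0_ij · β · Δx_ij · Pop_ij

where y0 is the baseline adult mortality rate in the cell, β the
concentration–response function (CRF), Δx the concentration change and
Pop the adult population. Default CRFs, from the epidemiological
literature on long-term exposure: a 1% mortality increase per 1 μg/m³ of
annual-average PM2.5 (β = 0.01), and a 0.4% increase per 10 ppb of daily
8-hr maximum O3 (β = 0.0004/ppb), applied at monthly resolution.

Each modeled month (January, July) stands for six months: the half-year
impact is half the annual-rate impact computed as if that month's mean
Δx persisted all year, and the annual impact is the sum of the two
half-year values (equivalently the mean of the two annual rates). Signs
are preserved throughout — winter NOx→O3 titration yields negative Δy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exposure import ExposureGrid
from .grid import SensitivityField

__all__ = [
    "CRF",
    "PM25_CRF",
    "O3_CRF",
    "crf_for",
    "ImpactRecord",
    "cell_impacts",
    "annualized_mortality",
    "half_year_impact",
    "annual_impact",
    "within_state_fraction",
]

PERIODS = ("JAN_HALF", "JUL_HALF", "ANNUAL")


@dataclass(frozen=True)
class CRF:
    """Concentration–response function: fractional mortality increase per unit Δx."""

    pollutant: str
    beta: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.pollutant not in ("PM25", "O3"):
            raise ValueError(f"pollutant must be PM25 or O3, got {self.pollutant!r}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")


PM25_CRF = CRF("PM25", 0.01, "1% mortality increase per 1 ug/m3 annual-average PM2.5")
O3_CRF = CRF("O3", 0.0004, "0.4% mortality increase per 10 ppb daily 8-hr max O3")


def crf_for(pollutant: str, beta_override: float | None = None) -> CRF:
    """Default CRF for a pollutant, optionally with an overridden β."""
    base = PM25_CRF if pollutant == "PM25" else O3_CRF if pollutant == "O3" else None
    if base is None:
        raise ValueError(f"no CRF for pollutant {pollutant!r}")
    if beta_override is not None:
        return CRF(pollutant, beta_override, "override")
    return base


@dataclass
class ImpactRecord:
    """Premature-mortality change for one (source state, sector, pair, period)."""

    source_state: str
    sector: str
    precursor: str
    pollutant: str
    period: str
    delta_deaths: float

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")


def _check_match(field: SensitivityField, exposure: ExposureGrid, crf: CRF) -> None:
    if field.grid != exposure.grid:
        raise ValueError("field grid and exposure grid do not match")
    if crf.pollutant != field.pair.pollutant:
        raise ValueError(
            f"CRF pollutant {crf.pollutant} does not match field pollutant "
            f"{field.pair.pollutant}"
        )


def cell_impacts(field: SensitivityField, exposure: ExposureGrid, crf: CRF) -> np.ndarray:
    """Per-cell annual-rate mortality change y0·β·Δx·Pop (signed)."""
    _check_match(field, exposure, crf)
    return exposure.y0 * crf.beta * field.values * exposure.pop


def annualized_mortality(field: SensitivityField, exposure: ExposureGrid, crf: CRF) -> float:
    """Δy = Σ y0·β·Δx·Pop: annual-rate deaths if the month's mean Δx persisted all year."""
    return float(cell_impacts(field, exposure, crf).sum())


def half_year_impact(annual_rate_deaths: float) -> float:
    """Half-year deaths under the convention that each modeled month covers 6 months."""
    return annual_rate_deaths / 2.0


def annual_impact(jan_half: float, jul_half: float) -> float:
    """Annual deaths: sum of the two half-year values (mean of the two annual rates)."""
    return jan_half + jul_half


def within_state_fraction(field: SensitivityField, exposure: ExposureGrid, crf: CRF,
                          state_cell_mask: np.ndarray) -> float:
    """Percent of the field's total impact occurring in the masked (source-state) cells.

    Returns NaN when the total impact is exactly zero (flagged missing).
    """
    mask = np.asarray(state_cell_mask, dtype=bool)
    if mask.shape != field.grid.shape:
        raise ValueError("state_cell_mask shape does not match grid")
    impacts = cell_impacts(field, exposure, crf)
    total = impacts.sum()
    if total == 0:
        return float("nan")
    return float(impacts[mask].sum() / total * 100.0)
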