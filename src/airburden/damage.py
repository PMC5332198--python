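"""Emissions-normalized health damage functions and descriptive comparisons.

A health damage function (HDF) expresses a source-state's mortality
burden per 1,000 tons of an emitted precursor. Monthly HDFs treat the
month's conditions as if they held all year: annual-rate deaths divided
by 12 × the monthly tons, per kiloton. The annual HDF is the mean of the
January and July values — the mortality risk of uniform year-round
emissions. Signs are retained: negative January NOx→O3 damage functions
are a real feature (O3 titration), not an error.

States with very low emissions produce abnormally inflated HDFs (a tiny
deaths numerator over a tinier tons denominator); a configurable rule
flags, per (sector, pair), the k lowest-emitting states plus any state
below an absolute annual floor. Flagged entries are excluded from the
summary percentiles but kept in the output tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .health import ImpactRecord

__all__ = [
    "DamageFunction",
    "SummaryTable",
    "monthly_hdf",
    "annual_hdf",
    "flag_low_emission",
    "summarize",
]

log = logging.getLogger(__name__)

PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_RANK_COUNT = 5
DEFAULT_FLOOR_TONS = 1.0


@dataclass
class DamageFunction:
    """Deaths per 1,000 tons of precursor for one (state, sector, pair, period)."""

    source_state: str
    sector: str
    precursor: str
    pollutant: str
    period: str  # JAN, JUL or ANNUAL
    value: float  # deaths per 1,000 tons; NaN when emissions are zero
    annualized_emissions_tons: float
    low_emission_flag: bool = False

    def __post_init__(self) -> None:
        if self.period not in ("JAN", "JUL", "ANNUAL"):
            raise ValueError(f"period must be JAN, JUL or ANNUAL, got {self.period!r}")
        if self.annualized_emissions_tons > 0 and not math.isfinite(self.value):
            raise ValueError("value must be finite when emissions are positive")

    def key(self) -> tuple[str, str, str, str]:
        return (self.source_state, self.sector, self.precursor, self.pollutant)


def monthly_hdf(annual_rate_deaths: float, monthly_emissions_tons: float, *,
                source_state: str = "", sector: str = "", precursor: str = "",
                pollutant: str = "", period: str = "JAN") -> DamageFunction:
    """Monthly HDF: deaths per 1,000 tons if this month's conditions held all year.

    value = annual_rate_deaths / (monthly_tons × 12) × 1000. Zero emissions
    give an undefined (NaN) value with the low-emission flag set.
    """
    if monthly_emissions_tons < 0:
        raise ValueError(f"emissions must be >= 0, got {monthly_emissions_tons}")
    annual_tons = monthly_emissions_tons * 12.0
    if annual_tons == 0:
        return DamageFunction(source_state, sector, precursor, pollutant, period,
                              float("nan"), 0.0, low_emission_flag=True)
    value = annual_rate_deaths / annual_tons * 1000.0
    return DamageFunction(source_state, sector, precursor, pollutant, period,
                          value, annual_tons)


def annual_hdf(jan: DamageFunction, jul: DamageFunction) -> DamageFunction:
    """Mean of the signed January and July HDFs; low-emission flags are OR-ed."""
    if jan.key() != jul.key():
        raise ValueError(f"mismatched HDF keys: {jan.key()} vs {jul.key()}")
    if (jan.period, jul.period) != ("JAN", "JUL"):
        raise ValueError(f"expected (JAN, JUL) periods, got ({jan.period}, {jul.period})")
    value = (jan.value + jul.value) / 2.0
    tons = (jan.annualized_emissions_tons + jul.annualized_emissions_tons) / 2.0
    return DamageFunction(jan.source_state, jan.sector, jan.precursor, jan.pollutant,
                          "ANNUAL", value, tons,
                          low_emission_flag=jan.low_emission_flag or jul.low_emission_flag)


def flag_low_emission(table: list[DamageFunction],
                      rank_count: int = DEFAULT_RANK_COUNT,
                      floor_tons: float = DEFAULT_FLOOR_TONS) -> list[DamageFunction]:
    """Flag, per (sector, precursor, pollutant), the ``rank_count`` states with the
    smallest annualized emissions plus any state below ``floor_tons``/yr.

    Ties in emissions break by state id. Existing flags (e.g. zero-emission
    entries) are kept. Returns a new list; input order is preserved.
    """
    if not table:
        raise ValueError("flag_low_emission requires a non-empty table")
    by_group: dict[tuple[str, str, str], dict[str, float]] = {}
    for d in table:
        group = by_group.setdefault((d.sector, d.precursor, d.pollutant), {})
        group.setdefault(d.source_state, d.annualized_emissions_tons)
    flagged_states: dict[tuple[str, str, str], set[str]] = {}
    for gkey, emis in by_group.items():
        ranked = sorted(emis, key=lambda s: (emis[s], s))
        flags = set(ranked[:rank_count])
        flags |= {s for s, tons in emis.items() if tons < floor_tons}
        flagged_states[gkey] = flags
    out = []
    for d in table:
        flag = (d.low_emission_flag
                or d.source_state in flagged_states[(d.sector, d.precursor, d.pollutant)])
        out.append(DamageFunction(d.source_state, d.sector, d.precursor, d.pollutant,
                                  d.period, d.value, d.annualized_emissions_tons, flag))
    return out


@dataclass
class SummaryTable:
    """Distribution summaries across states plus per-state sector death ratios."""

    hdf_percentiles: pd.DataFrame  # sector, precursor, pollutant, period, p5..p95, n_states
    ratios: pd.DataFrame           # state, egu_deaths, rc_deaths, egu_to_rc_ratio


def _percentile_row(values: np.ndarray) -> dict[str, float]:
    pts = np.percentile(values, PERCENTILES)  # linear interpolation between order stats
    return {f"p{p}": float(v) for p, v in zip(PERCENTILES, pts)}


def summarize(impacts: list[ImpactRecord], hdfs: list[DamageFunction]) -> SummaryTable:
    """Percentiles of HDFs across unflagged states per (sector, pair, period), and
    per-state EGU:RC annual-death ratios (missing where RC deaths are 0)."""
    groups: dict[tuple[str, str, str, str], list[DamageFunction]] = {}
    for d in hdfs:
        groups.setdefault((d.sector, d.precursor, d.pollutant, d.period), []).append(d)
    rows = []
    for (sector, prec, poll, period), ds in sorted(groups.items()):
        values = np.array([d.value for d in ds
                           if not d.low_emission_flag and math.isfinite(d.value)])
        row = {"sector": sector, "precursor": prec, "pollutant": poll,
               "period": period, "n_states": int(values.size)}
        if values.size == 0:
            log.warning("summarize: no unflagged states for %s %s->%s %s",
                        sector, prec, poll, period)
            row.update({f"p{p}": float("nan") for p in PERCENTILES})
        else:
            row.update(_percentile_row(values))
        rows.append(row)
    hdf_percentiles = pd.DataFrame(rows)

    deaths: dict[tuple[str, str], float] = {}
    for r in impacts:
        if r.period == "ANNUAL":
            key = (r.source_state, r.sector)
            deaths[key] = deaths.get(key, 0.0) + r.delta_deaths
    states = sorted({s for s, _ in deaths})
    ratio_rows = []
    for s in states:
        egu = deaths.get((s, "EGU"), 0.0)
        rc = deaths.get((s, "RC"), 0.0)
        ratio = egu / rc if rc != 0 else float("nan")
        ratio_rows.append({"state": s, "egu_deaths": egu, "rc_deaths": rc,
                           "egu_to_rc_ratio": ratio})
    ratios = pd.DataFrame(ratio_rows)
    return SummaryTable(hdf_percentiles=hdf_percentiles, ratios=ratios)
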