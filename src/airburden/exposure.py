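"""County population and baseline mortality → per-cell exposure surfaces.

Counties carry an adult (ages ≥ 25) population and ten yearly baseline
mortality rates (deaths per person per year), averaged for stability.
They are intersected with the modeling grid under a uniform-density
assumption: a cell receives each county's population in proportion to
the intersected area, and its baseline rate is the population-weighted
mean of the contributing counties' averaged rates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .grid import ModelGrid

__all__ = [
    "CountyRecord",
    "ExposureGrid",
    "average_rates",
    "intersect_to_grid",
    "read_counties_csv",
    "write_counties_csv",
    "read_exposure",
    "write_exposure",
]

log = logging.getLogger(__name__)

N_RATE_YEARS = 10  # a decade of yearly rates, averaged for stability


@dataclass
class CountyRecord:
    """One county: planar polygon (km), adult population, 10 yearly mortality rates."""

    county_id: str
    polygon: BaseGeometry
    adult_population: float
    yearly_mortality_rates: list[float]

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise ValueError(f"county {self.county_id}: polygon area must be > 0")
        if self.adult_population < 0:
            raise ValueError(f"county {self.county_id}: population must be >= 0")
        rates = [float(r) for r in self.yearly_mortality_rates]
        if len(rates) != N_RATE_YEARS:
            raise ValueError(
                f"county {self.county_id}: expected {N_RATE_YEARS} yearly mortality "
                f"rates, got {len(rates)}"
            )
        if any(r < 0 for r in rates):
            raise ValueError(f"county {self.county_id}: mortality rates must be >= 0")
        self.yearly_mortality_rates = rates


def average_rates(record: CountyRecord) -> float:
    """Arithmetic mean of the county's ten yearly baseline mortality rates."""
    return float(np.mean(record.yearly_mortality_rates))


@dataclass
class ExposureGrid:
    """Per-cell adult population (persons) and baseline mortality rate y0 (deaths/person/yr).

    Cells with zero population carry y0 = 0 by convention; they contribute
    nothing to the impact sum, whose per-cell term is y0 · β · Δx · Pop.
    """

    grid: ModelGrid
    pop: np.ndarray
    y0: np.ndarray

    def __post_init__(self) -> None:
        self.pop = np.asarray(self.pop, dtype=float)
        self.y0 = np.asarray(self.y0, dtype=float)
        for name, arr in (("pop", self.pop), ("y0", self.y0)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {self.grid.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")


def intersect_to_grid(counties: list[CountyRecord], grid: ModelGrid) -> ExposureGrid:
    """Areal-weighted gridding of county records under uniform density.

    cell population = Σ_counties pop_c · area(county ∩ cell) / area(county);
    cell y0 = population-weighted mean of contributing counties' averaged
    rates (0 where the cell population is 0). A county fully outside the
    domain contributes nothing (logged).
    """
    pop = np.zeros(grid.shape)
    rate_wsum = np.zeros(grid.shape)
    xmin_d, ymin_d, xmax_d, ymax_d = grid.extent
    cs = grid.cell_size_km
    x0, y0_ = grid.origin_xy
    for rec in counties:
        area_total = rec.polygon.area
        bxmin, bymin, bxmax, bymax = rec.polygon.bounds
        if bxmax <= xmin_d or bxmin >= xmax_d or bymax <= ymin_d or bymin >= ymax_d:
            log.info("county %s lies outside the domain; skipped", rec.county_id)
            continue
        rate = average_rates(rec)
        j_lo = max(0, int(math.floor((bxmin - x0) / cs)))
        j_hi = min(grid.n_cols - 1, int(math.ceil((bxmax - x0) / cs)) - 1)
        i_lo = max(0, int(math.floor((bymin - y0_) / cs)))
        i_hi = min(grid.n_rows - 1, int(math.ceil((bymax - y0_) / cs)) - 1)
        for i in range(i_lo, i_hi + 1):
            for j in range(j_lo, j_hi + 1):
                cell = box(*grid.cell_bounds(i, j))
                inter = rec.polygon.intersection(cell).area
                if inter <= 0:
                    continue
                share = rec.adult_population * inter / area_total
                pop[i, j] += share
                rate_wsum[i, j] += share * rate
    y0 = np.where(pop > 0, rate_wsum / np.where(pop > 0, pop, 1.0), 0.0)
    return ExposureGrid(grid, pop, y0)


# --- I/O -------------------------------------------------------------------

_RATE_COLS = [f"rate_{y}" for y in range(2001, 2011)]


def write_counties_csv(counties: list[CountyRecord], path: str) -> None:
    rows = []
    for c in counties:
        row = {"county_id": c.county_id, "polygon_wkt": c.polygon.wkt,
               "adult_population": c.adult_population}
        row.update(dict(zip(_RATE_COLS, c.yearly_mortality_rates)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counties_csv(path: str) -> list[CountyRecord]:
    df = pd.read_csv(path)
    required = {"county_id", "polygon_wkt", "adult_population", *_RATE_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"county CSV missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(CountyRecord(
            county_id=str(r["county_id"]),
            polygon=shapely_wkt.loads(r["polygon_wkt"]),
            adult_population=float(r["adult_population"]),
            yearly_mortality_rates=[float(r[c]) for c in _RATE_COLS],
        ))
    return out


def write_exposure(exposure: ExposureGrid, path: str) -> None:
    """NetCDF with variables 'pop' and 'y0' on dims (row, col)."""
    import xarray as xr

    g = exposure.grid
    ds = xr.Dataset(
        {"pop": (("row", "col"), exposure.pop), "y0": (("row", "col"), exposure.y0)},
        attrs={"cell_size_km": g.cell_size_km,
               "origin_x": g.origin_xy[0], "origin_y": g.origin_xy[1]},
    )
    ds.to_netcdf(path, engine="scipy")


def read_exposure(path: str) -> ExposureGrid:
    import xarray as xr

    from .grid import make_grid

    with xr.open_dataset(path, engine="scipy") as ds:
        for var in ("pop", "y0"):
            if var not in ds:
                raise ValueError(f"exposure file missing variable {var!r}")
        pop = np.asarray(ds["pop"].values, dtype=float)
        y0 = np.asarray(ds["y0"].values, dtype=float)
        attrs = dict(ds.attrs)
    grid = make_grid(pop.shape[0], pop.shape[1], float(attrs["cell_size_km"]),
                     (float(attrs.get("origin_x", 0.0)), float(attrs.get("origin_y", 0.0))))
    return ExposureGrid(grid, pop, y0)
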