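"""Synthetic scenario generation: Gaussian plumes, counties, emissions tables.

A scenario stands in for the output of a full chemical-transport
sensitivity simulation: for every (state, sector, month, precursor–
pollutant pair) a ground-truth sensitivity surface is built as a sum of
isotropic Gaussian kernels over the source's emission footprint,

    Δx(cell) = Σ_footprint  E · w · s · g · exp(-d² / 2σ²),

with E the monthly precursor emissions (tons), w the footprint weight,
s a seasonal multiplier, g a gain (concentration units per ton) and d
the distance from the cell center to the footprint cell displaced by a
fixed advection offset. Run-group composites are exact superpositions of
member ground truths, so segmentation can be validated against a known
decomposition. The seasonal multipliers encode the study's seasonal
structure: residential-combustion primary PM2.5 is strongly
winter-dominant (January ≈ 20× July), EGU SO2→PM2.5 is summer-enhanced
(July ≈ 5× January), and the NOx→O3 January multiplier is negative
(cold-weather O3 titration), flipping the whole plume's sign.

Counties tile the domain rectangle exactly (rectangular tiling, so areal
intersections are exact), with log-uniform adult populations and uniform
yearly baseline mortality rates. All randomness flows from the single
scenario seed; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .exposure import CountyRecord
from .grid import (
    MONTHS,
    ModelGrid,
    PrecursorPollutantPair,
    RunGroup,
    SensitivityField,
    SourceDefinition,
    make_grid,
    sum_fields,
)

__all__ = [
    "DispersionSpec",
    "StateSpec",
    "ScenarioConfig",
    "Scenario",
    "default_seasonal_profiles",
    "default_gains",
    "default_base_emissions",
    "default_config",
    "generate_plume",
    "generate_counties",
    "generate_scenario",
]


@dataclass(frozen=True)
class DispersionSpec:
    """Sector-level plume shape: kernel spread σ (km) and advection offset (km)."""

    sigma_km: float
    advect_km: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.sigma_km > 0:
            raise ValueError(f"dispersion sigma_km must be > 0, got {self.sigma_km}")


@dataclass(frozen=True)
class StateSpec:
    """A synthetic state: rectangular cell block [row0,row1) × [col0,col1) and an
    emission scale multiplying the sector base-emission table."""

    state_id: str
    row0: int
    row1: int
    col0: int
    col1: int
    emission_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.row1 > self.row0 and self.col1 > self.col0):
            raise ValueError(f"state {self.state_id}: empty cell block")
        if self.emission_scale <= 0:
            raise ValueError(f"state {self.state_id}: emission_scale must be > 0")

    def cells(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(self.row0, self.row1)
                for j in range(self.col0, self.col1)]

    def mask(self, grid: ModelGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[self.row0:self.row1, self.col0:self.col1] = True
        return m


def default_seasonal_profiles() -> dict[tuple[str, str], tuple[float, float]]:
    """(sector, pair-key) → (January multiplier, July multiplier).

    Encodes the seasonal contrasts the pipeline must reproduce: RC primary
    PM2.5 at 20:1 January:July, EGU SO2→PM2.5 at 1:5, and a negative
    January NOx→O3 multiplier for both sectors (winter titration, EGU
    smaller in magnitude).
    """
    rc = {
        "PEC->PM25": (2.0, 0.1),
        "POC->PM25": (2.0, 0.1),
        "PSO4->PM25": (2.0, 0.1),
        "NOX->PM25": (1.2, 0.8),
        "SO2->PM25": (0.8, 1.2),
        "VOC->PM25": (1.5, 0.7),
        "NOX->O3": (-0.5, 1.0),
        "VOC->O3": (0.8, 1.2),
    }
    egu = {
        "PEC->PM25": (1.1, 0.9),
        "POC->PM25": (1.1, 0.9),
        "PSO4->PM25": (1.1, 0.9),
        "NOX->PM25": (0.9, 1.1),
        "SO2->PM25": (0.4, 2.0),
        "VOC->PM25": (1.0, 1.0),
        "NOX->O3": (-0.2, 1.0),
        "VOC->O3": (0.9, 1.1),
    }
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for key, v in rc.items():
        out[("RC", key)] = v
    for key, v in egu.items():
        out[("EGU", key)] = v
    return out


def default_gains() -> dict[tuple[str, str], float]:
    """(sector, pair-key) → peak-concentration gain per ton of monthly emissions.

    Primary PM2.5 constituents couple strongly to nearby concentrations;
    secondary PM2.5 formation and O3 response are weaker per ton. Units:
    μg/m³ per ton for PM2.5 pairs, ppb per ton for O3 pairs.
    """
    base = {
        "PEC->PM25": 2.0e-4,
        "POC->PM25": 2.0e-4,
        "PSO4->PM25": 2.0e-4,
        "NOX->PM25": 2.5e-5,
        "SO2->PM25": 3.0e-5,
        "VOC->PM25": 1.5e-5,
        "NOX->O3": 5.0e-5,
        "VOC->O3": 4.0e-5,
    }
    out: dict[tuple[str, str], float] = {}
    for sector in ("RC", "EGU"):
        for key, v in base.items():
            out[(sector, key)] = v
    return out


def default_base_emissions() -> dict[str, dict[str, float]]:
    """Sector → precursor → base tons per month (scaled per state)."""
    return {
        "RC": {"PEC": 300.0, "POC": 1500.0, "PSO4": 50.0,
               "NOX": 800.0, "SO2": 200.0, "VOC": 2000.0},
        "EGU": {"PEC": 50.0, "POC": 30.0, "PSO4": 150.0,
                "NOX": 4000.0, "SO2": 8000.0, "VOC": 100.0},
    }


@dataclass
class ScenarioConfig:
    """Everything needed to regenerate a scenario bit-identically."""

    n_rows: int = 36
    n_cols: int = 60
    cell_size_km: float = 36.0
    origin_xy: tuple[float, float] = (0.0, 0.0)
    states: list[StateSpec] = dc_field(default_factory=list)
    groupings: list[tuple[str, list[str]]] = dc_field(default_factory=list)
    dispersion: dict[str, DispersionSpec] = dc_field(default_factory=lambda: {
        "RC": DispersionSpec(108.0, (72.0, 36.0)),
        "EGU": DispersionSpec(144.0, (108.0, 36.0)),
    })
    seasonal: dict[tuple[str, str], tuple[float, float]] = dc_field(
        default_factory=default_seasonal_profiles)
    gains: dict[tuple[str, str], float] = dc_field(default_factory=default_gains)
    base_emissions: dict[str, dict[str, float]] = dc_field(
        default_factory=default_base_emissions)
    n_counties: int = 48
    pop_range: tuple[float, float] = (2e4, 3e6)
    mortality_range: tuple[float, float] = (0.008, 0.015)
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.dispersion.values():
            if not spec.sigma_km > 0:
                raise ValueError("all dispersion spreads must be > 0")
        ids = {s.state_id for s in self.states}
        if len(ids) != len(self.states):
            raise ValueError("duplicate state ids in config")
        for gid, members in self.groupings:
            unknown = [m for m in members if m not in ids]
            if unknown:
                raise ValueError(f"grouping {gid} references undefined states {unknown}")
            if not 1 <= len(members) <= 3:
                raise ValueError(f"grouping {gid} must have 1-3 members")

    def state(self, state_id: str) -> StateSpec:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(state_id)


def default_config(seed: int = 0) -> ScenarioConfig:
    """The default study conditions: 6 states in two rows of three, grouped into
    3 two-state run groupings paired across the domain so plume tails overlap."""
    rng = np.random.default_rng(seed)
    blocks = [
        ("S1", 4, 14, 6, 16), ("S2", 4, 14, 26, 36), ("S3", 4, 14, 46, 56),
        ("S4", 22, 32, 6, 16), ("S5", 22, 32, 26, 36), ("S6", 22, 32, 46, 56),
    ]
    scales = rng.uniform(0.6, 1.8, size=len(blocks))
    states = [StateSpec(sid, r0, r1, c0, c1, float(scale))
              for (sid, r0, r1, c0, c1), scale in zip(blocks, scales)]
    groupings = [("G1", ["S1", "S5"]), ("G2", ["S2", "S4"]), ("G3", ["S3", "S6"])]
    return ScenarioConfig(states=states, groupings=groupings, seed=seed)


@dataclass
class Scenario:
    """Generated study world: grid, sources, run groups, ground truths, composites,
    county table and emissions table."""

    config: ScenarioConfig
    grid: ModelGrid
    sources: dict[tuple[str, str], SourceDefinition]      # (state_id, sector)
    run_groups: list[RunGroup]
    ground_truth: dict[tuple[str, str, str, str], SensitivityField]
    # keyed (state_id, sector, month, pair_key)
    composites: dict[tuple[str, str, str], SensitivityField]
    # keyed (run_id, month, pair_key)
    counties: list[CountyRecord]
    emissions: pd.DataFrame   # state, sector, precursor, jan_tons, jul_tons, annual_tons

    def state_mask(self, state_id: str) -> np.ndarray:
        return self.config.state(state_id).mask(self.grid)


def generate_plume(grid: ModelGrid, source: SourceDefinition, month: str,
                   pair: PrecursorPollutantPair, dispersion: DispersionSpec,
                   seasonal_multiplier: float, gain_per_ton: float = 1.0,
                   seed: int | None = None) -> SensitivityField:
    """Ground-truth plume for one source, month and pair.

    Deterministic Gaussian superposition over the footprint (the ``seed``
    argument is accepted for interface symmetry but unused: the plume
    model has no stochastic term). Doubling emissions doubles every cell;
    a negative seasonal multiplier flips the whole field's sign.
    """
    emissions = source.emissions_tons.get(month, {}).get(pair.precursor, 0.0)
    values = np.zeros(grid.shape)
    if emissions > 0 and seasonal_multiplier != 0:
        X, Y = grid.cell_centers()
        dx_adv, dy_adv = dispersion.advect_km
        two_sigma2 = 2.0 * dispersion.sigma_km ** 2
        amp = emissions * seasonal_multiplier * gain_per_ton
        for (i, j), w in source.footprint.items():
            cx, cy = grid.cell_center(i, j)
            cx, cy = cx + dx_adv, cy + dy_adv
            d2 = (X - cx) ** 2 + (Y - cy) ** 2
            values += amp * w * np.exp(-d2 / two_sigma2)
    return SensitivityField(grid, f"{source.state_id}-{source.sector}", month, pair, values)


def _tiling_shape(n_counties: int, n_rows: int, n_cols: int) -> tuple[int, int]:
    """Divisor pair (kr, kc) of n_counties closest to the domain aspect ratio."""
    best = (1, n_counties)
    best_err = float("inf")
    for kr in range(1, n_counties + 1):
        if n_counties % kr:
            continue
        kc = n_counties // kr
        err = abs(kr / kc - n_rows / n_cols)
        if err < best_err:
            best, best_err = (kr, kc), err
    return best


def generate_counties(grid: ModelGrid, n_counties: int,
                      pop_range: tuple[float, float],
                      mortality_range: tuple[float, float],
                      seed: int) -> list[CountyRecord]:
    """Rectangular county tiling of the domain with log-uniform populations and
    uniform yearly mortality rates. Same seed → identical table."""
    if n_counties < 1:
        raise ValueError("n_counties must be >= 1")
    lo_p, hi_p = pop_range
    lo_m, hi_m = mortality_range
    if not (0 < lo_p <= hi_p) or not (0 <= lo_m <= hi_m):
        raise ValueError("empty or invalid pop_range / mortality_range")
    rng = np.random.default_rng(seed)
    kr, kc = _tiling_shape(n_counties, grid.n_rows, grid.n_cols)
    xmin, ymin, xmax, ymax = grid.extent
    xs = np.linspace(xmin, xmax, kc + 1)
    ys = np.linspace(ymin, ymax, kr + 1)
    counties = []
    idx = 0
    for r in range(kr):
        for c in range(kc):
            pop = float(np.exp(rng.uniform(np.log(lo_p), np.log(hi_p))))
            rates = rng.uniform(lo_m, hi_m, size=10).tolist()
            counties.append(CountyRecord(
                county_id=f"C{idx:03d}",
                polygon=box(xs[c], ys[r], xs[c + 1], ys[r + 1]),
                adult_population=pop,
                yearly_mortality_rates=rates,
            ))
            idx += 1
    return counties


def _egu_cells(state: StateSpec) -> dict[tuple[int, int], float]:
    """Two point-source cells inside the state block (elevated stacks, aggregated)."""
    ci = (state.row0 + state.row1) // 2
    cj = (state.col0 + state.col1) // 2
    return {(ci, cj): 0.6, (ci - 1, cj + 1): 0.4}


def _build_source(config: ScenarioConfig, state: StateSpec, sector: str) -> SourceDefinition:
    if sector == "RC":
        cells = state.cells()
        w = 1.0 / len(cells)
        footprint = {c: w for c in cells}
    else:
        footprint = _egu_cells(state)
    base = config.base_emissions[sector]
    monthly = {prec: tons * state.emission_scale for prec, tons in base.items()}
    return SourceDefinition(
        state_id=state.state_id, sector=sector,
        emissions_tons={"JAN": dict(monthly), "JUL": dict(monthly)},
        footprint=footprint,
    )


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Build the full synthetic world from a config; bit-identical per (config, seed)."""
    grid = make_grid(config.n_rows, config.n_cols, config.cell_size_km, config.origin_xy)
    sources = {(s.state_id, sector): _build_source(config, s, sector)
               for s in config.states for sector in ("RC", "EGU")}

    pairs = PrecursorPollutantPair.all_pairs()
    ground_truth: dict[tuple[str, str, str, str], SensitivityField] = {}
    for (sid, sector), src in sources.items():
        disp = config.dispersion[sector]
        for month_idx, month in enumerate(MONTHS):
            for pair in pairs:
                mult = config.seasonal[(sector, pair.key)][month_idx]
                gain = config.gains[(sector, pair.key)]
                ground_truth[(sid, sector, month, pair.key)] = generate_plume(
                    grid, src, month, pair, disp, mult, gain)

    run_groups = []
    composites: dict[tuple[str, str, str], SensitivityField] = {}
    for gid, members in config.groupings:
        for sector in ("RC", "EGU"):
            run_id = f"{gid}-{sector}"
            group = RunGroup(run_id, sector, [sources[(m, sector)] for m in members])
            run_groups.append(group)
            for month in MONTHS:
                for pair in pairs:
                    parts = [ground_truth[(m, sector, month, pair.key)] for m in members]
                    composites[(run_id, month, pair.key)] = sum_fields(parts, run_id=run_id)

    counties = generate_counties(grid, config.n_counties, config.pop_range,
                                 config.mortality_range, config.seed)

    rows = []
    for s in sorted(config.states, key=lambda s: s.state_id):
        for sector in ("RC", "EGU"):
            src = sources[(s.state_id, sector)]
            for prec in sorted(config.base_emissions[sector]):
                jan = src.emissions_tons["JAN"][prec]
                jul = src.emissions_tons["JUL"][prec]
                rows.append({"state": s.state_id, "sector": sector, "precursor": prec,
                             "jan_tons": jan, "jul_tons": jul,
                             "annual_tons": 6.0 * jan + 6.0 * jul})
    emissions = pd.DataFrame(rows)

    return Scenario(config=config, grid=grid, sources=sources, run_groups=run_groups,
                    ground_truth=ground_truth, composites=composites,
                    counties=counties, emissions=emissions)


def scale_state_emissions(config: ScenarioConfig, state_id: str,
                          factor: float) -> ScenarioConfig:
    """New config with one state's emission scale multiplied by ``factor``
    (ground-truth fields scale by exactly the same factor — amplitude linearity)."""
    states = [replace(s, emission_scale=s.emission_scale * factor)
              if s.state_id == state_id else s for s in config.states]
    return replace(config, states=states)
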