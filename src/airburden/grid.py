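"""Planar modeling grid, gridded sensitivity fields, and the precursor–pollutant registry.

The modeling domain is an abstract planar, row-major grid of square cells
(36 km in the default configuration, mirroring a continental-scale air
quality model grid). Cell ``(i, j)`` is row ``i`` (counted from the lower
edge) and column ``j`` (from the left edge); the grid origin is the planar
coordinate of the lower-left corner of cell ``(0, 0)``, in km. No
geographic projection is attached: all upstream reprojection is out of
scope and fields are exchanged on this plane.

A :class:`SensitivityField` holds the change in ambient pollutant
concentration per grid cell attributable to a tagged group of emission
sources (a DDM-style sensitivity surface): μg/m³ of PM2.5 (monthly mean of
24-hr averages) or ppb of O3 (monthly mean of daily 8-hr maxima). Values
are signed — negative NOx→O3 sensitivities occur under winter titration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "MONTHS",
    "SECTORS",
    "PM25_PRECURSORS",
    "O3_PRECURSORS",
    "PrecursorPollutantPair",
    "ModelGrid",
    "SensitivityField",
    "SourceDefinition",
    "RunGroup",
    "make_grid",
    "sum_fields",
    "read_field",
    "write_field",
]

MONTHS = ("JAN", "JUL")
SECTORS = ("RC", "EGU")

PM25_PRECURSORS = ("PEC", "POC", "PSO4", "NOX", "SO2", "VOC")
O3_PRECURSORS = ("NOX", "VOC")


@dataclass(frozen=True)
class PrecursorPollutantPair:
    """One of the eight valid precursor → ambient pollutant relationships.

    PM2.5 responds to primary PM2.5 constituents (PEC, POC, PSO4) and to
    the secondary precursors NOx, SO2 and VOC; O3 responds to NOx and VOC
    only. Any other combination is rejected.
    """

    precursor: str
    pollutant: str

    def __post_init__(self) -> None:
        valid = (
            self.pollutant == "PM25" and self.precursor in PM25_PRECURSORS
        ) or (self.pollutant == "O3" and self.precursor in O3_PRECURSORS)
        if not valid:
            raise ValueError(
                f"invalid precursor-pollutant pair {self.precursor}->{self.pollutant}; "
                f"valid pairs are {{PEC,POC,PSO4,NOX,SO2,VOC}}->PM25 and {{NOX,VOC}}->O3"
            )

    @property
    def key(self) -> str:
        return f"{self.precursor}->{self.pollutant}"

    @property
    def units(self) -> str:
        """Field units: μg/m³ for PM2.5 pairs, ppb for O3 pairs."""
        return "ug/m3" if self.pollutant == "PM25" else "ppb"

    @classmethod
    def from_key(cls, key: str) -> "PrecursorPollutantPair":
        precursor, _, pollutant = key.partition("->")
        return cls(precursor, pollutant)

    @classmethod
    def all_pairs(cls) -> list["PrecursorPollutantPair"]:
        pairs = [cls(p, "PM25") for p in PM25_PRECURSORS]
        pairs += [cls(p, "O3") for p in O3_PRECURSORS]
        return pairs


@dataclass(frozen=True)
class ModelGrid:
    """Regular planar grid of square cells, indexed (row i, col j), origin lower-left."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if int(self.n_rows) < 1:
            raise ValueError(f"n_rows must be >= 1, got {self.n_rows}")
        if int(self.n_cols) < 1:
            raise ValueError(f"n_cols must be >= 1, got {self.n_cols}")
        if not self.cell_size_km > 0:
            raise ValueError(f"cell_size_km must be > 0, got {self.cell_size_km}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """Planar (x, y) of the center of cell (i, j), km."""
        x0, y0 = self.origin_xy
        return (x0 + (j + 0.5) * self.cell_size_km, y0 + (i + 0.5) * self.cell_size_km)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) with all cell-center coordinates."""
        x0, y0 = self.origin_xy
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_km
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_km
        return np.meshgrid(xs, ys)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of cell (i, j), km."""
        x0, y0 = self.origin_xy
        cs = self.cell_size_km
        return (x0 + j * cs, y0 + i * cs, x0 + (j + 1) * cs, y0 + (i + 1) * cs)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the whole domain, km."""
        x0, y0 = self.origin_xy
        return (x0, y0, x0 + self.n_cols * self.cell_size_km, y0 + self.n_rows * self.cell_size_km)


def _check_month(month: str) -> None:
    if month not in MONTHS:
        raise ValueError(f"month must be one of {MONTHS}, got {month!r}")


@dataclass
class SensitivityField:
    """Signed Δ-concentration surface for one run, month, and precursor–pollutant pair."""

    grid: ModelGrid
    run_id: str
    month: str
    pair: PrecursorPollutantPair
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_month(self.month)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensitivity values must be finite")

    @classmethod
    def zeros(cls, grid: ModelGrid, run_id: str, month: str,
              pair: PrecursorPollutantPair) -> "SensitivityField":
        return cls(grid, run_id, month, pair, np.zeros(grid.shape))

    def with_values(self, values: np.ndarray, run_id: str | None = None) -> "SensitivityField":
        return SensitivityField(self.grid, run_id or self.run_id, self.month, self.pair, values)

    def same_frame(self, other: "SensitivityField") -> bool:
        return (self.grid == other.grid and self.month == other.month
                and self.pair == other.pair)


@dataclass
class SourceDefinition:
    """A (state, sector) emitter: per-precursor monthly emissions plus a grid footprint.

    ``emissions_tons`` maps month → precursor → nonnegative tons emitted in
    that month; ``footprint`` maps (i, j) grid cells to nonnegative spatial
    weights summing to 1. Residential combustion (RC) sources are
    ground-level area sources spread over the state's cells; electricity
    generating units (EGU) are point sources aggregated to a few cells.
    """

    state_id: str
    sector: str
    emissions_tons: dict[str, dict[str, float]]
    footprint: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"sector must be one of {SECTORS}, got {self.sector!r}")
        if not self.footprint:
            raise ValueError("footprint must be non-empty")
        weights = np.array(list(self.footprint.values()), dtype=float)
        if np.any(weights < 0):
            raise ValueError("footprint weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"footprint weights must sum to 1, got {weights.sum()!r}")
        for month, by_prec in self.emissions_tons.items():
            _check_month(month)
            for prec, tons in by_prec.items():
                if tons < 0:
                    raise ValueError(
                        f"emissions must be >= 0; {self.state_id} {month} {prec} = {tons}"
                    )

    def annual_tons(self, precursor: str) -> float:
        """Annualized emissions: each modeled month stands for half the year."""
        jan = self.emissions_tons.get("JAN", {}).get(precursor, 0.0)
        jul = self.emissions_tons.get("JUL", {}).get(precursor, 0.0)
        return 6.0 * jan + 6.0 * jul


@dataclass
class RunGroup:
    """One to three same-sector states modeled together in a single sensitivity run."""

    run_id: str
    sector: str
    members: list[SourceDefinition] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 3:
            raise ValueError(f"run group must have 1-3 members, got {len(self.members)}")
        for m in self.members:
            if m.sector != self.sector:
                raise ValueError(
                    f"run group {self.run_id} has sector {self.sector} but member "
                    f"{m.state_id} has sector {m.sector}"
                )

    @property
    def state_ids(self) -> list[str]:
        return [m.state_id for m in self.members]


def make_grid(n_rows: int, n_cols: int, cell_size_km: float,
              origin_xy: tuple[float, float] = (0.0, 0.0)) -> ModelGrid:
    """Construct a :class:`ModelGrid`; rejects non-positive dimensions by name."""
    return ModelGrid(int(n_rows), int(n_cols), float(cell_size_km),
                     (float(origin_xy[0]), float(origin_xy[1])))


def sum_fields(fields: list[SensitivityField], run_id: str | None = None) -> SensitivityField:
    """Element-wise sum of same-frame fields (first-order sensitivities superpose)."""
    if not fields:
        raise ValueError("sum_fields requires at least one field")
    first = fields[0]
    for f in fields[1:]:
        if not first.same_frame(f):
            raise ValueError(
                f"cannot sum fields with mismatched frame: "
                f"({first.month}, {first.pair.key}) vs ({f.month}, {f.pair.key}) "
                f"or differing grids"
            )
    total = np.sum([f.values for f in fields], axis=0)
    return SensitivityField(first.grid, run_id or first.run_id, first.month, first.pair, total)


# ---------------------------------------------------------------------------
# Gridded-field I/O: NetCDF (dims row/col, variable delta_x) and a dense CSV
# dialect with a single metadata header line.

def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        f = format.lower()
        if f in ("netcdf", "nc"):
            return "netcdf"
        if f == "csv":
            return "csv"
        raise ValueError(f"unknown field format {format!r}; use 'netcdf' or 'csv'")
    p = str(path).lower()
    if p.endswith(".nc") or p.endswith(".nc4") or p.endswith(".netcdf"):
        return "netcdf"
    if p.endswith(".csv"):
        return "csv"
    raise ValueError(f"cannot infer field format from path {path!r}; pass format=")


def write_field(field: SensitivityField, path: str, format: str | None = None) -> None:
    """Serialize a field; NetCDF carries metadata as global attributes, CSV in a header line."""
    fmt = _infer_format(path, format)
    g = field.grid
    if fmt == "netcdf":
        import xarray as xr

        ds = xr.Dataset(
            {"delta_x": (("row", "col"), field.values)},
            attrs={
                "run_id": field.run_id,
                "month": field.month,
                "precursor": field.pair.precursor,
                "pollutant": field.pair.pollutant,
                "cell_size_km": g.cell_size_km,
                "origin_x": g.origin_xy[0],
                "origin_y": g.origin_xy[1],
            },
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        meta = (
            f"# run_id={field.run_id},month={field.month},"
            f"precursor={field.pair.precursor},pollutant={field.pair.pollutant},"
            f"n_rows={g.n_rows},n_cols={g.n_cols},cell_size_km={g.cell_size_km!r},"
            f"origin_x={g.origin_xy[0]!r},origin_y={g.origin_xy[1]!r}"
        )
        buf = io.StringIO()
        np.savetxt(buf, field.values, delimiter=",", fmt="%.17g")
        with open(path, "w") as fh:
            fh.write(meta + "\n")
            fh.write(buf.getvalue())


def _parse_csv_meta(line: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise ValueError("CSV field file must start with a '# key=value,...' metadata line")
    meta: dict[str, str] = {}
    for item in line.lstrip("#").strip().split(","):
        if "=" not in item:
            raise ValueError(f"malformed metadata item {item!r}")
        k, v = item.split("=", 1)
        meta[k.strip()] = v.strip()
    for key in ("run_id", "month", "precursor", "pollutant", "n_rows", "n_cols", "cell_size_km"):
        if key not in meta:
            raise ValueError(f"CSV field metadata missing required key {key!r}")
    return meta


def read_field(path: str, format: str | None = None) -> SensitivityField:
    """Read a field written by :func:`write_field`; write∘read is the identity."""
    fmt = _infer_format(path, format)
    if fmt == "netcdf":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            for key in ("run_id", "month", "precursor", "pollutant", "cell_size_km"):
                if key not in ds.attrs:
                    raise ValueError(f"NetCDF field file missing attribute {key!r}")
            if "delta_x" not in ds:
                raise ValueError("NetCDF field file missing variable 'delta_x'")
            values = np.asarray(ds["delta_x"].values, dtype=float)
            attrs = dict(ds.attrs)
        grid = make_grid(values.shape[0], values.shape[1], float(attrs["cell_size_km"]),
                         (float(attrs.get("origin_x", 0.0)), float(attrs.get("origin_y", 0.0))))
        pair = PrecursorPollutantPair(str(attrs["precursor"]), str(attrs["pollutant"]))
        return SensitivityField(grid, str(attrs["run_id"]), str(attrs["month"]), pair, values)
    with open(path) as fh:
        meta = _parse_csv_meta(fh.readline())
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    n_rows, n_cols = int(meta["n_rows"]), int(meta["n_cols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"CSV field body shape {values.shape} does not match header "
            f"n_rows={n_rows}, n_cols={n_cols}"
        )
    grid = make_grid(n_rows, n_cols, float(meta["cell_size_km"]),
                     (float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0))))
    pair = PrecursorPollutantPair(meta["precursor"], meta["pollutant"])
    return SensitivityField(grid, meta["run_id"], meta["month"], pair, values)
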