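"""Separation of multi-state sensitivity surfaces by seeded region growing.

Several source-states are modeled together in one sensitivity run; their
plumes superpose into a single composite surface. To attribute cells back
to member states, each state gets a seed at the strongest |Δx| cell near
its emission footprint and regions grow best-first: one frontier per
seed, every frontier cell prioritized by the magnitude |Δx| of the
composite surface at that cell, globally largest first. Signed cells are
claimable exactly like positive ones (winter O3 titration produces
negative sensitivities that still belong to a state), and because
priority is magnitude- rather than contiguity-of-arrival-based, a small
state's region can capture the full extent of its impacts even next to a
large neighbor.

Where two regions' frontiers both reach a cell before it is popped, the
cell is contested and deliberately left unattributed (OMITTED) rather
than arbitrated; this sacrifices a small fraction of the run's total
impact to guarantee clean state attribution. Cells whose |Δx| falls below
a background floor (default 1e-6 of the surface's max |Δx|) are
BACKGROUND and never claimed. A QA gate checks that the omitted share of
the run's health-impact magnitude stays below a threshold (default 10%);
runs that fail are flagged for single-state fallback.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exposure import ExposureGrid
from .grid import ModelGrid, SensitivityField, SourceDefinition
from .health import CRF, cell_impacts

__all__ = [
    "BACKGROUND",
    "OMITTED",
    "LabelMap",
    "QAReport",
    "select_seeds",
    "region_grow",
    "split_run",
    "qa_run",
    "write_label_map",
    "read_label_map",
]

log = logging.getLogger(__name__)

# Integer label codes; state labels are nonnegative indices into LabelMap.states.
BACKGROUND = -1
OMITTED = -2
_UNASSIGNED = -3

DEFAULT_BACKGROUND_FLOOR_REL = 1e-6
DEFAULT_OMISSION_THRESHOLD = 0.10

_NEIGHBORS_8 = tuple((di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                     if not (di == 0 and dj == 0))
_NEIGHBORS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class LabelMap:
    """Per-cell attribution of a run's composite surface to member states.

    ``labels`` holds, per cell, an index into ``states`` or the codes
    BACKGROUND (-1) / OMITTED (-2). Every cell has exactly one label and
    each state's cells form one 8-connected region containing its seed.
    """

    grid: ModelGrid
    labels: np.ndarray
    states: list[str]
    run_id: str
    month: str
    pair_key: str
    seeds: dict[str, tuple[int, int]] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")

    def state_mask(self, state_id: str) -> np.ndarray:
        return self.labels == self.states.index(state_id)

    @property
    def omitted_mask(self) -> np.ndarray:
        return self.labels == OMITTED

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == BACKGROUND

    @property
    def attributed_mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass
class QAReport:
    """Omission accounting for one segmented run.

    omission_fraction is the share of the run's total health-impact
    magnitude (sum of |per-cell impact| over non-BACKGROUND cells) that
    sits in OMITTED cells; the run passes when it is below the threshold.
    """

    run_id: str
    month: str
    pair_key: str
    omission_fraction: float
    per_state_impact: dict[str, float]
    passed: bool
    fallback_required: list[str]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "month": self.month,
            "pair": self.pair_key,
            "omission_fraction": self.omission_fraction,
            "per_state_impact": self.per_state_impact,
            "passed": self.passed,
            "fallback_required": self.fallback_required,
            "degenerate": self.degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _dilate_one(cells: set[tuple[int, int]], grid: ModelGrid) -> set[tuple[int, int]]:
    out = set(cells)
    for (i, j) in cells:
        for di, dj in _NEIGHBORS_8:
            ni, nj = i + di, j + dj
            if 0 <= ni < grid.n_rows and 0 <= nj < grid.n_cols:
                out.add((ni, nj))
    return out


def select_seeds(field: SensitivityField,
                 members: list[SourceDefinition]) -> dict[str, tuple[int, int]]:
    """Seed per member state: max-|Δx| cell within the footprint dilated by one cell.

    Ties break to the lexicographically smallest (i, j). If the field is
    identically zero over the dilated footprint, the seed falls back to
    the footprint's maximum-weight cell (logged, not fatal).
    """
    absval = np.abs(field.values)
    seeds: dict[str, tuple[int, int]] = {}
    for m in members:
        cells = sorted(_dilate_one(set(m.footprint), field.grid))
        best: tuple[int, int] | None = None
        best_val = 0.0
        for (i, j) in cells:
            v = absval[i, j]
            if v > best_val:
                best, best_val = (i, j), v
        if best is None:
            # all-zero surface near this footprint: fall back to max-weight cell
            best = min(m.footprint, key=lambda c: (-m.footprint[c], c[0], c[1]))
            log.warning(
                "state %s: field is zero over dilated footprint; seeding at "
                "max-weight footprint cell %s", m.state_id, best,
            )
        seeds[m.state_id] = best
    return seeds


def region_grow(field: SensitivityField, seeds: dict[str, tuple[int, int]],
                background_floor: float | None = None,
                connectivity: int = 8) -> LabelMap:
    """Best-first multi-seed region growing on |Δx|.

    One frontier per seed; the globally largest-|Δx| frontier cell is
    popped and assigned to its claiming region — unless more than one
    region has claimed it by then, in which case it is contested and
    labeled OMITTED. Cells with |Δx| below ``background_floor`` (default
    1e-6 × max|Δx|) are BACKGROUND and never enter a frontier; seed cells
    are always assigned to their own state. The result is independent of
    the order in which seeds are supplied: pop order depends only on
    (|Δx|, i, j).
    """
    if connectivity == 8:
        neighbors = _NEIGHBORS_8
    elif connectivity == 4:
        neighbors = _NEIGHBORS_4
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    if background_floor is not None and background_floor < 0:
        raise ValueError("background_floor must be >= 0")
    seed_cells = list(seeds.values())
    if len(set(seed_cells)) != len(seed_cells):
        raise ValueError(f"duplicate seed cells: {sorted(seed_cells)}")

    absval = np.abs(field.values)
    if background_floor is None:
        background_floor = DEFAULT_BACKGROUND_FLOOR_REL * float(absval.max())

    # canonical state order: sorted ids, so the result cannot depend on input order
    states = sorted(seeds)
    labels = np.full(field.grid.shape, _UNASSIGNED, dtype=int)
    labels[absval < background_floor] = BACKGROUND

    n_rows, n_cols = field.grid.shape
    claims: dict[tuple[int, int], set[int]] = {}
    heap: list[tuple[float, int, int, int]] = []
    for r, sid in enumerate(states):
        i, j = seeds[sid]
        labels[i, j] = r  # seed always belongs to its state, even below floor
    for r, sid in enumerate(states):
        i, j = seeds[sid]
        for di, dj in neighbors:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_rows and 0 <= nj < n_cols and labels[ni, nj] == _UNASSIGNED:
                c = claims.setdefault((ni, nj), set())
                if r not in c:
                    c.add(r)
                    heapq.heappush(heap, (-absval[ni, nj], ni, nj, r))

    while heap:
        _, i, j, r = heapq.heappop(heap)
        if labels[i, j] != _UNASSIGNED:
            continue
        claimants = claims[(i, j)]
        if len(claimants) > 1:
            labels[i, j] = OMITTED
            continue
        labels[i, j] = r
        for di, dj in neighbors:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_rows and 0 <= nj < n_cols and labels[ni, nj] == _UNASSIGNED:
                c = claims.setdefault((ni, nj), set())
                if r not in c:
                    c.add(r)
                    heapq.heappush(heap, (-absval[ni, nj], ni, nj, r))

    labels[labels == _UNASSIGNED] = BACKGROUND
    return LabelMap(field.grid, labels, states, field.run_id, field.month,
                    field.pair.key, dict(seeds))


def _check_map_matches(field: SensitivityField, label_map: LabelMap) -> None:
    if (label_map.run_id != field.run_id or label_map.month != field.month
            or label_map.pair_key != field.pair.key or label_map.grid != field.grid):
        raise ValueError(
            f"label map ({label_map.run_id}, {label_map.month}, {label_map.pair_key}) "
            f"does not match field ({field.run_id}, {field.month}, {field.pair.key})"
        )


def split_run(field: SensitivityField, label_map: LabelMap) -> dict[str, SensitivityField]:
    """Mask the composite by state label: each output equals the composite on that
    state's cells and 0 elsewhere. Together with the OMITTED- and BACKGROUND-masked
    remainders the outputs re-sum exactly to the composite."""
    _check_map_matches(field, label_map)
    out = {}
    for sid in label_map.states:
        masked = np.where(label_map.state_mask(sid), field.values, 0.0)
        out[sid] = field.with_values(masked, run_id=f"{field.run_id}:{sid}")
    return out


def qa_run(label_map: LabelMap, field: SensitivityField, exposure: ExposureGrid,
           crf: CRF, omission_threshold: float = DEFAULT_OMISSION_THRESHOLD) -> QAReport:
    """Omission QA on health impact: |impact in OMITTED cells| over the total
    non-BACKGROUND impact magnitude. A zero total is degenerate (fraction 0)."""
    _check_map_matches(field, label_map)
    impacts = cell_impacts(field, exposure, crf)
    mag = np.abs(impacts)
    omitted_mag = float(mag[label_map.omitted_mask].sum())
    total_mag = float(mag[~label_map.background_mask].sum())
    degenerate = total_mag == 0.0
    omission = 0.0 if degenerate else omitted_mag / total_mag
    passed = omission < omission_threshold
    per_state = {sid: float(impacts[label_map.state_mask(sid)].sum())
                 for sid in label_map.states}
    return QAReport(
        run_id=label_map.run_id, month=label_map.month, pair_key=label_map.pair_key,
        omission_fraction=omission, per_state_impact=per_state, passed=passed,
        fallback_required=[] if passed else list(label_map.states),
        degenerate=degenerate,
    )


# --- label raster I/O: integer CSV raster + JSON sidecar legend -------------

def write_label_map(label_map: LabelMap, raster_path: str, legend_path: str) -> None:
    np.savetxt(raster_path, label_map.labels, delimiter=",", fmt="%d")
    legend = {
        "states": label_map.states,
        "codes": {"BACKGROUND": BACKGROUND, "OMITTED": OMITTED,
                  **{sid: k for k, sid in enumerate(label_map.states)}},
        "run_id": label_map.run_id,
        "month": label_map.month,
        "pair": label_map.pair_key,
        "cell_size_km": label_map.grid.cell_size_km,
        "origin_xy": list(label_map.grid.origin_xy),
        "seeds": {sid: list(c) for sid, c in label_map.seeds.items()},
    }
    with open(legend_path, "w") as fh:
        json.dump(legend, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_label_map(raster_path: str, legend_path: str) -> LabelMap:
    from .grid import make_grid

    labels = np.loadtxt(raster_path, delimiter=",", dtype=int, ndmin=2)
    with open(legend_path) as fh:
        legend = json.load(fh)
    grid = make_grid(labels.shape[0], labels.shape[1], float(legend["cell_size_km"]),
                     tuple(legend.get("origin_xy", (0.0, 0.0))))
    return LabelMap(grid, labels, list(legend["states"]), legend["run_id"],
                    legend["month"], legend["pair"],
                    {sid: tuple(c) for sid, c in legend.get("seeds", {}).items()})
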