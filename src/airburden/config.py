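"""TOML scenario/pipeline configuration files.

A flat, sectioned key-value format: a [grid] and [counties] section, one
[[state]] table per synthetic state, one [[group]] table per run
grouping, per-sector [dispersion.*], [emissions.*], [seasonal.*] and
[gains.*] sections. Every key has a default (the default study
conditions), so a minimal file can be empty. Read with the standard
library TOML parser; written by a small emitter so configs round-trip.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .pipeline import PipelineConfig
from .synthetic import DispersionSpec, ScenarioConfig, StateSpec, default_config

__all__ = ["load_scenario_config", "dump_scenario_config", "load_pipeline_config"]


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return scenario_config_from_dict(doc)


def scenario_config_from_dict(doc: dict) -> ScenarioConfig:
    base = default_config(seed=int(doc.get("seed", 0)))
    grid = doc.get("grid", {})
    counties = doc.get("counties", {})
    kwargs = dict(
        n_rows=int(grid.get("n_rows", base.n_rows)),
        n_cols=int(grid.get("n_cols", base.n_cols)),
        cell_size_km=float(grid.get("cell_size_km", base.cell_size_km)),
        origin_xy=(float(grid.get("origin_x", 0.0)), float(grid.get("origin_y", 0.0))),
        n_counties=int(counties.get("n", base.n_counties)),
        pop_range=(float(counties.get("pop_min", base.pop_range[0])),
                   float(counties.get("pop_max", base.pop_range[1]))),
        mortality_range=(float(counties.get("mort_min", base.mortality_range[0])),
                         float(counties.get("mort_max", base.mortality_range[1]))),
        seed=int(doc.get("seed", base.seed)),
    )
    if "state" in doc:
        kwargs["states"] = [
            StateSpec(s["id"], int(s["row0"]), int(s["row1"]), int(s["col0"]),
                      int(s["col1"]), float(s.get("emission_scale", 1.0)))
            for s in doc["state"]
        ]
    else:
        kwargs["states"] = base.states
    if "group" in doc:
        kwargs["groupings"] = [(g["id"], list(g["members"])) for g in doc["group"]]
    else:
        kwargs["groupings"] = base.groupings

    dispersion = dict(base.dispersion)
    for sector, spec in doc.get("dispersion", {}).items():
        dispersion[sector] = DispersionSpec(
            float(spec["sigma_km"]),
            (float(spec.get("advect_x_km", 0.0)), float(spec.get("advect_y_km", 0.0))))
    kwargs["dispersion"] = dispersion

    emissions = {sector: dict(vals) for sector, vals in base.base_emissions.items()}
    for sector, vals in doc.get("emissions", {}).items():
        emissions.setdefault(sector, {}).update({k: float(v) for k, v in vals.items()})
    kwargs["base_emissions"] = emissions

    seasonal = dict(base.seasonal)
    for sector, vals in doc.get("seasonal", {}).items():
        for pair_key, (jan, jul) in vals.items():
            seasonal[(sector, pair_key)] = (float(jan), float(jul))
    kwargs["seasonal"] = seasonal

    gains = dict(base.gains)
    for sector, vals in doc.get("gains", {}).items():
        for pair_key, g in vals.items():
            gains[(sector, pair_key)] = float(g)
    kwargs["gains"] = gains

    return ScenarioConfig(**kwargs)


def dump_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    lines = [f"seed = {config.seed}", "", "[grid]",
             f"n_rows = {config.n_rows}", f"n_cols = {config.n_cols}",
             f"cell_size_km = {config.cell_size_km}",
             f"origin_x = {config.origin_xy[0]}", f"origin_y = {config.origin_xy[1]}",
             "", "[counties]", f"n = {config.n_counties}",
             f"pop_min = {config.pop_range[0]}", f"pop_max = {config.pop_range[1]}",
             f"mort_min = {config.mortality_range[0]}",
             f"mort_max = {config.mortality_range[1]}", ""]
    for sector, spec in sorted(config.dispersion.items()):
        lines += [f"[dispersion.{sector}]", f"sigma_km = {spec.sigma_km}",
                  f"advect_x_km = {spec.advect_km[0]}",
                  f"advect_y_km = {spec.advect_km[1]}", ""]
    for sector, vals in sorted(config.base_emissions.items()):
        lines.append(f"[emissions.{sector}]")
        lines += [f"{prec} = {tons}" for prec, tons in sorted(vals.items())]
        lines.append("")
    for sector in ("RC", "EGU"):
        lines.append(f"[seasonal.{sector}]")
        for (sec, pair_key), (jan, jul) in sorted(config.seasonal.items()):
            if sec == sector:
                lines.append(f'"{pair_key}" = [{jan}, {jul}]')
        lines.append("")
        lines.append(f"[gains.{sector}]")
        for (sec, pair_key), g in sorted(config.gains.items()):
            if sec == sector:
                lines.append(f'"{pair_key}" = {g}')
        lines.append("")
    for s in config.states:
        lines += ["[[state]]", f'id = "{s.state_id}"', f"row0 = {s.row0}",
                  f"row1 = {s.row1}", f"col0 = {s.col0}", f"col1 = {s.col1}",
                  f"emission_scale = {s.emission_scale}", ""]
    for gid, members in config.groupings:
        member_list = ", ".join(f'"{m}"' for m in members)
        lines += ["[[group]]", f'id = "{gid}"', f"members = [{member_list}]", ""]
    Path(path).write_text("\n".join(lines))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Pipeline TOML: scenario keys at top level plus an optional [pipeline] section."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    scenario = scenario_config_from_dict(doc)
    p = doc.get("pipeline", {})
    return PipelineConfig(
        scenario=scenario,
        out_dir=str(p.get("out_dir", "burden_out")),
        beta_overrides={k: float(v) for k, v in p.get("beta_overrides", {}).items()},
        background_floor=(float(p["background_floor"])
                          if "background_floor" in p else None),
        omission_threshold=float(p.get("omission_threshold", 0.10)),
        low_emission_rank=int(p.get("low_emission_rank", 1)),
        low_emission_floor_tons=float(p.get("low_emission_floor_tons", 1.0)),
        write_fields=bool(p.get("write_fields", False)),
        make_maps=bool(p.get("make_maps", False)),
    )
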