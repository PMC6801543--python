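"""End-to-end orchestration: synthetic scenario (or rasters on disk) →
terrain derivatives → five process maps → sensitivity table → residue
report, under one seeded configuration with a reproducible manifest.

Each process also exposes a *raw pipeline*: a function from raw
(unnormalized) inputs to the finished map that records the min–max
normalization bounds it used in a ``bounds`` dict on first run and
reuses them on subsequent runs.  The one-at-a-time sensitivity analysis
relies on this: perturbing a raw input by ±5 % and re-running with the
baseline's frozen bounds measures the model's response rather than the
rescaling of the normalization itself (a pure min–max re-fit would
absorb any uniform scaling exactly).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import leaching as _leach
from . import runoff as _runoff
from . import sedimentation as _sed
from . import sensitivity as _sens
from .grid import (Grid, GridStack, ProcessMap, as_process_map,
                   combine_linear, depth_weighted_average, normalize_minmax)
from .raster_io import write_grid
from .synthetic import ScenarioSpec, subseed, synth_residue_db, synth_scenario
from .terrain import (FlowField, d8_flow, delineate_watersheds, fill_pits,
                      horton_form_factor, slope, twi)

__all__ = [
    "RunConfig",
    "TerrainProducts",
    "derive_terrain",
    "leaching_from_raw",
    "runoff_generation_from_raw",
    "runoff_transfer_from_raw",
    "runoff_accumulation_from_raw",
    "sedimentation_from_raw",
    "sfc_from_raw",
    "volatilization_from_raw",
    "sensitivity_table",
    "run_all",
]


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    outdir: str = "pestfate_out"
    seed: int = 0
    shape: tuple[int, int] = (128, 128)
    cell_size_m: float = 1000.0
    stream_threshold: int = 50
    textural_dialect: str = "standard"        # or "as_printed"
    horton_dialect: str = "area_over_length"  # or "area_over_length2"
    slope_units: str = "degrees"
    sensitivity_delta: float = 0.05
    weight_deviations: tuple[int, ...] = (1, 2, 3, 4)
    residue_counts: dict = field(default_factory=lambda: {
        ("pp'DDD", "soil"): 169, ("pp'DDD", "sediment"): 216})
    residue_locations: int = 100
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "weight_deviations" in raw:
            raw["weight_deviations"] = tuple(raw["weight_deviations"])
        if "residue_counts" in raw:
            raw["residue_counts"] = {
                (c, s): int(n) for (c, s), n in
                ((tuple(k.split("|")), v) for k, v in raw["residue_counts"].items())}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps({k: sorted(map(str, v.items())) if isinstance(v, dict)
                           else list(v) if isinstance(v, tuple) else v
                           for k, v in asdict(self).items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# frozen-bounds normalization helpers


def _nm(g: Grid, bounds: dict, key: str) -> Grid:
    """Min–max normalize with record-on-first-use bounds."""
    if key not in bounds:
        vv = g.valid_values()
        if vv.size == 0:
            raise ValueError(f"all-nodata input {key!r}")
        bounds[key] = (float(vv.min()), float(vv.max()))
    lo, hi = bounds[key]
    vals = np.zeros_like(g.values) if hi == lo else (g.values - lo) / (hi - lo)
    return g.like(vals, units="dimensionless")


def _nm_stack(stack: GridStack, bounds: dict, key: str) -> GridStack:
    """Per-stack normalization (one bound pair for all 12 months)."""
    if key not in bounds:
        vals = np.concatenate([stack[m].valid_values() for m in sorted(stack.grids)])
        bounds[key] = (float(vals.min()), float(vals.max()))
    lo, hi = bounds[key]
    out = {}
    for m in sorted(stack.grids):
        g = stack[m]
        v = np.zeros_like(g.values) if hi == lo else (g.values - lo) / (hi - lo)
        out[m] = g.like(v, units="dimensionless")
    return GridStack(out, temporal=stack.temporal)


def _one_minus(g: Grid) -> Grid:
    # unchecked complement: frozen-bounds reruns may overshoot [0,1] slightly
    return g.like(1.0 - g.values)


# ---------------------------------------------------------------------------
# terrain products


@dataclass
class TerrainProducts:
    slope_deg: Grid
    dem_filled: Grid
    flow: FlowField
    twi: Grid
    watersheds: "object"
    form_factor_grid: Grid


def derive_terrain(dem: Grid, stream_threshold: int = 50,
                   horton_dialect: str = "area_over_length") -> TerrainProducts:
    """Slope, filled DEM, D8 flow, TWI, subwatersheds and form factor."""
    sl = slope(dem, mode="degrees")
    filled = fill_pits(dem)
    flow = d8_flow(filled, stream_threshold=stream_threshold)
    wetness = twi(sl, flow.accumulation, cell_m=dem.cell_size[0])
    ws = delineate_watersheds(flow)
    _, ff_grid = horton_form_factor(ws, dialect=horton_dialect)
    return TerrainProducts(sl, filled, flow, wetness, ws, ff_grid)


# ---------------------------------------------------------------------------
# raw pipelines (raw inputs -> finished ProcessMap, with bounds recording)


def leaching_from_raw(inputs: Mapping[str, object],
                      weights: Sequence[float] | None = None,
                      bounds: dict | None = None) -> ProcessMap:
    """DRASTIC-weighted leaching map from raw layers.

    Required keys: drainage_score (continuous propensity), groundwater_depth,
    depth_to_bedrock, slope, soil_moisture.
    """
    b = {} if bounds is None else bounds
    w = _leach.DRASTIC_WEIGHTS if weights is None else tuple(weights)
    raw = combine_linear([
        (w[0], _nm(inputs["drainage_score"], b, "drainage_score")),
        (w[1], _one_minus(_nm(inputs["groundwater_depth"], b, "groundwater_depth"))),
        (w[2], _one_minus(_nm(inputs["depth_to_bedrock"], b, "depth_to_bedrock"))),
        (w[3], _one_minus(_nm(inputs["slope"], b, "slope"))),
        (w[4], _nm(inputs["soil_moisture"], b, "soil_moisture")),
    ])
    out = _nm(raw, b, "__final__")
    return as_process_map(out, "leaching", provenance={"weights": list(w)})


def runoff_generation_from_raw(inputs: Mapping[str, object],
                               bounds: dict | None = None) -> ProcessMap:
    """Runoff-generation map from raw layers: drainage_score, soil_thickness,
    erodibility (K grid), slope, twi, landuse_w (weight grid)."""
    b = {} if bounds is None else bounds
    topo = combine_linear([(0.5, _nm(inputs["slope"], b, "slope")),
                           (0.5, _nm(inputs["twi"], b, "twi"))])
    raw = combine_linear([(0.2, g) for g in (
        _one_minus(_nm(inputs["drainage_score"], b, "drainage_score")),
        _one_minus(_nm(inputs["soil_thickness"], b, "soil_thickness")),
        _nm(inputs["erodibility"], b, "erodibility"),
        topo,
        _nm(inputs["landuse_w"], b, "landuse_w"),
    )])
    out = _nm(raw, b, "__final__")
    return as_process_map(out, "runoff_generation")


def runoff_transfer_from_raw(inputs: Mapping[str, object],
                             bounds: dict | None = None) -> ProcessMap:
    """Runoff-transfer map from raw layers: generation (map), slope,
    form_factor."""
    b = {} if bounds is None else bounds
    raw = combine_linear([(1 / 3, g) for g in (
        _nm(inputs["generation"], b, "generation"),
        _nm(inputs["slope"], b, "slope"),
        _nm(inputs["form_factor"], b, "form_factor"),
    )])
    out = _nm(raw, b, "__final__")
    return as_process_map(out, "runoff_transfer")


def runoff_accumulation_from_raw(inputs: Mapping[str, object],
                                 bounds: dict | None = None) -> ProcessMap:
    """Runoff-accumulation map from raw layers: generation, slope, twi,
    flow_accumulation."""
    b = {} if bounds is None else bounds
    raw = combine_linear([(0.25, g) for g in (
        _nm(inputs["generation"], b, "generation"),
        _one_minus(_nm(inputs["slope"], b, "slope")),
        _nm(inputs["twi"], b, "twi"),
        _nm(inputs["flow_accumulation"], b, "flow_accumulation"),
    )])
    out = _nm(raw, b, "__final__")
    return as_process_map(out, "runoff_accumulation")


def sedimentation_from_raw(inputs: Mapping[str, object],
                           bounds: dict | None = None) -> ProcessMap:
    """Sedimentation index from raw USLE factors and velocity.

    Required keys: rainfall_erosivity (R), erodibility (K grid), cover
    (C grid), slope (degrees), velocity (V grid), plus the fixed
    ``watersheds`` partition and ``cell_area_ha``.
    """
    b = {} if bounds is None else bounds
    R, K, C = inputs["rainfall_erosivity"], inputs["erodibility"], inputs["cover"]
    S_vals = _sed.slope_factor_S(np.clip(inputs["slope"].filled(0.0), 0.0, 89.9))
    S = inputs["slope"].like(S_vals, units="dimensionless")
    E = R.like(R.values * K.values * C.values * S.values, units="t/ha/yr",
               extra_nodata=K.nodata_mask | C.nodata_mask | S.nodata_mask)
    ws = inputs["watersheds"]
    loads = _sed.sediment_load(E, ws, cell_area_ha=inputs["cell_area_ha"])
    ws.records["load_t_yr"] = loads
    load_g = ws.broadcast("load_t_yr")
    V = inputs["velocity"]
    raw = load_g.like(
        _nm(load_g, b, "load").values * (1.0 - _nm(V, b, "velocity").values),
        extra_nodata=V.nodata_mask)
    out = _nm(raw, b, "__final__")
    return as_process_map(out, "sedimentation")


def sfc_from_raw(inputs: Mapping[str, object],
                 bounds: dict | None = None) -> ProcessMap:
    """Storage/filtering map from raw soil-profile stacks oc, clay, ph, cec
    (depth-weighted average, then normalization, then the linear overlay)."""
    b = {} if bounds is None else bounds
    terms = []
    for key, sign in (("oc", +1), ("clay", +1), ("ph", -1), ("cec", +1)):
        g = _nm(depth_weighted_average(inputs[key]), b, key)
        terms.append((1.0, g if sign > 0 else _one_minus(g)))
    out = _nm(combine_linear(terms), b, "__final__")
    return as_process_map(out, "storage_filtering")


def volatilization_from_raw(inputs: Mapping[str, object],
                            bounds: dict | None = None,
                            ) -> tuple[ProcessMap, Grid]:
    """Annual-mean volatilization map and monthly SD from raw monthly
    stacks wind, srad, temp, rh plus annual pet."""
    b = {} if bounds is None else bounds
    for key in ("wind", "srad", "temp", "rh", "pet"):
        if key not in inputs:
            full = {"pet": "potential evapotranspiration"}.get(key, key)
            raise KeyError(f"missing volatilization input: {full}")
    wv = _nm_stack(inputs["wind"], b, "wind")
    sr = _nm_stack(inputs["srad"], b, "srad")
    tt = _nm_stack(inputs["temp"], b, "temp")
    rh = _nm_stack(inputs["rh"], b, "rh")
    pet = _nm(inputs["pet"], b, "pet")
    months = {}
    for m in range(1, 13):
        months[m] = combine_linear([
            (1.0, wv[m]), (1.0, sr[m]), (1.0, tt[m]),
            (1.0, pet), (1.0, _one_minus(rh[m]))])
    stack = np.stack([months[m].filled(np.nan) for m in range(1, 13)])
    mask = np.zeros(stack.shape[1:], dtype=bool)
    for m in range(1, 13):
        mask |= months[m].nodata_mask
    ref = months[1]
    mean_g = ref.like(stack.mean(axis=0), extra_nodata=mask)
    sd_g = ref.like(stack.std(axis=0), units="score", extra_nodata=mask)
    out = _nm(mean_g, b, "__final__")
    return as_process_map(out, "volatilization"), sd_g


def _volat_mean_only(inputs, bounds=None) -> ProcessMap:
    return volatilization_from_raw(inputs, bounds)[0]


# ---------------------------------------------------------------------------
# assembling raw inputs per process from a scenario + terrain


def process_raw_inputs(scn: Mapping[str, object], terr: TerrainProducts,
                        cfg: RunConfig) -> dict[str, dict]:
    """Raw-input dict per process, shared by run_all and the OAT table."""
    drainage_score = _leach.drainage_class_score(scn["drainage_class"])
    landuse_w = _runoff.landuse_weights(scn["landuse"])
    M = _sed.textural_factor_M(scn["silt"].values, scn["sand"].values,
                               scn["clay"].values, dialect=cfg.textural_dialect)
    K_vals = _sed.erodibility_K(M, scn["organic_matter"].values,
                                scn["structure_class"].values,
                                scn["drainage_class"].values)
    K = scn["silt"].like(K_vals, units="t·ha·h/(ha·MJ·mm)",
                         extra_nodata=(scn["organic_matter"].nodata_mask
                                       | scn["structure_class"].nodata_mask
                                       | scn["drainage_class"].nodata_mask))
    cover = _sed.cover_factor_C(normalize_minmax(scn["evi"]))
    V = _sed.stream_velocity(terr.slope_deg, terr.flow.accumulation,
                             terr.watersheds)
    cell_area_ha = terr.watersheds.cell_area_m2 / 10_000.0

    gen_bounds: dict = {}
    gen = runoff_generation_from_raw({
        "drainage_score": drainage_score,
        "soil_thickness": scn["soil_thickness"],
        "erodibility": K, "slope": terr.slope_deg, "twi": terr.twi,
        "landuse_w": landuse_w}, bounds=gen_bounds)

    return {
        "leaching": {
            "drainage_score": drainage_score,
            "groundwater_depth": scn["groundwater_depth"],
            "depth_to_bedrock": scn["depth_to_bedrock"],
            "slope": terr.slope_deg,
            "soil_moisture": scn["soil_moisture"],
        },
        "runoff_generation": {
            "drainage_score": drainage_score,
            "soil_thickness": scn["soil_thickness"],
            "erodibility": K,
            "slope": terr.slope_deg,
            "twi": terr.twi,
            "landuse_w": landuse_w,
        },
        "runoff_transfer": {
            "generation": gen,
            "slope": terr.slope_deg,
            "form_factor": terr.form_factor_grid,
        },
        "runoff_accumulation": {
            "generation": gen,
            "slope": terr.slope_deg,
            "twi": terr.twi,
            "flow_accumulation": terr.flow.accumulation,
        },
        "sedimentation": {
            "rainfall_erosivity": scn["rainfall_erosivity"],
            "erodibility": K,
            "cover": cover,
            "slope": terr.slope_deg,
            "velocity": V,
            "watersheds": terr.watersheds,
            "cell_area_ha": cell_area_ha,
        },
        "storage_filtering": {
            "oc": scn["oc_profile"], "clay": scn["clay_profile"],
            "ph": scn["ph_profile"], "cec": scn["cec_profile"],
        },
        "volatilization": {
            "wind": scn["wind"], "srad": scn["srad"], "temp": scn["temp"],
            "rh": scn["rh"], "pet": scn["pet"],
        },
    }


PROCESS_MODELS = {
    "leaching": leaching_from_raw,
    "runoff_generation": runoff_generation_from_raw,
    "runoff_transfer": runoff_transfer_from_raw,
    "runoff_accumulation": runoff_accumulation_from_raw,
    "sedimentation": sedimentation_from_raw,
    "storage_filtering": sfc_from_raw,
    "volatilization": _volat_mean_only,
}

#: variables perturbed per process in the OAT table (fixed structural
#: inputs like the watershed partition are not variables)
PROCESS_VARIABLES = {
    "leaching": ("drainage_score", "groundwater_depth", "depth_to_bedrock",
                 "slope", "soil_moisture"),
    "runoff_generation": ("drainage_score", "soil_thickness", "erodibility",
                          "slope", "twi", "landuse_w"),
    "runoff_transfer": ("generation", "slope", "form_factor"),
    "runoff_accumulation": ("generation", "slope", "twi", "flow_accumulation"),
    "sedimentation": ("rainfall_erosivity", "erodibility", "cover", "slope",
                      "velocity"),
    "storage_filtering": ("oc", "clay", "ph", "cec"),
    "volatilization": ("wind", "srad", "temp", "pet", "rh"),
}


def sensitivity_table(raw_inputs: Mapping[str, dict],
                      delta: float = 0.05,
                      weight_deviations: Sequence[int] = (1, 2, 3, 4),
                      processes: Sequence[str] | None = None) -> pd.DataFrame:
    """OAT report over every process variable (±delta) and the leaching
    weight deviations, shaped like a (process, variable, −δ, +δ) table."""
    rows = []
    for proc in (processes or PROCESS_MODELS):
        model_fn = PROCESS_MODELS[proc]
        inputs = raw_inputs[proc]
        bounds: dict = {}
        model = lambda x, _f=model_fn, _b=bounds: _f(x, bounds=_b)
        model(inputs)  # freeze bounds on the baseline
        for var in PROCESS_VARIABLES[proc]:
            recs = {}
            for sign in ("-", "+"):
                d = -delta if sign == "-" else delta
                recs[sign] = _sens.oat_variable(model, inputs, var, d, proc)
            rows.append({
                "process": proc, "variable": var, "delta": delta,
                "minus_mean_pct": recs["-"].mean_change_pct,
                "minus_dispersion": recs["-"].change_dispersion,
                "plus_mean_pct": recs["+"].mean_change_pct,
                "plus_dispersion": recs["+"].change_dispersion,
            })
    lb: dict = {}
    leach_inputs = raw_inputs["leaching"]
    leaching_from_raw(leach_inputs, bounds=lb)
    for dev in weight_deviations:
        rec = _sens.oat_leaching_weights(
            leach_inputs, dev,
            model=lambda x, w, _b=lb: leaching_from_raw(x, weights=w, bounds=_b))
        rows.append({
            "process": "leaching", "variable": f"weights±{dev}", "delta": dev,
            "minus_mean_pct": rec.mean_change_pct,
            "minus_dispersion": rec.change_dispersion,
            "plus_mean_pct": rec.mean_change_pct,
            "plus_dispersion": rec.change_dispersion,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run-all


def run_all(cfg: RunConfig, scenario: Mapping[str, object] | None = None,
            ) -> dict:
    """Full pipeline under one config; returns the artifact manifest.

    Stage failures abort with the stage name and the offending input in
    the exception chain.  Re-running with the same config is
    bit-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if scenario is None:
        spec = ScenarioSpec(shape=cfg.shape, cell_size_m=cfg.cell_size_m,
                            seed=cfg.seed)
        scenario = stage("generate", synth_scenario, spec)
    terr = stage("terrain", derive_terrain, scenario["dem"],
                 cfg.stream_threshold, cfg.horton_dialect)
    raw = stage("inputs", process_raw_inputs, scenario, terr, cfg)

    maps: dict[str, ProcessMap] = {}
    for proc, model in PROCESS_MODELS.items():
        if proc == "volatilization":
            maps[proc], sd_g = stage(proc, volatilization_from_raw, raw[proc])
            artifacts["volatilization_sd"] = write_grid(
                outdir / "volatilization_sd.tif", sd_g, process="volatilization_sd")
        else:
            maps[proc] = stage(proc, model, raw[proc])
        artifacts[proc] = write_grid(outdir / f"{proc}.tif", maps[proc],
                                     process=proc)

    # erosion + per-watershed loads as side tables
    sed_in = raw["sedimentation"]
    S = sed_in["slope"].like(_sed.slope_factor_S(
        np.clip(sed_in["slope"].filled(0.0), 0.0, 89.9)))
    E = stage("erosion", _sed.usle_erosion, sed_in["rainfall_erosivity"],
              sed_in["erodibility"], sed_in["cover"], S)
    artifacts["erosion"] = write_grid(outdir / "erosion.tif", E,
                                      process="usle_erosion")
    loads = terr.watersheds.records.copy()
    loads.to_csv(outdir / "watershed_loads.csv")
    artifacts["watershed_loads"] = outdir / "watershed_loads.csv"

    sens = stage("sensitivity", sensitivity_table, raw,
                 cfg.sensitivity_delta, cfg.weight_deviations)
    sens.to_csv(outdir / "sensitivity.csv", index=False)
    artifacts["sensitivity"] = outdir / "sensitivity.csv"

    from .residues import funnel
    db = stage("residues", synth_residue_db, cfg.residue_counts,
               georef_fraction=1.0, seed=subseed(cfg.seed, "residues"),
               n_locations=cfg.residue_locations)
    db.write(outdir / "residues.csv")
    artifacts["residues"] = outdir / "residues.csv"
    report = funnel(db)
    (outdir / "residue_report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    artifacts["residue_report"] = outdir / "residue_report.json"

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": {k: {"path": p.name,
                          "sha256": hashlib.sha256(p.read_bytes()).hexdigest()}
                      for k, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
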