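"""Surface-runoff susceptibility: generation, transfer, accumulation.

The three maps follow the IRIP (Indicator of Intense Pluvial Runoff)
logic — a susceptibility score built by combining simple per-pixel
indicators — but with continuous normalized indicators in place of the
classical binary ones.  Each stage's score is the arithmetic mean of its
indicators (equivalent, up to the 1/n scale, to IRIP's sum of binary
indicators), then min–max renormalized.

Stage indicators (orientation in brackets):

* generation — impermeable soil (1 − drainage score), thin soil
  (1 − thickness), erodibility K, topography (mean of slope and TWI),
  land-use imperviousness weight.
* transfer — generation score, slope (steep ⇒ transfer), catchment form
  factor (compact ⇒ transfer).  Break of slope and artificial linear
  axes are not modelled at continental scale.
* accumulation — generation score, 1 − slope (flat ⇒ ponding), TWI,
  flow accumulation.

Land-use weights follow the 5-class imperviousness table
(forest 0 … built-up 1); the reduction of the 17 MODIS land-cover
classes to those five targets ships as editable configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (Grid, ProcessMap, as_process_map, combine_linear,
                   complement, normalize_minmax, require_aligned)

__all__ = [
    "DEFAULT_LANDUSE_WEIGHTS",
    "LANDUSE_CODES",
    "MODIS_TO_5CLASS",
    "RunoffInputs",
    "landuse_weights",
    "topography_indicator",
    "runoff_generation",
    "runoff_transfer",
    "runoff_accumulation",
]

#: imperviousness weight per land-use class
DEFAULT_LANDUSE_WEIGHTS: dict[str, float] = {
    "forest": 0.0,
    "grass_scrub_woodland": 0.2,
    "barren_sparse": 0.6,
    "cultivated": 0.8,
    "built_up": 1.0,
}

#: integer raster codes for the 5-class vocabulary
LANDUSE_CODES: dict[int, str] = {
    1: "forest", 2: "grass_scrub_woodland", 3: "barren_sparse",
    4: "cultivated", 5: "built_up",
}

#: default regrouping of the 17 MODIS IGBP land-cover classes into the five
#: weight targets; editable via YAML config
MODIS_TO_5CLASS: dict[int, str] = {
    1: "forest", 2: "forest", 3: "forest", 4: "forest", 5: "forest",
    6: "grass_scrub_woodland", 7: "grass_scrub_woodland",
    8: "grass_scrub_woodland", 9: "grass_scrub_woodland",
    10: "grass_scrub_woodland", 11: "grass_scrub_woodland",
    12: "cultivated", 13: "built_up", 14: "cultivated",
    15: "barren_sparse", 16: "barren_sparse", 17: "barren_sparse",
}


@dataclass
class RunoffInputs:
    """Normalized indicator grids for the three runoff stages."""

    drainage_score: Grid
    soil_thickness: Grid
    erodibility_K: Grid
    slope_n: Grid
    twi_n: Grid
    landuse_w: Grid
    form_factor_n: Grid
    flow_acc_n: Grid

    def __post_init__(self) -> None:
        gs = [self.drainage_score, self.soil_thickness, self.erodibility_K,
              self.slope_n, self.twi_n, self.landuse_w, self.form_factor_n,
              self.flow_acc_n]
        require_aligned(*gs)


def landuse_weights(classes: Grid,
                    table: dict[str, float] | None = None,
                    codes: dict[int, str] | None = None) -> Grid:
    """Per-pixel land-use imperviousness weight lookup."""
    table = DEFAULT_LANDUSE_WEIGHTS if table is None else table
    codes = LANDUSE_CODES if codes is None else codes
    bad = [float(w) for w in table.values() if not 0.0 <= w <= 1.0]
    if bad:
        raise ValueError(f"land-use weights outside [0,1]: {bad}")
    vals = classes.values
    present = set(np.unique(vals[classes.valid_mask]).astype(int).tolist())
    unmapped = [c for c in sorted(present)
                if c not in codes or codes[c] not in table]
    if unmapped:
        raise ValueError(f"unmapped land-use class code(s): {unmapped}")
    out = np.full(classes.shape, np.nan)
    for code in present:
        out[vals == code] = table[codes[code]]
    return classes.like(out, units="dimensionless")


def _mean_indicators(grids: list[Grid]) -> Grid:
    w = 1.0 / len(grids)
    return combine_linear([(w, g) for g in grids])


def topography_indicator(slope_n: Grid, twi_n: Grid) -> Grid:
    """Mean of normalized slope and normalized TWI."""
    require_aligned(slope_n, twi_n)
    return _mean_indicators([slope_n, twi_n])


def runoff_generation(x: RunoffInputs, normalize: bool = True) -> ProcessMap:
    """Susceptibility to runoff generation: mean of five indicators."""
    topo = topography_indicator(x.slope_n, x.twi_n)
    raw = _mean_indicators([
        complement(x.drainage_score),
        complement(x.soil_thickness),
        x.erodibility_K,
        topo,
        x.landuse_w,
    ])
    out = normalize_minmax(raw) if normalize else raw
    return as_process_map(out, "runoff_generation",
                          provenance={"normalized": normalize})


def runoff_transfer(gen: ProcessMap, slope_n: Grid, form_factor_n: Grid,
                    normalize: bool = True) -> ProcessMap:
    """Susceptibility to runoff transfer: mean of the three available
    indicators (generation, slope, catchment form factor)."""
    require_aligned(gen, slope_n, form_factor_n)
    raw = _mean_indicators([gen, slope_n, form_factor_n])
    out = normalize_minmax(raw) if normalize else raw
    return as_process_map(out, "runoff_transfer",
                          provenance={"normalized": normalize})


def runoff_accumulation(gen: ProcessMap, slope_n: Grid, twi_n: Grid,
                        flow_acc_n: Grid, normalize: bool = True) -> ProcessMap:
    """Susceptibility to runoff accumulation: mean of four indicators with
    slope complemented (runoff ponds where the terrain is flat)."""
    require_aligned(gen, slope_n, twi_n, flow_acc_n)
    raw = _mean_indicators([gen, complement(slope_n), twi_n, flow_acc_n])
    out = normalize_minmax(raw) if normalize else raw
    return as_process_map(out, "runoff_accumulation",
                          provenance={"normalized": normalize})
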