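"""Leaching vulnerability by a DRASTIC-weighted overlay.

The leaching score is the weighted sum

    L = 5·D + 5·(1 − GW) + 2·(1 − DB) + (1 − SL) + 5·SM

over normalized inputs: drainage-class score D, groundwater depth GW,
depth to bedrock DB, slope SL and mean soil moisture SM, each in [0, 1].
Shallow water tables, shallow bedrock and flat terrain all increase the
score, hence the complements.  The weights are the DRASTIC weights; the
raw score spans [0, 18] (= 5+5+2+1+5 at the extremes) and the map is
min–max normalized afterwards.  Bedrock type is represented by the
drainage-class layer (drainage integrates the same porosity information),
so there is no separate bedrock-type input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (Grid, ProcessMap, as_process_map, combine_linear,
                   complement, normalize_minmax, require_aligned)

__all__ = [
    "DRASTIC_WEIGHTS",
    "DRAINAGE_CLASS_SCORES",
    "LeachingInputs",
    "drainage_class_score",
    "leaching_vulnerability",
]

#: weights on (D, 1−GW, 1−DB, 1−SL, SM); read-only — overridden only by the
#: sensitivity module's weight-deviation analysis
DRASTIC_WEIGHTS: tuple[float, ...] = (5.0, 5.0, 2.0, 1.0, 5.0)

#: ordinal score per drainage/infiltration class; class bounds are
#: low < 15 mm/h, moderate 15–50 mm/h, high > 50 mm/h — the numeric coding
#: is equally spaced and configurable
DRAINAGE_CLASS_SCORES: dict[str, float] = {"low": 0.0, "moderate": 0.5, "high": 1.0}

#: integer raster codes for the 3-level drainage vocabulary
DRAINAGE_CLASS_CODES: dict[int, str] = {1: "low", 2: "moderate", 3: "high"}


@dataclass
class LeachingInputs:
    """Normalized [0,1] inputs to the leaching overlay, all aligned."""

    D: Grid    # drainage-class score (infiltration propensity)
    GW: Grid   # groundwater depth
    DB: Grid   # depth to bedrock
    SL: Grid   # slope
    SM: Grid   # mean soil moisture

    def __post_init__(self) -> None:
        require_aligned(self.D, self.GW, self.DB, self.SL, self.SM)
        for name in ("D", "GW", "DB", "SL", "SM"):
            _check_unit_interval(getattr(self, name), name)


def _check_unit_interval(g: Grid, name: str) -> None:
    vv = g.valid_values()
    if vv.size and (vv.min() < -1e-9 or vv.max() > 1 + 1e-9):
        raise ValueError(f"leaching input {name} must be normalized to [0, 1]")


def drainage_class_score(classes: Grid,
                         scores: dict[str, float] | None = None) -> Grid:
    """Map a categorical drainage-class raster (codes 1/2/3) to [0,1] scores."""
    scores = DRAINAGE_CLASS_SCORES if scores is None else scores
    vals = classes.values
    out = np.full(classes.shape, np.nan)
    seen = set(np.unique(vals[classes.valid_mask]).astype(int).tolist())
    unknown = seen - set(DRAINAGE_CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown drainage class code(s): {sorted(unknown)}")
    for code, name in DRAINAGE_CLASS_CODES.items():
        if name not in scores:
            raise ValueError(f"no score for drainage class {name!r}")
        out[vals == code] = scores[name]
    return classes.like(out, units="dimensionless")


def leaching_vulnerability(x: LeachingInputs,
                           weights: tuple[float, ...] | None = None,
                           normalize: bool = True) -> ProcessMap:
    """DRASTIC-weighted leaching overlay, min–max normalized to [0, 1].

    ``normalize=False`` returns the raw weighted sum (range [0, Σw]) —
    used by the equivalence tests and the sensitivity analysis.
    """
    w = DRASTIC_WEIGHTS if weights is None else tuple(float(v) for v in weights)
    if len(w) != 5:
        raise ValueError("leaching needs exactly 5 weights")
    raw = combine_linear([
        (w[0], x.D),
        (w[1], complement(x.GW)),
        (w[2], complement(x.DB)),
        (w[3], complement(x.SL)),
        (w[4], x.SM),
    ])
    out = normalize_minmax(raw) if normalize else raw
    return as_process_map(out, "leaching",
                          provenance={"weights": list(w), "normalized": normalize})
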