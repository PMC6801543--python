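"""Volatilization-associated variable: monthly score, annual mean and
seasonal dispersion.

For month i the score is

    V_i = WV_i + Srad_i + T_i + PET + (1 − RH_i)

on normalized inputs: wind velocity, solar radiation, surface
temperature, (annual) potential evapotranspiration and relative
humidity.  Hot, sunny, windy, evaporative and dry conditions all favour
volatilization; humid air suppresses it, hence the complement.  PET is
available only as a long-term annual average and enters every month
identically.  Each monthly stack is normalized across the whole
12-month stack (not month by month) so months remain comparable.

The summary maps are the per-pixel annual mean of the 12 monthly scores
(min–max normalized) and the per-pixel population standard deviation of
the 12 values, which captures seasonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (Grid, GridStack, ProcessMap, as_process_map,
                   combine_linear, complement, normalize_minmax,
                   require_aligned)

__all__ = ["VolatInputs", "monthly_volatilization", "annual_summary",
           "normalize_stack"]


@dataclass
class VolatInputs:
    """Monthly (12-band) normalized climate stacks plus annual PET."""

    WV: GridStack
    Srad: GridStack
    T: GridStack
    RH: GridStack
    PET: Grid

    def __post_init__(self) -> None:
        for name in ("WV", "Srad", "T", "RH"):
            stack = getattr(self, name)
            if sorted(stack.grids) != list(range(1, 13)):
                raise ValueError(f"{name} must have month keys 1..12")
        require_aligned(self.PET, *(self.WV[m] for m in range(1, 13)))


def normalize_stack(stack: GridStack) -> GridStack:
    """Min–max normalize a monthly stack across all 12 bands jointly."""
    vals = np.stack([stack[m].filled(np.nan) for m in sorted(stack.grids)])
    lo = np.nanmin(vals)
    hi = np.nanmax(vals)
    if not np.isfinite(lo):
        raise ValueError("cannot normalize an all-nodata stack")
    rng = hi - lo
    out = {}
    for m in sorted(stack.grids):
        g = stack[m]
        v = np.zeros_like(g.values) if rng == 0 else (g.values - lo) / rng
        out[m] = g.like(v, units="dimensionless")
    return GridStack(out, temporal=True)


def monthly_volatilization(x: VolatInputs, i: int) -> Grid:
    """Month-i volatilization score WV + Srad + T + PET + (1 − RH); the raw
    sum spans [0, 5] and is not yet normalized."""
    if not 1 <= int(i) <= 12:
        raise ValueError(f"month {i} out of range 1..12")
    i = int(i)
    return combine_linear([
        (1.0, x.WV[i]),
        (1.0, x.Srad[i]),
        (1.0, x.T[i]),
        (1.0, x.PET),
        (1.0, complement(x.RH[i])),
    ])


def annual_summary(months: GridStack) -> tuple[ProcessMap, Grid]:
    """Annual mean (normalized ProcessMap) and population SD over the 12
    monthly scores."""
    if sorted(months.grids) != list(range(1, 13)):
        raise ValueError("annual summary needs month keys 1..12")
    stack = np.stack([months[m].filled(np.nan) for m in range(1, 13)])
    mask = np.zeros(stack.shape[1:], dtype=bool)
    for m in range(1, 13):
        mask |= months[m].nodata_mask
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0)  # population SD (ddof=0) of the 12 months
    ref = months[1]
    mean_map = normalize_minmax(ref.like(mean, extra_nodata=mask))
    sd_grid = ref.like(sd, units="score", extra_nodata=mask)
    return as_process_map(mean_map, "volatilization"), sd_grid
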