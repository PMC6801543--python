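"""One-at-a-time (OAT) sensitivity analysis.

Each raw input variable is scaled by ±5 % and the full pipeline —
including every re-normalization — is re-run; the report gives the mean
and the pixel-wise standard deviation of the per-pixel relative change
100·|out′ − out| / out over valid pixels (pixels where the baseline is
below 1e-9 are excluded).  Because perturbation precedes normalization,
+5 % and −5 % need not give symmetric responses for models that
renormalize.

For the leaching overlay the weights themselves are also perturbed: each
weight is shifted by ±d points (one at a time, floored at 1 and capped
at 5, the range the weights span), and the per-run changes are averaged
over weights and signs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .grid import Grid, GridStack, SoilProfileStack

__all__ = [
    "SensitivityRecord",
    "oat_variable",
    "oat_weights",
    "oat_leaching_weights",
    "percent_change",
]


@dataclass
class SensitivityRecord:
    """One row of the OAT report."""

    process: str
    variable: str
    delta: float              # relative perturbation (±0.05) or weight points
    mean_change_pct: float
    change_dispersion: float  # pixel SD of the percent change

    def __post_init__(self) -> None:
        if self.mean_change_pct < 0 or self.change_dispersion < 0:
            raise ValueError("change statistics must be non-negative")


def percent_change(base: Grid, pert: Grid,
                   floor: float = 1e-9) -> tuple[float, float]:
    """Mean and SD over valid pixels of 100·|pert − base| / base."""
    ok = base.valid_mask & pert.valid_mask & (np.abs(base.values) >= floor)
    if not ok.any():
        raise ValueError("no valid pixels above the baseline floor")
    ratio = 100.0 * np.abs(pert.values[ok] - base.values[ok]) / base.values[ok]
    return float(ratio.mean()), float(ratio.std())


def _scale(obj, factor: float):
    """Scale a raw input (Grid, GridStack, SoilProfileStack or scalar)."""
    if isinstance(obj, Grid):
        return obj.like(obj.values * factor)
    if isinstance(obj, GridStack):
        return GridStack({k: g.like(g.values * factor) for k, g in obj.items()},
                         temporal=obj.temporal)
    if isinstance(obj, SoilProfileStack):
        return SoilProfileStack(
            [g.like(g.values * factor) for g in obj.layers], obj.intervals)
    if isinstance(obj, (int, float)):
        return obj * factor
    raise TypeError(f"cannot perturb input of type {type(obj).__name__}")


def oat_variable(model: Callable[[Mapping[str, object]], Grid],
                 inputs: Mapping[str, object], variable: str,
                 delta: float = 0.05, process: str = "") -> SensitivityRecord:
    """Perturb one raw input by (1 + delta) and re-run the whole pipeline."""
    if variable not in inputs:
        raise KeyError(f"unknown variable {variable!r}; "
                       f"model inputs are {sorted(inputs)}")
    base = model(inputs)
    pert_inputs = dict(inputs)
    pert_inputs[variable] = _scale(inputs[variable], 1.0 + delta)
    pert = model(pert_inputs)
    mean, sd = percent_change(base, pert)
    return SensitivityRecord(process, variable, delta, mean, sd)


def oat_weights(model: Callable[[Sequence[float]], Grid],
                weights: Sequence[float], deviation: float,
                lo: float = 1.0, hi: float = 5.0,
                process: str = "", variable: str = "weights",
                ) -> SensitivityRecord:
    """Shift each weight by ±deviation (clamped to [lo, hi]), one at a
    time, and average the percent change over all weight/sign runs."""
    if deviation < 0:
        raise ValueError("deviation must be non-negative")
    weights = [float(w) for w in weights]
    base = model(weights)
    means, sds = [], []
    for i in range(len(weights)):
        for sign in (+1.0, -1.0):
            w = list(weights)
            w[i] = min(max(w[i] + sign * deviation, lo), hi)
            if w[i] == weights[i]:
                means.append(0.0)
                sds.append(0.0)
                continue
            mean, sd = percent_change(base, model(w))
            means.append(mean)
            sds.append(sd)
    return SensitivityRecord(process, variable, deviation,
                             float(np.mean(means)), float(np.mean(sds)))


def oat_leaching_weights(inputs: Mapping[str, object], deviation: int,
                         model: Callable[[Mapping[str, object],
                                          Sequence[float]], Grid] | None = None,
                         ) -> SensitivityRecord:
    """OAT deviation of the leaching weights (5, 5, 2, 1, 5) by ±`deviation`
    integer points, clamped to the 1–5 range the weights span."""
    from .leaching import DRASTIC_WEIGHTS
    if not float(deviation).is_integer() or deviation < 0:
        raise ValueError("weight deviation must be a non-negative integer")
    if deviation >= 5:
        raise ValueError("weight deviation must be below the 1–5 span")
    if model is None:
        from .pipeline import leaching_from_raw
        model = leaching_from_raw
    return oat_weights(lambda w: model(inputs, w), DRASTIC_WEIGHTS,
                       float(deviation), process="leaching",
                       variable="drastic_weights")
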