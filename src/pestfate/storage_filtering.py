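"""Soil storage and filtering capacity (SFC).

SFC = OC + clay + (1 − pH) + CEC on normalized inputs, min–max
normalized afterwards.  Organic carbon, clay and cation-exchange
capacity all increase a soil's ability to retain pesticides; high pH
reduces sorption, hence the complement.  Each input is first aggregated
over the soil profile by depth-weighted averaging, then normalized.
Low SFC flags areas susceptible to pesticide movement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grid import (Grid, ProcessMap, as_process_map, combine_linear,
                   complement, normalize_minmax, require_aligned)

__all__ = ["SfcInputs", "sfc"]


@dataclass
class SfcInputs:
    """Normalized [0,1] profile-averaged soil properties, aligned."""

    OC: Grid
    clay: Grid
    pH: Grid
    CEC: Grid

    def __post_init__(self) -> None:
        require_aligned(self.OC, self.clay, self.pH, self.CEC)
        for name in ("OC", "clay", "pH", "CEC"):
            vv = getattr(self, name).valid_values()
            if vv.size and (vv.min() < -1e-9 or vv.max() > 1 + 1e-9):
                raise ValueError(f"SFC input {name} must be normalized to [0, 1]")


def sfc(x: SfcInputs, normalize: bool = True) -> ProcessMap:
    """Storage/filtering capacity OC + clay + (1 − pH) + CEC, normalized.

    ``normalize=False`` returns the raw sum in [0, 4].
    """
    raw = combine_linear([
        (1.0, x.OC),
        (1.0, x.clay),
        (1.0, complement(x.pH)),
        (1.0, x.CEC),
    ])
    out = normalize_minmax(raw) if normalize else raw
    return as_process_map(out, "storage_filtering",
                          provenance={"normalized": normalize})
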