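"""USLE erosion, watershed sediment load, stream velocity and the
sedimentation-vulnerability index.

Annual soil loss follows the Universal Soil Loss Equation

    E = R · K · C · S        (t/ha/yr)

with rainfall erosivity R (MJ·mm/ha/h/yr), erodibility K from the
Wischmeier–Smith nomograph, cover factor C proxied by 1 − EVI, and the
slope-steepness factor S; the slope-length component L and the support-
practice factor P are not modelled (L acts at much finer resolution than
the grid, and no continental support-practice data exist).

Sediment load per watershed is the sum of E over the watershed's cells.
Stream velocity follows the slope–area scaling

    V = V_m · s^b A^c / [s^b A^c]_m ,   b = c = 0.5

where [·]_m is the watershed mean over stream cells and the velocity
scale V_m is, by default, the watershed's min–max-normalized mean slope.
Deposition is favoured where the load is high and the velocity low, so
the sedimentation index is normalized_load × (1 − normalized_velocity).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .grid import (Grid, ProcessMap, as_process_map, normalize_minmax,
                   require_aligned)
from .terrain import WatershedPartition

__all__ = [
    "textural_factor_M",
    "erodibility_K",
    "slope_factor_S",
    "cover_factor_C",
    "usle_erosion",
    "sediment_load",
    "stream_velocity",
    "sedimentation_index",
]


def textural_factor_M(msilt, msand, mclay, dialect: str = "standard"):
    """Nomograph textural factor from texture percentages.

    ``standard`` is the Wischmeier–Smith form (msilt + mvfs)·(100 − mclay)
    with the very-fine-sand fraction mvfs = 0.2 × msand; the
    ``as_printed`` dialect msilt + mvfs·(100 − mclay) reproduces a variant
    in which the leading parentheses were dropped.  Accepts scalars or
    arrays.
    """
    msilt = np.asarray(msilt, dtype=float)
    msand = np.asarray(msand, dtype=float)
    mclay = np.asarray(mclay, dtype=float)
    if (np.nanmin(msilt) < 0 or np.nanmin(msand) < 0 or np.nanmin(mclay) < 0):
        raise ValueError("texture fractions must be non-negative")
    mvfs = 0.2 * msand
    if dialect == "standard":
        M = (msilt + mvfs) * (100.0 - mclay)
    elif dialect == "as_printed":
        M = msilt + mvfs * (100.0 - mclay)
    else:
        raise ValueError(f"unknown textural dialect {dialect!r}")
    return M if M.ndim else float(M)


def erodibility_K(M, OM, s_class, p_class):
    """Soil erodibility ((t·ha·h)/(ha·MJ·mm)) from the nomograph:

    K = ([2.1e-4·M^1.14·(12 − OM) + 3.25·(s − 2) + 2.5·(p − 3)] / 100) × 0.1317

    floored at 0 (the nomograph can go negative for extreme inputs).
    Structure class s ∈ {1..4}; p is the drainage class.
    """
    M = np.asarray(M, dtype=float)
    OM = np.asarray(OM, dtype=float)
    s = np.asarray(s_class, dtype=float)
    p = np.asarray(p_class, dtype=float)
    K = ((2.1e-4 * M**1.14 * (12.0 - OM) + 3.25 * (s - 2.0)
          + 2.5 * (p - 3.0)) / 100.0) * 0.1317
    K = np.maximum(K, 0.0)
    return K if K.ndim else float(K)


def slope_factor_S(theta):
    """Slope-steepness factor from slope θ in degrees.

    S = 10.8·sin θ + 0.03 below the 9 % breakpoint (tan θ < 0.09), else
    S = 16.8·sin θ − 0.5.  The two branches differ by < 0.01 at the
    breakpoint itself.
    """
    theta = np.asarray(theta, dtype=float)
    if np.nanmin(theta) < 0 or np.nanmax(theta) > 90:
        raise ValueError("slope must be within [0, 90] degrees")
    rad = np.radians(theta)
    flat = np.tan(rad) < 0.09
    S = np.where(flat, 10.8 * np.sin(rad) + 0.03, 16.8 * np.sin(rad) - 0.5)
    return S if S.ndim else float(S)


def cover_factor_C(evi_n: Grid) -> Grid:
    """Cover-management factor C = 1 − EVI (normalized); dense vegetation
    shields the soil, bare ground does not."""
    return evi_n.like(np.clip(1.0 - evi_n.values, 0.0, 1.0),
                      units="dimensionless")


def usle_erosion(R: Grid, K: Grid, C: Grid, S: Grid) -> Grid:
    """Per-pixel annual soil loss E = R·K·C·S (t/ha/yr), support practice
    factor P ≡ 1."""
    require_aligned(R, K, C, S)
    for name, g in (("R", R), ("K", K), ("C", C), ("S", S)):
        vv = g.valid_values()
        if vv.size and vv.min() < 0:
            raise ValueError(f"USLE factor {name} has negative values")
    mask = R.nodata_mask | K.nodata_mask | C.nodata_mask | S.nodata_mask
    E = R.values * K.values * C.values * S.values
    return R.like(E, units="t/ha/yr", extra_nodata=mask)


def sediment_load(E: Grid, ws: WatershedPartition,
                  cell_area_ha: float) -> pd.Series:
    """Sediment load per watershed (t/yr): Σ E × cell area over its cells."""
    require_aligned(E, ws.labels)
    lab = ws.label_array()
    loads = {}
    ev = np.where(E.nodata_mask, 0.0, E.values)
    for wid in ws.records.index:
        loads[wid] = float(ev[lab == wid].sum() * cell_area_ha)
    s = pd.Series(loads, name="load_t_yr")
    s.index.name = "watershed"
    return s


def _vm_normalized_mean_slope(ws: WatershedPartition, slope_g: Grid,
                              stream: np.ndarray) -> pd.Series:
    """Default velocity scale: per-watershed mean slope, min–max normalized
    across watersheds (small positive floor keeps V well defined)."""
    lab = ws.label_array()
    sv = np.where(slope_g.nodata_mask, np.nan, slope_g.values)
    means = {wid: float(np.nanmean(sv[lab == wid])) for wid in ws.records.index}
    m = pd.Series(means)
    rng = m.max() - m.min()
    vm = (m - m.min()) / rng if rng > 0 else pd.Series(0.0, index=m.index)
    return vm.clip(lower=1e-3)


def stream_velocity(slope_g: Grid, acc: Grid, ws: WatershedPartition,
                    b: float = 0.5, c: float = 0.5,
                    vm_strategy: Callable[..., pd.Series] | None = None,
                    fill_offstream: bool = True) -> Grid:
    """Relative stream velocity V = V_m · s^b A^c / [s^b A^c]_m.

    Evaluated on stream cells (slope floored at 1e-4 so s^b is positive);
    the watershed mean of V over its stream cells equals V_m by
    construction.  With ``fill_offstream`` the watershed's V_m is painted
    onto non-stream cells so the sedimentation index covers the full map.
    """
    require_aligned(slope_g, acc, ws.labels)
    lab = ws.label_array()
    stream = ws.stream_mask

    vm_fn = vm_strategy or _vm_normalized_mean_slope
    vm = vm_fn(ws, slope_g, stream)

    s = np.maximum(np.where(slope_g.nodata_mask, np.nan, slope_g.values), 1e-4)
    t = s**b * np.where(acc.nodata_mask, np.nan, acc.values)**c

    V = np.full(lab.shape, np.nan)
    for wid in ws.records.index:
        cells = (lab == wid) & stream
        if not cells.any():
            raise ValueError(f"watershed {wid} has no stream cells")
        tm = float(np.nanmean(t[cells]))
        V[cells] = vm[wid] * t[cells] / tm
        if fill_offstream:
            off = (lab == wid) & ~cells
            V[off] = vm[wid]
    ws.records["velocity_scale_Vm"] = vm
    return slope_g.like(V, units="relative")


def sedimentation_index(load_g: Grid, V: Grid) -> ProcessMap:
    """Deposition-vulnerability index: normalized load × (1 − normalized
    velocity), renormalized to [0, 1]."""
    require_aligned(load_g, V)
    ln = normalize_minmax(load_g)
    vn = normalize_minmax(V)
    mask = ln.nodata_mask | vn.nodata_mask
    raw = ln.values * (1.0 - vn.values)
    out = normalize_minmax(load_g.like(raw, extra_nodata=mask))
    return as_process_map(out, "sedimentation")
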