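"""Terrain and hydrology derivatives from a DEM.

Slope (Horn 3×3), priority-flood pit filling, D8 single-direction flow
routing with deterministic tie-breaking, flow accumulation, topographic
wetness index, stream extraction and subwatershed delineation by stream
segment.  These stand in for the precomputed hydrography products
(flow accumulation, watershed area, stream length) that continental
studies usually take from HydroSHEDS.

D8 neighbor order is fixed at (E, SE, S, SW, W, NW, N, NE); ties in the
steepest-descent choice are broken by that order so results are
bit-reproducible.  Direction codes are the index 0–7 into that order,
``-1`` for an outlet (flow leaves the valid grid) and ``-2`` for nodata.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid, require_aligned

__all__ = [
    "FlowField",
    "WatershedPartition",
    "slope",
    "fill_pits",
    "d8_flow",
    "twi",
    "delineate_watersheds",
    "horton_form_factor",
    "NEIGHBORS",
]

# (dr, dc) in fixed tie-break order E, SE, S, SW, W, NW, N, NE
NEIGHBORS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2)] * 2)

OUTLET = -1
NODATA_DIR = -2


@dataclass
class FlowField:
    """D8 directions, flow accumulation (cells, incl. self) and stream mask."""

    directions: Grid      # int codes stored as float Grid values
    accumulation: Grid    # drained cell count including the cell itself
    stream_mask: np.ndarray
    stream_threshold: int

    @property
    def dir_array(self) -> np.ndarray:
        d = self.directions.values.copy()
        d[self.directions.nodata_mask] = NODATA_DIR
        return d.astype(int)


def slope(dem: Grid, mode: str = "degrees", geographic: bool = False) -> Grid:
    """Slope magnitude from a 3×3 Horn finite-difference gradient.

    Border pixels effectively use one-sided differences (edge replication).
    ``mode`` is ``"degrees"`` or ``"percent"``.
    """
    if mode not in ("degrees", "percent"):
        raise ValueError("mode must be 'degrees' or 'percent'")
    if min(dem.shape) < 2:
        raise ValueError("DEM must have at least 2 rows and 2 columns")
    from .grid import cell_dims_m
    dx_row, dy = cell_dims_m(dem, geographic=geographic)

    z = dem.filled(np.nan)
    # odd reflection linearly extrapolates across the border, so border
    # pixels reduce to one-sided differences
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")

    def shift(dr: int, dc: int) -> np.ndarray:
        # neighbor view; masked neighbors fall back to the centre value so
        # border/nodata-adjacent pixels reduce to one-sided differences
        view = zp[1 + dr:zp.shape[0] - 1 + dr, 1 + dc:zp.shape[1] - 1 + dc]
        return np.where(np.isfinite(view), view, z)

    a = shift(-1, -1); b = shift(-1, 0); c = shift(-1, 1)
    d = shift(0, -1); f = shift(0, 1)
    g_ = shift(1, -1); h = shift(1, 0); i = shift(1, 1)
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g_)) / (8.0 * dx_row[:, None])
    dzdy = ((g_ + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dy)
    rise = np.hypot(dzdx, dzdy)
    if mode == "percent":
        out = 100.0 * rise
        units = "percent"
    else:
        out = np.degrees(np.arctan(rise))
        units = "degrees"
    return dem.like(out, units=units)


def fill_pits(dem: Grid) -> Grid:
    """Raise every closed depression to its spill elevation (priority flood).

    After filling, every interior cell has a monotone non-ascending path to
    the grid edge; a pit-free DEM is returned unchanged.  Output ≥ input
    everywhere.
    """
    z = dem.filled(np.nan)
    nr, nc = z.shape
    valid = dem.valid_mask
    filled = np.where(valid, -np.inf, np.nan)
    closed = ~valid  # nodata never processed
    heap: list[tuple[float, int, int]] = []

    # seed: valid cells on the grid edge or adjacent to nodata
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            edge = r in (0, nr - 1) or c in (0, nc - 1)
            if not edge:
                for dr, dc in NEIGHBORS:
                    rr, cc = r + dr, c + dc
                    if not valid[rr, cc]:
                        edge = True
                        break
            if edge:
                filled[r, c] = z[r, c]
                closed[r, c] = True
                heapq.heappush(heap, (z[r, c], r, c))

    while heap:
        elev, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                closed[rr, cc] = True
                filled[rr, cc] = max(z[rr, cc], elev)
                heapq.heappush(heap, (filled[rr, cc], rr, cc))

    return dem.like(filled)


def _steepest_descent(zf: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """First pass: steepest strictly-descending neighbor, or OUTLET at the
    valid-grid boundary when no interior descent exists."""
    nr, nc = zf.shape
    dirs = np.full((nr, nc), NODATA_DIR, dtype=int)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            z0 = zf[r, c]
            best, best_drop = None, 0.0
            touches_boundary = False
            for k, (dr, dc) in enumerate(NEIGHBORS):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or not valid[rr, cc]:
                    touches_boundary = True
                    continue
                drop = (z0 - zf[rr, cc]) / _DIST[k]
                if drop > best_drop:
                    best, best_drop = k, drop
            if best is not None:
                dirs[r, c] = best
            elif touches_boundary:
                dirs[r, c] = OUTLET
            else:
                dirs[r, c] = -3  # unresolved flat, fixed in second pass
    return dirs


def _resolve_flats(zf: np.ndarray, valid: np.ndarray, dirs: np.ndarray) -> None:
    """Drain flat cells toward the spill path by BFS from resolved cells of
    equal elevation (epsilon-gradient without modifying the DEM)."""
    nr, nc = zf.shape
    queue: deque[tuple[int, int]] = deque()
    flat = dirs == -3
    # seed with resolved cells that have an unresolved equal-elevation neighbor
    rs, cs = np.nonzero(flat)
    for r, c in zip(rs, cs):
        for k, (dr, dc) in enumerate(NEIGHBORS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]
                    and dirs[rr, cc] not in (-3, NODATA_DIR)
                    and zf[rr, cc] == zf[r, c]):
                dirs[r, c] = k
                queue.append((r, c))
                break
    while queue:
        r, c = queue.popleft()
        for k, (dr, dc) in enumerate(NEIGHBORS):
            rr, cc = r + dr, c + dc
            if (0 <= rr < nr and 0 <= cc < nc and dirs[rr, cc] == -3
                    and zf[rr, cc] == zf[r, c]):
                # point back toward the cell that just resolved
                dirs[rr, cc] = (k + 4) % 8
                queue.append((rr, cc))
    if np.any(dirs == -3):
        raise RuntimeError("unresolved flats after epsilon drainage; "
                           "is the DEM pit-filled?")


def d8_flow(dem_filled: Grid, stream_threshold: int = 50) -> FlowField:
    """D8 directions and flow accumulation from a pit-filled DEM.

    Accumulation counts the number of cells draining through each cell,
    including the cell itself, so it is ≥ 1 on every valid pixel.  Stream
    cells are those with accumulation ≥ ``stream_threshold``.
    """
    zf = dem_filled.filled(np.nan)
    valid = dem_filled.valid_mask
    dirs = _steepest_descent(zf, valid)
    _resolve_flats(zf, valid, dirs)

    nr, nc = zf.shape
    acc = np.where(valid, 1.0, np.nan)
    # Kahn topological order over the flow graph (also proves acyclicity)
    indeg = np.zeros((nr, nc), dtype=int)
    rs, cs = np.nonzero(valid)
    for r, c in zip(rs, cs):
        k = dirs[r, c]
        if k >= 0:
            indeg[r + NEIGHBORS[k][0], c + NEIGHBORS[k][1]] += 1
    queue = deque((r, c) for r, c in zip(rs, cs) if indeg[r, c] == 0)
    processed = 0
    while queue:
        r, c = queue.popleft()
        processed += 1
        k = dirs[r, c]
        if k >= 0:
            rr, cc = r + NEIGHBORS[k][0], c + NEIGHBORS[k][1]
            acc[rr, cc] += acc[r, c]
            indeg[rr, cc] -= 1
            if indeg[rr, cc] == 0:
                queue.append((rr, cc))
    if processed != len(rs):
        raise RuntimeError("cycle detected in D8 flow graph")

    dir_grid = dem_filled.like(dirs.astype(float), units="d8-code")
    acc_grid = dem_filled.like(acc, units="cells")
    stream = valid & (acc >= stream_threshold)
    return FlowField(dir_grid, acc_grid, stream, stream_threshold)


def twi(slope_g: Grid, acc: Grid, cell_m: float) -> Grid:
    """Topographic wetness index ln(a / tan β).

    ``a`` is the specific catchment area (accumulation × cell size, m);
    tan β is floored at 0.001 so flat pixels stay finite.  Slope grid must
    be in degrees.
    """
    require_aligned(slope_g, acc)
    tanb = np.maximum(np.tan(np.radians(slope_g.values)), 1e-3)
    a = acc.values * float(cell_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log(a / tanb)
    return slope_g.like(out, units="ln(m)")


@dataclass
class WatershedPartition:
    """Subcatchments labelled by the stream segment they drain to.

    Label 0 collects cells whose flow path leaves the grid without meeting
    a stream; it has no stream segment and is excluded from per-watershed
    shape statistics, but it still participates in the partition of the
    valid extent.
    """

    labels: Grid
    records: pd.DataFrame  # index: watershed id ≥ 1
    unassigned_cells: int
    cell_area_m2: float
    stream_segments: np.ndarray = None  # type: ignore[assignment]

    @property
    def stream_mask(self) -> np.ndarray:
        return self.stream_segments > 0

    def label_array(self) -> np.ndarray:
        lab = self.labels.values.copy()
        lab[self.labels.nodata_mask] = -1
        return lab.astype(int)

    def broadcast(self, column: str, fill: float = np.nan) -> Grid:
        """Paint a per-watershed value onto the grid by label."""
        lab = self.label_array()
        out = np.full(lab.shape, fill)
        for wid, val in self.records[column].items():
            out[lab == wid] = val
        out[lab == -1] = np.nan
        return self.labels.like(out, units="")


def delineate_watersheds(flow: FlowField, geographic: bool = False) -> WatershedPartition:
    """Partition the valid extent into subwatersheds of stream segments.

    A stream segment is a maximal stream reach between confluences (a
    confluence being a stream cell with ≥ 2 stream inflows); every cell is
    labelled by the segment its D8 path first reaches.  Stream length is
    the sum of cell steps (×√2 for diagonals) × cell size.
    """
    stream = flow.stream_mask
    if not stream.any():
        raise ValueError(
            "no stream cells at threshold "
            f"{flow.stream_threshold}; lower --stream-threshold")
    dirs = flow.dir_array
    valid = flow.directions.valid_mask
    nr, nc = dirs.shape
    from .grid import cell_dims_m
    dx_row, dy = cell_dims_m(flow.directions, geographic=geographic)
    cell_m = float((dx_row.mean() + dy) / 2.0)
    cell_area = float(dx_row.mean() * dy)

    # stream inflow counts -> segment heads
    inflows = np.zeros((nr, nc), dtype=int)
    rs, cs = np.nonzero(stream)
    for r, c in zip(rs, cs):
        k = dirs[r, c]
        if k >= 0:
            rr, cc = r + NEIGHBORS[k][0], c + NEIGHBORS[k][1]
            if stream[rr, cc]:
                inflows[rr, cc] += 1

    seg = np.zeros((nr, nc), dtype=int)
    seg_len: dict[int, float] = {}
    next_id = 1
    starts = [(r, c) for r, c in zip(rs, cs) if inflows[r, c] != 1]
    for r0, c0 in sorted(starts):
        wid = next_id
        next_id += 1
        seg[r0, c0] = wid
        length = 0.0
        r, c = r0, c0
        while True:
            k = dirs[r, c]
            if k < 0:
                break
            rr, cc = r + NEIGHBORS[k][0], c + NEIGHBORS[k][1]
            if not stream[rr, cc]:
                break
            step = _DIST[k] * cell_m
            if inflows[rr, cc] != 1:  # next segment starts at the confluence
                length += step
                break
            length += step
            seg[rr, cc] = wid
            r, c = rr, cc
        # a one-cell segment (confluence at an outlet) still spans its cell
        seg_len[wid] = length if length > 0 else cell_m

    # label every cell by the first stream segment on its flow path (memoized)
    labels = np.full((nr, nc), -1, dtype=int)
    labels[stream] = seg[stream]
    order = np.argsort(flow.accumulation.filled(np.inf), axis=None)
    for idx in order:
        r, c = divmod(int(idx), nc)
        if not valid[r, c] or labels[r, c] != -1:
            continue
        path = []
        rr, cc = r, c
        lab = 0
        while True:
            if labels[rr, cc] != -1:
                lab = labels[rr, cc]
                break
            path.append((rr, cc))
            k = dirs[rr, cc]
            if k < 0:
                lab = 0  # exits the grid without meeting a stream
                break
            rr, cc = rr + NEIGHBORS[k][0], cc + NEIGHBORS[k][1]
        for pr, pc in path:
            labels[pr, pc] = lab

    ids = sorted(seg_len)
    counts = {wid: int((labels == wid).sum()) for wid in ids}
    records = pd.DataFrame({
        "cells": pd.Series(counts),
        "area_m2": pd.Series({w: counts[w] * cell_area for w in ids}),
        "stream_cells": pd.Series({w: int((seg == w).sum()) for w in ids}),
        "stream_length_m": pd.Series(seg_len),
    })
    records.index.name = "watershed"
    lab_grid = flow.directions.like(labels.astype(float), units="label")
    return WatershedPartition(lab_grid, records,
                              unassigned_cells=int((labels == 0).sum()),
                              cell_area_m2=cell_area,
                              stream_segments=seg)


def horton_form_factor(ws: WatershedPartition,
                       dialect: str = "area_over_length") -> tuple[pd.Series, Grid]:
    """Catchment-shape factor per watershed, broadcast to a grid by label.

    ``area_over_length`` is A/L (metres); the classical Horton definition
    A/L² (dimensionless) is available as dialect ``"area_over_length2"``.
    """
    if dialect not in ("area_over_length", "area_over_length2"):
        raise ValueError(f"unknown Horton dialect {dialect!r}")
    L = ws.records["stream_length_m"]
    if (L <= 0).any():
        raise ValueError("watershed with zero stream length")
    A = ws.records["area_m2"]
    ff = A / L if dialect == "area_over_length" else A / L**2
    ff.name = "form_factor"
    ws.records["form_factor"] = ff
    return ff, ws.broadcast("form_factor")
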