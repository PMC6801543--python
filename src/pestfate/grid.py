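"""Raster data model shared by every pipeline stage.

A :class:`Grid` is one 2-D band with a GDAL-style geotransform and an
explicit nodata mask.  All arithmetic between grids requires identical
shape and transform — nothing is ever resampled implicitly.  Nodata
propagates by union: a pixel that is nodata in any input is nodata in the
output, and no value is ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Grid",
    "GridStack",
    "SoilProfileStack",
    "ProcessMap",
    "normalize_minmax",
    "complement",
    "depth_weighted_average",
    "combine_linear",
    "resample_mean",
    "require_aligned",
    "cell_dims_m",
]

#: metres per degree of latitude (spherical approximation)
M_PER_DEG = 111_320.0


class GridAlignmentError(ValueError):
    """Raised when grids with different shape/transform are combined."""


@dataclass
class Grid:
    """One raster band: values + geotransform + nodata mask.

    Parameters
    ----------
    values:
        2-D float array, row 0 = northernmost row.
    transform:
        GDAL geotransform ``(x0, dx, 0, y0, 0, -dy)``; rotation terms must
        be zero (north-up rasters only) and cell sizes strictly positive.
    nodata_mask:
        Boolean array, True where the pixel is invalid.
    units:
        Free-text units of the values.
    crs_tag:
        Free-text CRS identifier (e.g. ``"local-metric"`` or ``"EPSG:4326"``).
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    units: str = ""
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        t = tuple(float(v) for v in self.transform)
        if len(t) != 6:
            raise ValueError("transform must have 6 elements")
        if t[2] != 0.0 or t[4] != 0.0:
            raise ValueError("rotated rasters are not supported (north-up only)")
        if t[1] <= 0 or t[5] >= 0:
            raise ValueError("cell sizes must be strictly positive, dy negative (north-up)")
        self.transform = t

    # -- basic geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> tuple[float, float]:
        """(dx, dy) in transform units, both positive."""
        return self.transform[1], -self.transform[5]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out

    def like(self, values: np.ndarray, *, units: str | None = None,
             extra_nodata: np.ndarray | None = None) -> "Grid":
        """New Grid on this geometry, nodata = this mask ∪ extra_nodata ∪ non-finite."""
        values = np.asarray(values, dtype=float)
        mask = self.nodata_mask | ~np.isfinite(values)
        if extra_nodata is not None:
            mask = mask | extra_nodata
        vals = values.copy()
        vals[mask] = np.nan
        return Grid(vals, self.transform, mask,
                    units=self.units if units is None else units,
                    crs_tag=self.crs_tag)

    def row_latitudes(self) -> np.ndarray:
        """Latitude (y coordinate) of each row centre."""
        y0, dy = self.transform[3], self.transform[5]
        return y0 + dy * (np.arange(self.shape[0]) + 0.5)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Grid(shape={self.shape}, cell={self.cell_size}, "
                f"units={self.units!r}, valid={self.n_valid()}/{self.values.size})")


@dataclass
class ProcessMap(Grid):
    """A normalized [0, 1] vulnerability grid tagged with its process name."""

    process: str = ""
    provenance: dict = field(default_factory=dict)


@dataclass
class GridStack:
    """Named collection of aligned grids; month keys 1..12 when temporal."""

    grids: Mapping[object, Grid]
    temporal: bool = False

    def __post_init__(self) -> None:
        self.grids = dict(self.grids)
        if not self.grids:
            raise ValueError("empty GridStack")
        require_aligned(*self.grids.values())
        if self.temporal and sorted(self.grids) != list(range(1, 13)):
            raise ValueError("temporal stack requires month keys 1..12")

    def __getitem__(self, key) -> Grid:
        return self.grids[key]

    def __iter__(self):
        return iter(self.grids)

    def __len__(self) -> int:
        return len(self.grids)

    def items(self):
        return self.grids.items()


@dataclass
class SoilProfileStack:
    """Soil property at fixed depth intervals (contiguous, starting at 0 cm)."""

    layers: Sequence[Grid]
    intervals: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.layers = list(self.layers)
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        if len(self.layers) != len(self.intervals):
            raise ValueError("layer count must equal interval count")
        if not self.layers:
            raise ValueError("empty profile stack")
        require_aligned(*self.layers)
        top = 0.0
        for a, b in self.intervals:
            if a != top or b <= a:
                raise ValueError(
                    "intervals must be contiguous, non-overlapping and start at 0")
            top = b


# ---------------------------------------------------------------------------
# operations


def require_aligned(*grids: Grid) -> None:
    """Raise GridAlignmentError unless all grids share shape and transform."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or g.transform != ref.transform:
            raise GridAlignmentError(
                f"grids are not aligned: {g.shape}/{g.transform} vs "
                f"{ref.shape}/{ref.transform}")


def normalize_minmax(g: Grid) -> Grid:
    """Min–max rescale valid pixels to [0, 1] over the full map extent.

    Constant maps map to 0 (documented degenerate rule); an all-nodata grid
    is an error.
    """
    if g.n_valid() == 0:
        raise ValueError("cannot normalize an all-nodata grid")
    vv = g.valid_values()
    lo, hi = float(vv.min()), float(vv.max())
    if hi == lo:
        out = np.zeros_like(g.values)
    else:
        out = (g.values - lo) / (hi - lo)
    return g.like(out, units="dimensionless")


def complement(g: Grid) -> Grid:
    """Per-pixel 1 − x for a grid already normalized to [0, 1]."""
    vv = g.valid_values()
    if vv.size and (vv.min() < -1e-9 or vv.max() > 1 + 1e-9):
        raise ValueError("complement requires values in [0, 1]")
    return g.like(1.0 - g.values, units="dimensionless")


def depth_weighted_average(p: SoilProfileStack) -> Grid:
    """Thickness-weighted mean over the soil profile.

    A pixel is nodata in the output if any layer is nodata there.
    """
    thick = np.array([b - a for a, b in p.intervals], dtype=float)
    total = thick.sum()
    if total <= 0:
        raise ValueError("zero total profile thickness")
    ref = p.layers[0]
    acc = np.zeros(ref.shape)
    mask = np.zeros(ref.shape, dtype=bool)
    for t, layer in zip(thick, p.layers):
        acc += t * np.where(layer.nodata_mask, 0.0, layer.values)
        mask |= layer.nodata_mask
    return ref.like(acc / total, extra_nodata=mask)


def combine_linear(terms: Iterable[tuple[float, Grid]]) -> Grid:
    """Per-pixel weighted sum of aligned grids with union-nodata propagation."""
    terms = list(terms)
    if not terms:
        raise ValueError("combine_linear requires at least one term")
    require_aligned(*(g for _, g in terms))
    ref = terms[0][1]
    acc = np.zeros(ref.shape)
    mask = np.zeros(ref.shape, dtype=bool)
    for w, g in terms:
        acc += float(w) * np.where(g.nodata_mask, 0.0, g.values)
        mask |= g.nodata_mask
    return ref.like(acc, units="", extra_nodata=mask)


def resample_mean(g: Grid, factor: int) -> Grid:
    """Aggregate to coarser cells by block mean over valid pixels.

    Blocks with no valid pixel become nodata.  Never invoked implicitly;
    inputs to the pipeline must be pre-aligned.
    """
    if factor < 1 or g.shape[0] % factor or g.shape[1] % factor:
        raise ValueError("shape must be divisible by the aggregation factor")
    nr, nc = g.shape[0] // factor, g.shape[1] // factor
    v = np.where(g.nodata_mask, 0.0, g.values).reshape(nr, factor, nc, factor)
    n = g.valid_mask.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    s = v.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    x0, dx, _, y0, _, dy = g.transform
    t = (x0, dx * factor, 0.0, y0, 0.0, dy * factor)
    return Grid(out, t, n == 0, units=g.units, crs_tag=g.crs_tag)


def cell_dims_m(g: Grid, geographic: bool = False) -> tuple[np.ndarray, float]:
    """Cell width per row and cell height, in metres.

    For planar CRSs the transform units are metres.  For geographic rasters
    the per-row width is ``dx_deg × 111320 m × cos(latitude)`` and the height
    ``dy_deg × 111320 m``.
    """
    dx, dy = g.cell_size
    if not geographic:
        return np.full(g.shape[0], dx), dy
    lat = np.radians(g.row_latitudes())
    return dx * M_PER_DEG * np.cos(lat), dy * M_PER_DEG


def as_process_map(g: Grid, process: str, provenance: dict | None = None) -> ProcessMap:
    """Tag a normalized grid as a named ProcessMap."""
    return ProcessMap(g.values, g.transform, g.nodata_mask,
                      units="dimensionless", crs_tag=g.crs_tag,
                      process=process, provenance=provenance or {})
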