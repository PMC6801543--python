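"""Seeded synthetic inputs for every pipeline stage.

The generators emulate the *statistical* structure the analysis assumes —
spatially autocorrelated fields on a shared grid with a common nodata
mask, terrain with ridges and valleys that yield nontrivial drainage
networks, monthly climate with sinusoidal seasonality, categorical land
use drawn from a latent field, and a residue table with controllable
counts — with no claim of geographic realism.

One global seed fans out to per-variable subseeds by stable hashing, so
adding a generator never perturbs the output of an existing one, and a
fixed seed reproduces every raster and table bit-for-bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Grid, GridStack, SoilProfileStack

__all__ = [
    "ScenarioSpec",
    "random_field",
    "synth_dem",
    "synth_climate_stack",
    "synth_landuse",
    "synth_residue_db",
    "synth_scenario",
    "subseed",
]

#: SoilGrids-style fixed depth intervals, 0–200 cm, seven layers
SOIL_DEPTH_INTERVALS = ((0, 5), (5, 15), (15, 30), (30, 60),
                        (60, 100), (100, 150), (150, 200))

#: Africa bounding box for residue coordinates (lat, lon)
AFRICA_BBOX = (-35.0, 38.0, -26.0, 64.0)

_DEFAULT_SOIL_RANGES: dict[str, tuple[float, float]] = {
    "groundwater_depth": (0.5, 80.0),    # m
    "depth_to_bedrock": (10.0, 5000.0),  # cm
    "soil_moisture": (0.02, 0.45),       # m3/m3
    "soil_thickness": (10.0, 200.0),     # cm
    "organic_matter": (0.2, 6.0),        # %
    "rainfall_erosivity": (500.0, 9000.0),   # MJ·mm/ha/h/yr
    "evi": (0.05, 0.85),
    "oc": (0.1, 3.5),                    # % organic carbon
    "clay_profile": (5.0, 60.0),         # %
    "ph": (4.5, 8.5),
    "cec": (2.0, 40.0),                  # cmol(+)/kg
}

_DEFAULT_CLIMATE: dict[str, dict[str, float]] = {
    # range of the spatial base field, seasonal amplitude, phase (months)
    "wind": {"low": 0.5, "high": 6.0, "amplitude": 1.0, "phase": 3.0},
    "srad": {"low": 12.0, "high": 28.0, "amplitude": 3.0, "phase": 0.0},
    "temp": {"low": 12.0, "high": 38.0, "amplitude": 5.0, "phase": 0.0},
    "rh": {"low": 0.25, "high": 0.9, "amplitude": 0.08, "phase": 6.0},
}

_DEFAULT_LANDUSE_PROPORTIONS: dict[str, float] = {
    "forest": 0.30, "grass_scrub_woodland": 0.35, "barren_sparse": 0.15,
    "cultivated": 0.15, "built_up": 0.05,
}


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study scenario."""

    shape: tuple[int, int] = (128, 128)
    cell_size_m: float = 1000.0
    seed: int = 0
    correlation_length: float = 6.0   # cells
    relief_m: float = 400.0
    nodata_fraction: float = 0.02
    soil_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SOIL_RANGES))
    climate: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CLIMATE.items()})
    landuse_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LANDUSE_PROPORTIONS))

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("scenario grids must be at least 16×16")
        total = sum(self.landuse_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("land-use proportions must sum to 1")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata fraction must be in [0, 1)")
        if self.correlation_length >= min(self.shape):
            raise ValueError("correlation length must be below the grid extent")

    @property
    def transform(self) -> tuple[float, ...]:
        c = self.cell_size_m
        return (0.0, c, 0.0, self.shape[0] * c, 0.0, -c)


def subseed(seed: int, name: str) -> int:
    """Stable per-variable subseed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _nodata_mask(spec: ScenarioSpec) -> np.ndarray:
    """Shared autocorrelated nodata mask used by every scenario raster."""
    if spec.nodata_fraction == 0:
        return np.zeros(spec.shape, dtype=bool)
    rng = np.random.default_rng(subseed(spec.seed, "nodata"))
    latent = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                     spec.correlation_length)
    cut = np.quantile(latent, spec.nodata_fraction)
    return latent < cut


def random_field(spec: ScenarioSpec, name: str, low: float, high: float,
                 correlation_length: float | None = None,
                 mask: np.ndarray | None = None) -> Grid:
    """Smoothed-noise field rescaled exactly to [low, high].

    Gaussian-kernel smoothing of white noise; correlation length 0
    recovers white noise.  Deterministic per (spec.seed, name).
    """
    corr = spec.correlation_length if correlation_length is None else correlation_length
    if corr < 0:
        raise ValueError("correlation length must be non-negative")
    if high < low:
        raise ValueError("invalid range")
    rng = np.random.default_rng(subseed(spec.seed, name))
    f = rng.standard_normal(spec.shape)
    if corr > 0:
        f = ndimage.gaussian_filter(f, corr)
    lo, hi = f.min(), f.max()
    f = (f - lo) / (hi - lo) * (high - low) + low if hi > lo else np.full_like(f, low)
    if mask is None:
        mask = _nodata_mask(spec)
    return Grid(np.where(mask, np.nan, f), spec.transform, mask)


def synth_dem(spec: ScenarioSpec, mode: str = "ridged") -> Grid:
    """Synthetic elevation model.

    ``ridged`` superposes a broad tilt, a ridge-and-valley field (folded
    correlated noise) and fine noise, giving a D8 network with several
    subwatersheds at the default stream threshold on a 128×128 grid.
    ``inclined`` is a doubly tilted plane whose flow converges to the
    south-west corner (single outlet); ``flat`` is constant.
    """
    nr, nc = spec.shape
    mask = _nodata_mask(spec)
    if mode == "flat":
        z = np.zeros(spec.shape)
    elif mode == "inclined":
        col = np.arange(nc)[None, :]
        row = np.arange(nr)[:, None]
        z = spec.relief_m * (col / max(nc - 1, 1)
                             + 2.0 * (nr - 1 - row) / max(nr - 1, 1)) / 3.0
        z = np.broadcast_to(z, spec.shape).copy()
    elif mode == "ridged":
        rng = np.random.default_rng(subseed(spec.seed, "dem"))
        broad = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                        max(spec.correlation_length * 3, 1.0))
        folds = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                        spec.correlation_length)

        def unit(a: np.ndarray) -> np.ndarray:
            return (a - a.min()) / (a.max() - a.min())

        ridges = 1.0 - np.abs(2.0 * unit(folds) - 1.0)
        fine = ndimage.gaussian_filter(rng.standard_normal(spec.shape), 1.0)
        col = np.arange(nc)[None, :] / max(nc - 1, 1)
        z = spec.relief_m * (0.55 * ridges + 0.30 * unit(broad)
                             + 0.05 * unit(fine) + 0.10 * col)
    else:
        raise ValueError(f"unknown DEM mode {mode!r}")
    return Grid(np.where(mask, np.nan, z), spec.transform, mask, units="m")


def synth_climate_stack(spec: ScenarioSpec, variable: str) -> GridStack:
    """12 monthly grids: base field × 1 + seasonal sinusoid + noise.

    Month m value = base + A·sin(2π(m − 1 − phase)/12) + ε_m with monthly
    noise ε_m of SD 0.1·A, so amplitude 0 gives 12 identical months.
    """
    if variable not in spec.climate:
        raise ValueError(f"unknown climate variable {variable!r}")
    p = spec.climate[variable]
    mask = _nodata_mask(spec)
    base = random_field(spec, f"climate:{variable}", p["low"], p["high"],
                        mask=mask)
    amp, phase = float(p["amplitude"]), float(p["phase"])
    rng = np.random.default_rng(subseed(spec.seed, f"climate-noise:{variable}"))
    months = {}
    for m in range(1, 13):
        season = amp * np.sin(2.0 * np.pi * (m - 1 - phase) / 12.0)
        noise = 0.1 * amp * rng.standard_normal(spec.shape)
        months[m] = base.like(base.values + season + noise)
    return GridStack(months, temporal=True)


def _latent_classes(spec: ScenarioSpec, name: str,
                    proportions: Mapping[str, float]) -> Grid:
    """Quantile-bin a latent correlated field into ordered class codes 1..k."""
    latent = random_field(spec, name, 0.0, 1.0)
    vals = latent.valid_values()
    out = np.full(spec.shape, np.nan)
    cum = 0.0
    lower = -np.inf
    for code, (cls, prop) in enumerate(proportions.items(), start=1):
        cum += prop
        upper = np.quantile(vals, min(cum, 1.0))
        sel = (latent.values > lower) & (latent.values <= upper)
        out[sel] = code
        lower = upper
    out[np.isnan(out) & latent.valid_mask] = len(proportions)
    return latent.like(out, units="class")


def synth_landuse(spec: ScenarioSpec) -> Grid:
    """Land-use class codes 1..5 drawn from a latent correlated field with
    the requested class proportions."""
    return _latent_classes(spec, "landuse", spec.landuse_proportions)


def synth_soil_profile(spec: ScenarioSpec, name: str,
                       low: float, high: float) -> SoilProfileStack:
    """Soil property at the seven fixed depth intervals: a lateral base
    field plus a smooth depth trend and small per-layer noise."""
    mask = _nodata_mask(spec)
    base = random_field(spec, f"profile:{name}", low, high, mask=mask)
    trend = random_field(spec, f"profile-trend:{name}", -1.0, 1.0, mask=mask)
    rng = np.random.default_rng(subseed(spec.seed, f"profile-noise:{name}"))
    span = 0.15 * (high - low)
    layers = []
    n = len(SOIL_DEPTH_INTERVALS)
    for i in range(n):
        depth_frac = i / (n - 1)
        vals = (base.values + span * trend.values * depth_frac
                + 0.02 * (high - low) * rng.standard_normal(spec.shape))
        layers.append(base.like(np.clip(vals, low, high)))
    return SoilProfileStack(layers, SOIL_DEPTH_INTERVALS)


def synth_scenario(spec: ScenarioSpec) -> dict[str, object]:
    """Every input the full pipeline needs, on one shared grid and mask."""
    sr = spec.soil_ranges
    mask = _nodata_mask(spec)

    def rf(name: str, key: str | None = None) -> Grid:
        lo, hi = sr[key or name]
        return random_field(spec, name, lo, hi, mask=mask)

    scenario: dict[str, object] = {
        "dem": synth_dem(spec),
        "drainage_class": _latent_classes(
            spec, "drainage", {"low": 0.3, "moderate": 0.4, "high": 0.3}),
        "groundwater_depth": rf("groundwater_depth"),
        "depth_to_bedrock": rf("depth_to_bedrock"),
        "soil_moisture": rf("soil_moisture"),
        "soil_thickness": rf("soil_thickness"),
        "organic_matter": rf("organic_matter"),
        "rainfall_erosivity": rf("rainfall_erosivity"),
        "evi": rf("evi"),
        "landuse": synth_landuse(spec),
        "structure_class": _latent_classes(
            spec, "structure",
            {"very_fine": 0.2, "fine": 0.35, "medium_coarse": 0.3, "blocky": 0.15}),
        "oc_profile": synth_soil_profile(spec, "oc", *sr["oc"]),
        "clay_profile": synth_soil_profile(spec, "clay", *sr["clay_profile"]),
        "ph_profile": synth_soil_profile(spec, "ph", *sr["ph"]),
        "cec_profile": synth_soil_profile(spec, "cec", *sr["cec"]),
        "pet": random_field(spec, "pet", 800.0, 2400.0, mask=mask),
    }
    # texture percentages from three positive fields scaled to sum to 95 %
    comps = [np.exp(random_field(spec, f"texture:{t}", -1.0, 1.0,
                                 mask=mask).values)
             for t in ("silt", "sand", "clay")]
    total = sum(comps)
    ref = scenario["evi"]
    for name, comp in zip(("silt", "sand", "clay"), comps):
        scenario[name] = ref.like(95.0 * comp / total, units="%")
    for var in ("wind", "srad", "temp", "rh"):
        scenario[var] = synth_climate_stack(spec, var)
    return scenario


# ---------------------------------------------------------------------------
# residue table generator


def synth_residue_db(counts: Mapping[tuple[str, str], int],
                     georef_fraction: float = 1.0,
                     seed: int = 0,
                     n_locations: int | None = None,
                     n_studies: int = 10,
                     year_range: tuple[int, int] = (1992, 2016)):
    """Synthetic insecticide-residue table with exact per-(compound,
    substrate) counts.

    ``round(georef_fraction × n)`` rows receive coordinates drawn from a
    pool of ``n_locations`` distinct points inside the Africa bounding
    box; the remainder get no coordinates.  Returns a
    :class:`~pestfate.residues.ResidueDatabase`.
    """
    from .residues import ResidueDatabase, SUBSTRATES
    for key, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {key}")
        if key[1] not in SUBSTRATES:
            raise ValueError(f"unknown substrate {key[1]!r}")
    total = int(sum(counts.values()))
    rng = np.random.default_rng(seed % (2**31))
    n_geo = int(round(georef_fraction * total))
    if n_locations is None:
        n_locations = max(1, n_geo // 4) if n_geo else 1
    lat_min, lat_max, lon_min, lon_max = AFRICA_BBOX
    # strictly interior pool of distinct coordinate pairs
    pool = set()
    while len(pool) < n_locations:
        lat = float(np.round(rng.uniform(lat_min + 1, lat_max - 1), 6))
        lon = float(np.round(rng.uniform(lon_min + 1, lon_max - 1), 6))
        pool.add((lat, lon))
    pool = sorted(pool)

    if n_geo < n_locations and n_geo:
        raise ValueError("more distinct locations requested than "
                         "georeferenced rows")
    # every pool point is used at least once so the requested number of
    # distinct locations is recovered exactly by the funnel
    coord_of = list(range(n_locations)) + [
        int(k) for k in rng.integers(n_locations, size=max(n_geo - n_locations, 0))]
    # likewise every study id occurs at least once
    n_studies = min(n_studies, total) if total else n_studies
    study_of = list(range(n_studies)) + [
        int(k) for k in rng.integers(max(n_studies, 1),
                                     size=max(total - n_studies, 0))]
    study_of = [study_of[j] for j in rng.permutation(total)] if total else []

    rows = []
    i = 0
    for (compound, substrate), n in sorted(counts.items()):
        for _ in range(n):
            geo = i < n_geo
            lat, lon = pool[coord_of[i]] if geo else (np.nan, np.nan)
            rows.append({
                "study_id": f"S{1 + study_of[i]:03d}",
                "year": int(rng.integers(year_range[0], year_range[1] + 1)),
                "months": "1-12",
                "substrate": substrate,
                "collection_method": "grab",
                "depth_cm": float(rng.integers(0, 30)),
                "extraction_method": "soxhlet",
                "quantification_method": "GC-MS",
                "detection_limit": 0.001,
                "quantification_limit": 0.005,
                "compound": compound,
                "compound_class": "organochlorine",
                "concentration": float(np.round(rng.lognormal(-2.0, 1.0), 6)),
                "concentration_units": "mg/kg",
                "latitude": lat,
                "longitude": lon,
            })
            i += 1
    table = pd.DataFrame(rows, columns=ResidueDatabase.COLUMNS)
    return ResidueDatabase(table)
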