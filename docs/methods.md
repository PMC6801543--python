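# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `pestfate`, and what the synthetic test
bed does and does not demonstrate.

## Scope and philosophy

The five process maps are *relative vulnerability indices*, not
calibrated flux predictions.  Each combines normalized environmental
covariates through a deliberately simple, documented rule (weighted sum,
mean of indicators, or a published empirical equation), because in
data-sparse regions there are no observations of the processes
themselves to fit anything richer.  Pesticide-specific behaviour
(degradation, charge-dependent sorption, application dose and method)
is out of scope, as is combining the five maps into a single risk
score: the maps are inputs to risk assessment, not a risk assessment.

## Raster conventions

* A `Grid` is one north-up band with a GDAL-style geotransform and an
  explicit boolean nodata mask.  Cell sizes must be strictly positive;
  rotated rasters are rejected.
* **Alignment is never implicit.** Any operation combining grids
  requires identical shape and transform and raises otherwise.  A
  block-mean `resample_mean` (valid-pixel-aware) exists for preparing
  inputs but is never invoked automatically.
* **Nodata propagates by union** and is never imputed: an output pixel
  is invalid iff any contributing input pixel is.
* **Normalization** is min–max over the valid pixels of the full map
  extent (the maps are continent-scale, so the extremes are
  population extremes, not sample artifacts).  A constant map maps to
  0 — the degenerate rule is "no contrast, no vulnerability signal".
  Whether robust quantile scaling should replace min–max for
  heavy-tailed soil variables (CEC, clay) is an open question; min–max
  is the default because it is what index overlays of this family use.
* For geographic rasters, per-row cell width is
  `Δlon × 111 320 m × cos(latitude)`; synthetic tests use a planar CRS
  with square metric cells.
* GeoTIFF I/O is built on `tifffile`, writing the standard
  georeferencing tags (ModelPixelScale, ModelTiepoint), the GDAL nodata
  tag and a JSON description carrying units and process metadata.  No
  reprojection is supported.

## Terrain and hydrology

* **Slope** uses the Horn 3×3 stencil; the border is padded by odd
  reflection, which reduces border pixels to one-sided differences.
  Neighbors under the nodata mask fall back to the centre value.
* **Pit filling** is priority-flood: every interior cell ends with a
  monotone non-ascending path to the edge, a pit-free DEM is returned
  unchanged, and output ≥ input everywhere.
* **D8 routing**: steepest descent over the 8 neighbors with diagonal
  distances ×√2.  Ties are broken by the fixed neighbor order
  E, SE, S, SW, W, NW, N, NE for bit-reproducibility.  Flats left by
  filling are drained by a breadth-first sweep from their resolved
  rim (an epsilon gradient toward the spill path without modifying
  elevations); unresolvable flats raise an error.  Accumulation counts
  each cell itself (so it is ≥ 1 and log-transforms are defined) and is
  computed in topological order, which simultaneously proves the flow
  graph acyclic.
* **TWI** is ln(a / tan β) with specific catchment area
  a = accumulation × cell size and tan β floored at 0.001 so flat
  pixels stay finite.
* **Streams** are cells with accumulation ≥ a configurable threshold
  (default 50 cells; continental studies use precomputed hydrography,
  so the threshold is a free parameter of the emulation).
  **Subwatersheds** are the drainage areas of stream segments between
  confluences; every cell is labelled by the first segment its D8 path
  reaches.  Cells that exit the grid without meeting a stream form a
  catch-all unit (label 0) that participates in the partition but has
  no shape statistics.  Stream length sums cell steps (×√2 diagonal);
  a degenerate single-cell segment is assigned one cell length so
  shape factors stay defined.
* **Horton form factor**: the default is area / stream length, as used
  by the runoff-transfer indicator here; the classical dimensionless
  area / length² is available behind a dialect flag because the two
  definitions coexist in the literature.

## Process models — choices where the design was open

* **Leaching weights** (5, 5, 2, 1, 5) are the DRASTIC weights; they
  are exposed read-only and can be overridden only through the
  sensitivity machinery.  Drainage class (low/moderate/high
  infiltration, boundaries 15 and 50 mm/h) is coded 0 / 0.5 / 1 —
  equally spaced because no numeric coding is prescribed — and the same
  layer stands in for bedrock type, whose porosity it reflects.  Raw
  depths are normalized first and complemented inside the formula
  (normalize-then-complement), reading the equation as printed.
* **Runoff indicators** are combined by arithmetic mean, which on
  binary {0,1} indicators is exactly the classical integer IRIP score
  divided by the indicator count (a tested equivalence).  Orientation:
  drainage and soil thickness are complemented for generation
  (impermeable/thin ⇒ runoff); slope enters transfer directly
  (steep ⇒ transport) but complemented for accumulation
  (flat ⇒ ponding).  Break-of-slope and artificial linear axes are not
  representable at continental resolution and are omitted.  The
  17-class MODIS-style land-cover vocabulary reduces to the five
  weighted classes through an editable mapping table.
* **Erodibility nomograph**: the textural factor uses the standard
  parenthesization (m_silt + m_vfs)(100 − m_clay); a literal variant
  without the leading parentheses is selectable as a dialect.  K is
  floored at 0 (the nomograph goes negative for extreme inputs).  The
  slope factor branches on tan θ (slope percent), not sin θ; the jump
  between branches at 9 % is < 0.01.  The slope-length component L and
  support-practice factor P are not modelled (sub-grid process; no
  continental data).
* **Stream velocity**: b = c = 0.5.  The velocity scale V_m is the
  watershed's mean slope, min–max normalized across watersheds and
  floored at 10⁻³ — one defensible reading of "related to the mean
  slope"; it is injectable as a strategy.  Velocity is evaluated on
  stream cells (slope floored at 10⁻⁴), where deposition physically
  happens; for a gapless index map the watershed's V_m is painted onto
  off-stream cells.  The sedimentation index is normalized load ×
  (1 − normalized velocity) — a product, so either zero load or fast
  flow suppresses it.
* **SFC**: depth-weighted profile averaging over the seven fixed
  0–200 cm intervals precedes normalization; weights are all 1.
* **Volatilization**: monthly stacks are normalized across the whole
  12-month stack (not per month) so months remain comparable; PET is an
  annual climatology and enters every month identically.  The seasonal
  dispersion map is the population SD of the 12 monthly scores.

## Sensitivity analysis

One-at-a-time: a raw input is scaled by (1 + δ), δ = ±5 %, and the full
pipeline re-run; the report is the mean and the pixel-wise SD of
100·|out′ − out|/out over valid pixels, excluding pixels whose baseline
is below 10⁻⁹.  Because these overlays are scale-free — a min–max
re-fit absorbs any uniform rescaling exactly — the re-run reuses the
*baseline's* normalization bounds (recorded on the first run and frozen
thereafter).  This measures the model's response to the perturbation
itself; values may then exceed the frozen [0,1] range slightly, which
is accepted arithmetic, not an error.  For purely linear overlays the
±5 % responses are symmetric.

Weight deviations for the leaching overlay shift each of the five
weights by ±d points (d = 1…4), one at a time, clamped to the 1–5 range
the weights span, and average the percent change over all weight/sign
runs.  Clamping makes some runs no-ops (a weight of 5 cannot increase),
so the response flattens mildly at large d, but remains near-linear:
the through-origin fit of response vs deviation has uncentered
R² > 0.99 on synthetic inputs.

## Synthetic data: what it emulates, what it does not

Generators are seeded; one global seed fans out to per-variable
subseeds by SHA-256 hashing, so adding a generator never perturbs
existing outputs, and all rasters and tables are bit-reproducible.

* Continuous fields are Gaussian-smoothed white noise rescaled exactly
  to a stated range (correlation length → 0 recovers white noise); all
  scenario rasters share one autocorrelated nodata mask.
* The DEM superposes a broad tilt, a folded ridge-and-valley field and
  fine noise; at the default 128×128 / threshold-50 configuration it
  yields several subwatersheds.  An inclined-plane mode with a single
  outlet and a flat mode exist for hand-checkable routing tests.
* Monthly climate is a spatial base field plus a sinusoidal seasonal
  cycle (amplitude and phase per variable) plus monthly noise with SD
  equal to 10 % of the amplitude — so zero amplitude gives an exactly
  constant year.
* Land use, drainage class and structure class are quantile bins of
  latent correlated fields with configurable proportions; soil texture
  fractions are three positive fields scaled to sum to 95 %.
* The residue generator produces exact per-(compound, substrate)
  counts, an exact number of distinct sampling locations inside the
  African bounding box, a controllable georeferenced fraction and a
  guaranteed number of distinct studies.

The emulation is statistical only: ranges, autocorrelation,
seasonality and class proportions are plausible, but there is no
geographic realism, no covariance between soil variables and climate,
and no measurement error structure.  Passing tests therefore
demonstrate the *correctness and invariances of the pipeline*
(conservation laws, normalization, monotonic orientations, equivalence
to hand evaluation), not the accuracy of any map over real terrain.
Published values tied to the real continental layers (map patterns,
absolute sensitivity percentages, maximum erosion rates) are not
reproducible from synthetic inputs and are not asserted.

## Problem sizes and determinism

The test suite runs on 32–64² grids (seconds); hydrology conservation
and the acceptance script use a 128×128 scenario, the scale at which
the default stream threshold produces a rich subwatershed mosaic while
the whole end-to-end run stays around a second.  `run_all` writes a
manifest with a config hash and SHA-256 of every artifact; re-running
with the same config is bit-identical.

## Known limitations

* D8 is single-direction routing; divergent flow (D-infinity, MFD) is
  not modelled, so accumulation on convex hillslopes is concentrated
  into single cell chains.
* Vertisol crack flow is not represented in the leaching overlay.
* Sediment is not routed between watersheds; the load is a
  within-watershed sum.
* The index overlays assume linear, independent contributions; real
  sorption and volatilization are non-linear and compound-specific.
* Min–max normalization is outlier-sensitive; consider the quantile
  variant for heavy-tailed inputs.
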