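# pestfate

**Continental mapping of the processes that govern the environmental fate
of agricultural pesticides.**

After a field is sprayed, where a pesticide ends up is controlled by a
handful of landscape-scale processes: **leaching** toward groundwater,
**surface runoff** (its generation, transfer and accumulation),
**erosion and sedimentation** of particle-bound compounds, the soil's
**storage and filtering capacity**, and **volatilization** to the
atmosphere.  In data-sparse regions — the motivating case is the African
continent — none of these can be fitted to observations, but each can be
mapped as a *relative vulnerability index* from widely available gridded
environmental covariates.  `pestfate` implements that pipeline as a
reusable raster library for environmental-exposure scientists: the five
process models, the terrain/hydrology derivatives they need, a
one-at-a-time sensitivity analysis, seeded synthetic input generators so
everything is testable without downloads, and an insecticide-residue
observation database with validation and summary tooling.

## The models

All inputs are min–max normalized to [0, 1] over the map extent; every
output map is again normalized, so maps rank vulnerability rather than
predict absolute fluxes.

**Leaching** — a DRASTIC-weighted linear overlay:

    L = 5·D + 5·(1 − GW) + 2·(1 − DB) + (1 − SL) + 5·SM

with drainage-class score *D*, groundwater depth *GW*, depth to bedrock
*DB*, slope *SL* and mean soil moisture *SM*.  Shallow water tables,
shallow bedrock and flat, moist, permeable ground leach most.

**Surface runoff** — three susceptibility maps in the style of the IRIP
method (Indicator of Intense Pluvial Runoff), each the mean of
normalized continuous indicators: *generation* from impermeable soil,
thin soil, erodibility, topography (slope + TWI) and land-use
imperviousness (forest 0 … built-up 1); *transfer* from generation,
slope and the Horton form factor; *accumulation* from generation,
complemented slope, TWI and flow accumulation.

**Sedimentation** — USLE erosion `E = R·K·C·S` (t/ha/yr) with the
Wischmeier–Smith erodibility nomograph

    K = ([2.1·10⁻⁴·M^1.14·(12 − OM) + 3.25·(s − 2) + 2.5·(p − 3)]/100)·0.1317,
    M = (m_silt + m_vfs)·(100 − m_clay),   m_vfs = 0.2·m_sand

cover factor `C = 1 − EVI`, and the slope factor `S = 10.8·sin θ + 0.03`
below the 9 % breakpoint, `16.8·sin θ − 0.5` above it.  Sediment load is
E summed per subwatershed; stream velocity scales as
`V = V_m·s^0.5·A^0.5 / [s^0.5·A^0.5]_m`; deposition vulnerability is
normalized load × (1 − normalized velocity).

**Storage & filtering** — `SFC = OC + clay + (1 − pH) + CEC` on
depth-weighted soil-profile averages; low SFC flags soils that retain
pesticides poorly.

**Volatilization** — monthly score
`V_i = WV_i + Srad_i + T_i + PET + (1 − RH_i)`, reported as the annual
mean map and the across-month standard deviation (seasonality).

## Worked example

```python
from pestfate.sedimentation import textural_factor_M, erodibility_K, slope_factor_S

M = textural_factor_M(msilt=30, msand=40, mclay=20)   # → 3040
K = erodibility_K(M, OM=2, s_class=2, p_class=3)      # → 0.0258
S5 = slope_factor_S(5.0)                              # → 0.971
```

A soil with 30 % silt, 40 % sand and 20 % clay has textural factor
M = 3040; with 2 % organic matter, fine-granular structure (class 2) and
drainage class 3 its erodibility is K ≈ 0.0258 (t·ha·h)/(ha·MJ·mm); a 5°
hillslope multiplies erosion by S ≈ 0.971.

Running the whole chain on a seeded synthetic landscape
(`python examples/02_terrain_hydrology.py`) prints

```
valid cells: 16056
outlet cells: 40, accumulation at outlets: 16056 (must equal valid cells)
subwatersheds at threshold 50: 115
```

— D8 flow accumulation is exactly conservative and the watershed labels
partition the grid.  The other scripts in `examples/` walk through each
capability (leaching map, erosion/sedimentation, SFC and
volatilization, sensitivity analysis, residue funnel) and print what the
numbers mean.  The same chain is available as a CLI:

```bash
pestfate run-all --seed 1 --out out/        # all maps + tables + manifest
pestfate generate --seed 1 --out scenario/  # synthetic inputs as GeoTIFFs
pestfate residue-stats --db residues.csv --compound "pp'DDD" --substrates soil,sediment
```

## Layout

- `src/pestfate/grid.py` — raster data model, normalization, profile averaging
- `src/pestfate/terrain.py` — slope, pit filling, D8 flow, TWI, watersheds
- `src/pestfate/{leaching,runoff,sedimentation,storage_filtering,volatilization}.py` — the five process models
- `src/pestfate/sensitivity.py` — one-at-a-time perturbation analysis
- `src/pestfate/synthetic.py` — seeded generators for every input
- `src/pestfate/residues.py` — residue database load/validate/funnel
- `src/pestfate/pipeline.py`, `cli.py` — orchestration and the `pestfate` command
- `docs/methods.md` — modelling assumptions, parameters and numerical choices
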