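"""USLE erosion and the sedimentation-vulnerability index.

E = R·K·C·S (t/ha/yr) per pixel; sediment load is E summed per
watershed; stream velocity follows V = V_m·s^0.5·A^0.5/[s^0.5·A^0.5]_m;
deposition is favoured where the load is high and the velocity low.
"""

import numpy as np

from pestfate import ScenarioSpec, synth_scenario
from pestfate.pipeline import (RunConfig, process_raw_inputs, derive_terrain,
                               sedimentation_from_raw)
from pestfate.sedimentation import erodibility_K, slope_factor_S, textural_factor_M

# the nomograph worked through by hand for one soil
M = textural_factor_M(msilt=30, msand=40, mclay=20)
K = erodibility_K(M, OM=2, s_class=2, p_class=3)
print(f"textural factor M(silt 30 %, sand 40 %, clay 20 %) = {M:.0f}")
print(f"erodibility K(M, OM 2 %, fine granular, drainage class 3) = {K:.4f}")
print(f"slope factor S(5°) = {slope_factor_S(5.0):.3f}, "
      f"S(20 % slope) = {slope_factor_S(np.degrees(np.arctan(0.2))):.3f}")

spec = ScenarioSpec(shape=(64, 64), seed=1)
scn = synth_scenario(spec)
terr = derive_terrain(scn["dem"])
raw = process_raw_inputs(scn, terr, RunConfig())
index = sedimentation_from_raw(raw["sedimentation"])

loads = terr.watersheds.records["load_t_yr"]
print(f"\nper-watershed sediment load (t/yr): total {loads.sum():.0f}, "
      f"max {loads.max():.0f} over {len(loads)} watersheds")
vals = index.valid_values()
print(f"sedimentation index: mean {vals.mean():.3f}, max {vals.max():.3f}")
print("Pixels near 1 sit in heavily eroding catchments where stream flow "
      "slows down — the likeliest deposition zones for sediment-bound "
      "pesticides.")
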