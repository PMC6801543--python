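"""Build a synthetic scenario and map leaching vulnerability.

The leaching score is the DRASTIC-weighted overlay
L = 5·D + 5·(1−GW) + 2·(1−DB) + (1−SL) + 5·SM on normalized inputs,
then min–max normalized: 1 marks the pixels most vulnerable to
pesticide leaching toward groundwater, 0 the least.
"""

import numpy as np

from pestfate import ScenarioSpec, synth_scenario
from pestfate.pipeline import derive_terrain, leaching_from_raw
from pestfate.leaching import drainage_class_score

spec = ScenarioSpec(shape=(64, 64), seed=1)
scn = synth_scenario(spec)
terr = derive_terrain(scn["dem"])

lmap = leaching_from_raw({
    "drainage_score": drainage_class_score(scn["drainage_class"]),
    "groundwater_depth": scn["groundwater_depth"],
    "depth_to_bedrock": scn["depth_to_bedrock"],
    "slope": terr.slope_deg,
    "soil_moisture": scn["soil_moisture"],
})

vals = lmap.valid_values()
print(f"leaching vulnerability over {vals.size} pixels:")
print(f"  mean {vals.mean():.3f}, min {vals.min():.3f}, max {vals.max():.3f}")
print(f"  share of highly vulnerable pixels (>0.75): {(vals > 0.75).mean():.1%}")
print("High values combine permeable soil, a shallow water table and "
      "bedrock, flat terrain and moist soil.")
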