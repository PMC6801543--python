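"""Soil storage/filtering capacity and the volatilization seasonality.

SFC = OC + clay + (1−pH) + CEC on depth-averaged, normalized soil
profiles: low values flag soils that retain pesticides poorly.  The
monthly volatilization score V_i = WV + Srad + T + PET + (1−RH) is
summarized as an annual-mean map and the SD over the 12 months.
"""

import numpy as np

from pestfate import ScenarioSpec, synth_scenario
from pestfate.pipeline import sfc_from_raw, volatilization_from_raw

spec = ScenarioSpec(shape=(64, 64), seed=1)
scn = synth_scenario(spec)

sfc_map = sfc_from_raw({"oc": scn["oc_profile"], "clay": scn["clay_profile"],
                        "ph": scn["ph_profile"], "cec": scn["cec_profile"]})
vals = sfc_map.valid_values()
print(f"storage/filtering capacity: mean {vals.mean():.3f}; "
      f"{(vals < 0.25).mean():.1%} of pixels are low-retention (<0.25)")

mean_map, sd = volatilization_from_raw(
    {k: scn[k] for k in ("wind", "srad", "temp", "rh", "pet")})
print(f"volatilization annual mean map: mean {np.nanmean(mean_map.filled(np.nan)):.3f}")
print(f"monthly SD (seasonality, score units): "
      f"mean {np.nanmean(sd.filled(np.nan)):.3f}, "
      f"max {np.nanmax(sd.filled(np.nan)):.3f}")
print("Hot, windy, sunny, evaporative and dry pixels volatilize most; the "
      "SD map shows where that risk is concentrated in part of the year.")
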