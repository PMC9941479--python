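"""Compute WBGT for a single hot, humid, sunny afternoon observation.

Builds one meteorological state (35 degC air, 25 degC dew point, light
wind, strong radiant load), runs both WBGT approximations and prints the
components.
"""

from wbgtgrid import AirState, wbgt_acsm87_from_state, wbgt_brimicombe
from wbgtgrid.evaluation import CATEGORY_LABELS, categorize

state = AirState(
    ta=308.15,    # 35 degC air temperature
    td=298.15,    # 25 degC dew point -> humid
    va=1.0,       # light wind, m/s
    tmrt=328.15,  # 55 degC mean radiant temperature: full sun on the globe
)

brim = wbgt_brimicombe(state)
acsm = wbgt_acsm87_from_state(state)

print(f"wet-bulb temperature (Stull):  {float(brim.tw):6.2f} degC")
print(f"globe temperature (from MRT):  {float(brim.tg):6.2f} degC")
print(f"WBGT (radiant route):          {float(brim.wbgt):6.2f} degC")
print(f"WBGT (ACSM87 linear model):    {float(acsm.wbgt):6.2f} degC")

code = categorize(float(brim.wbgt))
print(f"heat-stress category:          {code} ({CATEGORY_LABELS[code]})")
print()
print("The radiant route sees the solar load through the globe temperature;")
print("the linear model only sees air temperature and humidity, which is why")
print("the two disagree most in strong sunshine.")
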