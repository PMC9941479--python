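"""Monthly heat-stress map from a synthetic hourly grid.

Generates a warm-humid synthetic month, computes the hourly WBGT stack,
aggregates to the monthly mean of daily maxima (the canonical heat-map
quantity), applies a coastal land-sea mask, and prints field summaries.
"""

import numpy as np

from wbgtgrid import (
    SyntheticConfig,
    apply_land_mask,
    categorize_field,
    compute_wbgt_grid,
    daily_max,
    generate_grid,
    monthly_mean_of_daily_max,
)

cfg = SyntheticConfig(seed=11, n_lat=8, n_lon=8, n_days=31,
                      land_fraction_pattern="coastal")
grid = generate_grid(cfg)

wbgt = compute_wbgt_grid(grid, method="brimicombe")
monthly = monthly_mean_of_daily_max(daily_max(wbgt["wbgt"]))
masked = apply_land_mask(monthly, grid["lsm"])
cats = categorize_field(masked)

print(f"hourly stack shape:          {wbgt['wbgt'].shape}  (time, lat, lon)")
print(f"monthly mean of daily max:   {float(monthly.min()):.1f} .. "
      f"{float(monthly.max()):.1f} degC")
print(f"sea cells masked:            {int(np.isnan(masked.values).sum())} of "
      f"{masked.size}")
finite = cats.values[np.isfinite(cats.values)]
for code in sorted(set(finite.astype(int))):
    print(f"  category {code}: {int((finite == code).sum())} land cells")
print()
print("Each land cell's value is the month-mean of its daily WBGT maxima;")
print("the categories map those values onto ISO work/rest recommendations.")
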