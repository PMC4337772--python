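"""Terrain operators and uplift proxies on an analytic DEM.

Builds a Gaussian-hill DEM, evaluates Horn slope/aspect and window-SD
rugosity at grid nodes, and computes the orographic uplift a 10 m/s wind
would generate on the windward flank, plus the convective (thermal) uplift
scale for a typical sunny boundary layer.
"""

import math

from envtrack import FieldSpec, make_field, orographic_uplift, thermal_uplift
from envtrack.derived import terrain_at_node

dem, _ = make_field(FieldSpec(
    form="dem_hill", params={"height": 800.0, "lon0": 0.5, "lat0": 0.5,
                             "sigma": 0.2},
    x=(0.0, 0.05, 21), y=(0.0, 0.05, 21), var_id="syn.dem"))

# a node on the western flank of the hill (upslope toward the east)
cell = terrain_at_node(dem, iy=10, ix=5)
print(f"western flank: slope {math.degrees(cell.slope):5.2f} deg, "
      f"aspect {cell.aspect:6.1f} deg (downslope azimuth), "
      f"rugosity {cell.rugosity:6.1f} m")

for u, label in [(10.0, "westerly (blowing east, upslope)"),
                 (-10.0, "easterly (blowing west, downslope)")]:
    w = orographic_uplift(u, 0.0, cell)
    print(f"orographic uplift, {label}: {w:+5.2f} m/s")

w_star = thermal_uplift(H=300.0, z_i=1000.0, T=288.0)
print(f"thermal uplift w* (H=300 W/m2, z_i=1000 m, T=288 K): {w_star:.2f} m/s")
print("\nPositive orographic uplift marks windward slopes (rising air that")
print("soaring birds exploit); w* is the convective velocity scale of a")
print("heated boundary layer.")
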