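"""Generate a synthetic study system with known truth.

Builds correlated climate surfaces plus elevation on a 30-arc-second grid,
a microclimate winter anomaly, the true cold-stress-frequency surface for a
species with CT_min 0.85 C, and a virtual species whose suitability is the
product of bell-shaped climate responses and a hard winter-survival
constraint.  Prints the realised structure so the generator's statistical
assumptions can be eyeballed.
"""

import numpy as np

import physiosdm as ps
from physiosdm.synthetic import make_microclimate

grid = ps.GridDef(west_lon=85.0, north_lat=32.0, n_rows=100, n_cols=100)
spec = ps.LandscapeSpec(n_climate_vars=4)
rasters = ps.make_landscape(spec, grid, seed=7)
climate, elevation = rasters[:-1], rasters[-1]

print(f"landscape: {len(climate)} climate surfaces + elevation "
      f"({elevation.values.min():.0f}-{elevation.values.max():.0f} m)")
r = np.corrcoef(climate[0].values.ravel(), elevation.values.ravel())[0, 1]
print(f"clim1 vs elevation correlation: {r:+.2f} "
      "(temperature-like surface tracks altitude, imperfectly)")

anomaly = make_microclimate(grid, sd_C=3.0, seed=8)
window = ps.OverwinterWindow(2019)
stress = ps.true_stress_frequency(elevation, ps.TempParams(), 0.85, window,
                                  anomaly=anomaly)
print(f"true cold-stress frequency: {stress.values.min():.0f}-"
      f"{stress.values.max():.0f} days of the {window.n_days}-day winter")

niche = ps.NicheSpec({"clim1": (0.5, 0.5), "clim2": (0.0, 0.6)},
                     cold_tolerance_days=110.0, ctmin=0.85)
truth = ps.make_virtual_species(climate, stress, niche)
survivable = truth.winter_survival.values.mean()
print(f"survivable fraction of the landscape: {survivable:.0%} "
      "(cells with at most 110 stress days)")

occ = ps.sample_occurrences(truth, 2000, seed=9, species_id="virtual_A")
surv_at_points = truth.winter_survival.sample(*occ.coords())
print(f"sampled {len(occ)} occurrences; "
      f"{int((surv_at_points == 0).sum())} fall in winter-lethal cells "
      "(must be 0: the constraint is absolute)")
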