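"""Compute the overwintering cold-stress statistic for one station.

Builds a 3-hourly, multi-depth soil-temperature series for a single
high-plateau station, depth-averages it over the 10-40 cm nest band, clips
it to the 1 November - 31 March hibernation window, and counts cold-stress
events (3-h intervals below CT_min) and cold-stress days.  Also pools the
published-style CT_min summaries of two sampled populations.
"""

import numpy as np

import physiosdm as ps
from physiosdm.synthetic import TempParams, make_soil_temp_stations

# one station at 4150 m on a single-cell grid
grid = ps.GridDef(west_lon=85.0, north_lat=32.0, n_rows=1, n_cols=1, cell_size=0.1)
elevation = ps.Raster(grid, [[4150.0]], "elevation")
params = TempParams(noise_sd_C=0.5)
(station,) = make_soil_temp_stations(elevation, 1, params, seed=4)

window = ps.OverwinterWindow(2019)  # 1 Nov 2019 .. 31 Mar 2020 (leap spring)
kept = ps.drop_incomplete_stations([station], window)
print(f"stations kept after completeness screen: {len(kept)}/1")

profile = ps.depth_average(kept[0], (10.0, 40.0))
profile = ps.clip_window(profile, window)
print(f"window covers {window.n_days} days = {window.n_intervals} 3-h intervals")

ctmin = 0.85  # deg C, the lower-tolerance species
res = ps.count_stress(profile, ctmin, window)
print(f"CT_min {ctmin} C -> {res.n_events} cold-stress events on "
      f"{res.n_stress_days} stress days")
print("  (a stress day is a calendar day with at least one 3-h interval "
      "whose 10-40 cm mean soil temperature fell below CT_min)")

# pooled CT_min across two sampled populations, as a physiologist would
# summarise assay results
pops = [
    ps.PopulationCTmin("Gar", 12, 0.9, 0.5, 1.2, sd=0.2),
    ps.PopulationCTmin("Zhongba", 12, 0.8, 0.6, 1.0, sd=0.1),
]
summary = ps.pool_ctmin(pops)
print(f"pooled CT_min: {summary.pooled_value:.2f} C "
      f"(overall range {summary.overall_range:.1f} C across individuals)")
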