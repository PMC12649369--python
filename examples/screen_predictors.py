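"""Collinearity screening of a predictor stack.

Generates a landscape in which two climate surfaces are strongly correlated
(rho 0.9), labels cells from a known gradient, scores each variable by
cross-validated single-variable AUC, and lets the screen drop the weaker
member of each collinear pair.
"""

import numpy as np

import physiosdm as ps

grid = ps.GridDef(west_lon=85.0, north_lat=32.0, n_rows=80, n_cols=80)
corr = np.eye(4)
corr[2, 3] = corr[3, 2] = 0.9  # clim3 and clim4 nearly duplicate each other
spec = ps.LandscapeSpec(n_climate_vars=4, cross_correlation=corr,
                        temp_elevation_corr=0.0)
stack = ps.make_landscape(spec, grid, seed=1)[:-1]  # climate only

# a species that responds to clim1 and (weakly) clim3
niche = ps.NicheSpec({"clim1": (0.5, 0.5), "clim3": (0.0, 0.8)},
                     cold_tolerance_days=np.inf, ctmin=0.85)
stress = ps.Raster(grid, np.zeros(grid.shape), "stress")
truth = ps.make_virtual_species(stack, stress, niche)
occ = ps.sample_occurrences(truth, 800, seed=2)
occ = ps.thin_to_grid(occ, grid)
pa = ps.draw_pseudo_absences(grid, occ, n_sets=2, n_per_set=100, seed=3)

rho = ps.spearman_matrix(stack, sample_cells=4000, seed=4)
scores = ps.univariate_contribution(
    stack, occ.coords(),
    (np.concatenate([p.lon for p in pa]), np.concatenate([p.lat for p in pa])),
    seed=5,
)
report = ps.collinearity_filter(rho, scores, [r.name for r in stack])

print("pairwise Spearman rho (sampled cells):")
for i, a in enumerate(report.names):
    for j in range(i + 1, len(report.names)):
        print(f"  {a} ~ {report.names[j]}: {rho[i, j]:+.2f}")
print("single-variable CV-AUC contribution scores:")
for name, s in scores.items():
    print(f"  {name}: {s:.3f}")
print(f"kept: {report.kept}")
for dropped, kept, r in report.dropped:
    print(f"dropped {dropped} (|rho|={abs(r):.2f} with {kept}, lower score)")
print("no kept pair reaches |rho| >= 0.8, so the model stack is free of "
      "strong collinearity")
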