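# Methods

`physiosdm` implements a physiology-informed species distribution
modelling (SDM) workflow for ectotherms whose ranges are limited by
overwinter cold. The pipeline has six stages: occurrence thinning, the
cold-stress predictor, collinearity screening, ensemble model fitting,
habitat binarisation and comparison, and a synthetic world that supplies
every input with known truth. This note records the model choices, the
defaults and why they were made, and what the synthetic validation does and
does not demonstrate.

## The cold-stress statistic

The physiological predictor is an event–day statistic on 3-hourly,
multi-depth soil temperature series:

- **event** — a 3-h interval whose mean soil temperature over the nest
  depth band (default 10–40 cm, unweighted mean of the depths inside the
  band) falls *strictly below* the species' critical thermal minimum
  CT_min. "Fell below" is read as a strict inequality, so a series sitting
  exactly at CT_min produces no events; the comparison is configurable.
- **stress day** — a calendar day (naive UTC) containing at least one
  event.
- **cold-stress frequency** — the number of stress days in the
  overwintering window, 00:00 on 1 November through the 3-h interval
  beginning 21:00 on 31 March (timestamps mark interval starts, so "through
  23:00" means through the last interval of 31 March). The window spans 151
  days, or 152 when the spring falls in a leap year.

Two window policies exist because observational archives are often cut by
calendar year: `spanning` (default; Nov of year *y* to Mar of *y*+1 — one
physical winter) and `single_year` (Nov–Dec and Jan–Mar of the same
calendar year — the composite a one-year archive forces). The policy is
recorded in results.

Stations missing *any* in-window reading at a required depth are dropped
rather than gap-filled: an imputed interval could silently create or
destroy an event, and the statistic is a count of threshold crossings, not
a mean. The depth band question (archives sometimes describe acquisition
over 1–40 cm while nest biology argues for 10–40 cm) is left to a
configurable `depth_range`, defaulting to 10–40 cm.

Station frequencies reach the 30-arc-second modelling grid by
inverse-distance weighting over the `k = 4` nearest stations with power 2
(nearest-neighbour mode via `k = 1`); a cell co-located with a station
reproduces the station value exactly, and every interpolated value lies
inside the station value range (convexity). Distances are Euclidean in
degrees, adequate at the regional extents the statistic targets. IDW was
chosen because nothing in the data constrains a more elaborate
geostatistical model; it is monotone, exact at stations and parameter-poor.

CT_min summaries pool across populations by sample-size-weighted mean; the
overall range is the global max minus global min across individuals.

## Occurrence thinning

One presence per species per grid cell. Cells are half-open with row =
floor((north − lat)/cell), col = floor((lon − west)/cell); points exactly
on the southern/eastern outer boundary clamp into the last row/column so
the extent is covered totally. Within a (species, cell) group the retained
record is the first in input order after a stable sort by (species, source,
row index) — deterministic and idempotent. Thinning is per species: pooled
thinning would let one species' records delete another's.

## Collinearity screening

Pairwise Spearman rho over a common random sample of valid cells (default
2000). A pair with |rho| ≥ 0.8 (inclusive) loses its lower-contribution
member; elimination is greedy, highest |rho| first, until no kept pair
reaches the threshold. The contribution proxy is the cross-validated rank
AUC of a single-variable logistic model with linear + quadratic terms
(5-fold, stratified): label-aware, cheap, and able to credit unimodal
responses that a linear score would miss. Constant variables have
undefined rank correlations; they are set to 0 with a warning so they can
never trigger an elimination. Score ties drop the later variable in the
stable input ordering.

## Ensemble modelling

The design follows the standard ensemble-platform recipe:

- 10 sets of 100 random pseudo-absence points by default, each set drawn
  from cells containing no presence of the modelled species, one point per
  cell, placed uniformly inside its cell;
- 80/20 stratified calibration/evaluation splits, repeated over 10
  cross-validation repetitions by default;
- a pluggable learner registry shipping four families: logistic regression
  with linear + quadratic terms (the classical GLM formulation for
  bell-shaped niches), a depth-6 recursive-partitioning tree, a 100-tree
  bagged ensemble (random forest) and gradient-boosted trees. Further
  families (GAM/MARS/MaxEnt analogues) can be registered; the retention and
  ensembling logic is learner-agnostic;
- evaluation on the held-out 20% only, by rank AUC, max-TSS and max-kappa.
  TSS and kappa are maximised over a fixed grid of 101 thresholds
  0.00–1.00 (the reproducible convention of ensemble platforms), reporting
  the smallest maximising threshold on ties;
- retention iff TSS ≥ 0.8 **and** AUC ≥ 0.7 **and** kappa ≥ 0.6, all
  inclusive;
- the ensemble is the TSS-weighted mean of retained member predictions
  (equal weights available), a convex combination bounded by the member
  range cellwise. Ensemble metrics are recomputed by scoring the ensemble
  at every member's held-out points and pooling.

Each (learner, pseudo-absence set, repetition) run receives an independent
seed derived from the master seed and its coordinates, so results are
reproducible and order-independent. Run counting obeys
`n_runs = n_learners × n_pa_sets × n_cv_reps` for any configuration.

Variable contributions are permutation-based: raw importance of a variable
is 1 − cor(prediction, prediction with that variable's column permuted),
averaged over permutations and normalised to percentages. Response curves
use the evaluation-strip convention: sweep one variable over its observed
range with all others fixed at presence-cell means.

## Habitat comparison

"High suitability" is binarised at the ensemble's max-TSS threshold (a
fixed-quantile alternative is a one-liner on top of `binarize`). Areas are
summed in km² with the spherical band formula `R² Δλ (sin φ_top − sin
φ_bot)`, R = 6371.0088 km, at each cell's centre latitude; summing a full
0.5° globe reproduces 4πR² to better than 0.1%. Overlap is the area of the
elementwise AND. Two percentage summaries are defined exactly as their
published usage requires: the overlap ratio is 100 × overlap_physio /
overlap_traditional (2 decimals), and the area difference is 100 ×
(area_traditional − area_physio) / area_physio (1 decimal) — the
physiology-informed area is the denominator, the only reading under which
the published area pair reproduces the published percentage. The
difference map classifies cells as reduction (suitable only without the
constraint), expansion (suitable only with it), or unchanged.

## The synthetic world

The generator supplies inputs with the statistical structure the analysis
assumes, plus a known truth:

- **Climate surfaces** are Gaussian-smoothed white noise (correlation
  length 8 cells by default), standardised, then mixed to a target
  cross-correlation matrix via its symmetric square root. The first
  surface is temperature-like: it is re-mixed to correlate with elevation
  at −0.85, because real bioclimatic temperature summaries are strong but
  imperfect altitude proxies. This has two consequences the workflow
  depends on: the collinearity screen drops raw elevation (as happens with
  real predictor stacks), and the climate-only model retains only a blurry
  proxy of the winter-survival axis.
- **Elevation** runs 3000–5000 m north-to-south with 150 m of smooth
  relief — a high-plateau margin.
- **Soil temperature** at a station is annual mean 8 °C at the 4000 m
  reference, lapse 6.5 °C/km, annual amplitude 8 °C with the minimum on 15
  January, diurnal amplitude 4 °C at the shallowest depth damped by ×0.6
  per successive depth (depths 10/20/40 cm), Gaussian noise sd 1 °C per
  reading. These are plausible magnitudes for 10–40 cm soil under a
  continental alpine climate, where depth strongly damps the diurnal and
  (partly) the annual cycle.
- **Microclimate anomaly**: a smooth random field (sd 3 °C, same
  correlation length) shifts each cell's winter series rigidly,
  representing snow-cover insulation, exposure and drainage. It is
  statistically independent of every predictor, so the true survival
  boundary is *not* a deterministic function of anything a climate-only
  model can see. This is the load-bearing design choice: without it the
  winter constraint is a function of elevation alone, any flexible learner
  reconstructs it from the elevation proxy, and the two model variants
  converge — there is then no overestimation for the physiological
  predictor to remove, contradicting the premise the workflow exists to
  test. Stations measure the anomaly at their locations, so the
  interpolated cold-stress raster carries (noisy, undersampled) information
  about it that the climate stack cannot.
- **Virtual species**: climate suitability is a product of Gaussian bells
  (the standard virtual-species response), rescaled to max 1; winter
  survival is the hard constraint `stress_days ≤ tolerance`; truth is
  their product. The default species pair are plateau specialists with
  narrow niches (breadths 0.5–0.6 sd) and contrasting cold physiology
  (CT_min 0.85 °C with tolerance 110 days; CT_min −1.58 °C), so the
  survival boundary crosses the upper tail of each climate niche and the
  constraint is active without dominating. Occurrences are drawn with cell
  probability proportional to true suitability and placed uniformly within
  their cell; winter-lethal cells can never receive a presence.

With these conditions the per-run metric distribution (AUC ~0.8–0.97, TSS
mostly 0.6–0.9) and the retained fraction of runs sit in the range typical
of real ensemble SDM studies, which is what makes the fixed retention
thresholds meaningful rather than vacuous.

What the synthetic validation shows: the full pipeline, run end-to-end at
study scale (100 × 100 cells, ~2000 occurrences thinned to ~1400, two
learner families, 5 pseudo-absence sets × 4–5 repetitions), recovers the
qualitative headline — averaged over landscape realisations, the
climate-only ensemble claims more high-suitability area and flags more
winter-lethal ground as suitable than the physiology-informed ensemble.
What it does not show: realistic climate field anisotropy or orographic
structure, observation bias in occurrences, soil heat-flux physics, or the
magnitudes of any published area — those depend on unpublished coordinates
and external rasters and are outside what a synthetic study can certify.

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds; derived seeds come
  from `SeedSequence((master, *coordinates))`, keeping runs
  order-independent and below 2³¹.
- The 101-point threshold grid makes TSS/kappa maximisation exact and
  platform-independent; argmax returns the smallest maximising threshold.
- AUC uses average ranks, so ties count one half exactly.
- Degenerate inputs fail loudly: single-class evaluation sets, zero
  retained models, all-zero suitability, zero stations, points outside the
  grid extent, non-PSD correlation targets.
- Nodata cells propagate; they are never silently filled.
- Problem sizes in the test suite are chosen so the whole suite (including
  the five-realisation end-to-end comparison) completes in a few minutes
  on one CPU; unit tests use 10–80-cell grids, the end-to-end checks use
  the full 100 × 100 default.

## Known limitations

- The IDW bridge from ~0.5°-spaced stations to a 1-km grid undersamples
  microclimate; the physiology-informed variant is therefore better, not
  perfect, at excluding lethal ground (visible in its nonzero lethal
  false-positive rate).
- The contribution proxy used for screening is univariate; a variable
  informative only in interaction can be screened out.
- Pseudo-absences are treated as true absences during fitting and
  evaluation, the standard presence/pseudo-absence simplification;
  prevalence weighting is off by default.
- `single_year` windows splice two different winters and are provided only
  because some archives force them.
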