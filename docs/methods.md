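# Methods

This note documents the models implemented in `khulan`, the choices made
where the methodology was genuinely open, and what the synthetic data can
and cannot establish.

## Data model

A trajectory is a time-ordered sequence of fixes (animal id, tz-aware
timestamp, planar x/y in metres) at a nominal 1-h cadence inside an
analysis window (default 50 days). Timestamps within ±5 min of a whole
hour are snapped to it (GPS scheduling jitter); the tolerance is
configurable. Gaps are recorded, never interpolated: each downstream
module decides its own gap semantics (below). Duplicate (id, timestamp)
pairs are rejected rather than averaged so that visit counting stays
well-defined. Geographic (lon/lat) coordinates are rejected at ingest —
every statistic in the package is a metric distance, so projection is the
caller's responsibility.

## Displacement

Each valid 1-h step (duration within tolerance of the cadence) is assigned
to the hour bin of its **start** fix; binning by end fix is available. Gap
steps are excluded from hourly statistics. Per-hour SE is sample SD/√n.
All cross-animal summaries are two-stage: per-individual means first, then
mean ± SE of those means — individuals, not fixes, are the replicates.
The activity–distance relation is a Spearman rank correlation with
average ranks on ties. Mixed-model inference on hour/season effects is
out of scope; profiles are exported as tidy CSV for external tools.

## Utilization distribution and home ranges

The UD is a movement-based kernel: every step with duration ≤ T_max
(default 2.5 h) and length ≥ L_min (50 m) is densified by interpolating
points every τ = 0.1 h along the straight segment; an isotropic Gaussian
kernel of bandwidth h_min = 100 m is centred at every observed and
interpolated point; the sum is normalized to integrate to 1 on the grid.
This keeps the serial correlation between successive fixes that motivates
movement-based estimators while deliberately **not** reproducing the
time-dependent bandwidth of the full movement-based kernel family: the
variance-growth parameter `b` is retained in `UDParams` for provenance but
unused (with b = 0 the two coincide in spirit), and a full implementation
is a documented extension point. Steps longer than T_max contribute
endpoint kernels only — T_max acts as a bridging cutoff across gaps.

Numerically, points are deposited with bilinear weights and convolved
with a Gaussian (σ = h_min); mass smoothed past the grid border is folded
back by the final normalization. The x% home range is the smallest cell
set holding x% of the mass, built by descending-density inclusion with
ties broken in row-major order (deterministic); 50% ⊆ 95% by
construction.

## Habitat selection

Five variables: thalweg (binary, cell centre within a 25-m buffer of the
drainage network — closed boundary), NDVI, elevation, slope, and northern
exposure E_N = sin θ cos α, the projection of the terrain unit normal on
the south–north axis. Slope and aspect come from Horn 3×3 finite
differences (edge cells use replicated margins); flat cells get aspect 0
and a flag.

Availability is sampled at the nodes of a 30-m square lattice anchored at
the minimum corner of the home-range bounding box (the anchor slightly
affects availability; it is documented and fixed for reproducibility).
Use is the habitat at the animal's in-range fixes, grouped by clock hour.
SC uses the sample (n−1) SD of the availability values (the denominator
convention is configurable). A zero availability SD yields an undefined
SC marker (NaN) that propagates as missing — never as 0 — and
cross-animal averages skip it with a logged count.

## Water-point visits

The visit circle of a water point is derived from local travel speed:
passing series are maximal runs of ≥3 consecutive fixes whose interior
fixes pass strictly within 50 m of the point; the mean 1-h step length
over all series, halved and **rounded up to the nearest 10 m**, is the
visit radius. This rounding rule is the one consistent with all three
derived radii of the source data (879→440, 408→210, 1633→820 m) and can
be overridden per point. A visit is a maximal run of consecutive fixes
inside the closed visit circle, timed at the closest fix (earliest on
ties). A cadence gap flanked by in-radius fixes does not split a visit —
the animal plausibly stayed — with a strict-splitting option.

## Residence and recursion

For each focal fix, a circle of 200 m (matching the scale between the
median and mean hourly displacement of the study system) is centred on
it and every fix is classified in/out. Residence time is the span of the
maximal in-circle run containing the focal fix, counted in cadence hours
(a 3-fix run = 3 h); recursion time is the number of hours spent outside
before the next entry, right-censored at the window end; the number of
visits counts the maximal in-circle runs over the window. Unobserved
hours bridge a run only when flanked by in-circle fixes (mirroring the
visit rule; strict mode available).

Censored durations enter only the Kaplan–Meier analysis (lifelines'
product-limit estimator); the median is the smallest time with survival
≤ 0.5, undefined if never reached. The pooled histogram used for the
periodicity fit contains the uncensored first-recursion durations of all
fixes (one duration per focal fix — the first return after the focal
run); pooling all inter-visit gaps instead is available behind an option.

### Periodicity scan

Counts of durations per integer hour t ∈ [1, 168] (zero bins included;
the 168-h cap matches the analysis range of the recursion-time
distribution and is configurable) are fit by Poisson GLM (log link,
statsmodels IRLS) under five nested forms: M1 (linear trend), M2
(log-time), M3 (both), and the periodic M4-k / M5-k adding
α₃·cos(2π(t+k)/24) or α₃·log(cos(2π(t+k)/24)+2), scanned over integer
k = 0…23. The phase is a scanned constant, not an estimated parameter, so
M4/M5 carry 4 df; AIC = 2·df − 2·logL; ties break toward fewer df, then
smaller k. Because cos(2π(t+k+12)/24) = −cos(2π(t+k)/24), M4-k and
M4-(k+12) are the same model with the amplitude sign flipped; fits are
canonicalized to α₃ ≥ 0 so that the reported phase always marks the rate
maxima (peaks every 24 h minus k hours). Non-converged fits are excluded
from ranking with a warning.

### Visits vs home-range size

If within-range use were uniform, the mean number of visits per location
ñ would be inversely proportional to range size A; on log scales, a slope
of −1. The model family R1–R8 crosses season-specific vs common
intercepts and slopes with a fixed −log A offset (the inverse law) and
includes intercept-only nulls. Models are Gaussian random-intercept
(per-animal) regressions of log ñ, fit by direct maximum likelihood
(fixed effects profiled by GLS; the two variance components optimized by
Nelder–Mead on the log scale) and ranked by AICc with
p = fixed coefficients + 2 variance components. The direct-ML routine
exists because the offset models constrain a coefficient to −1, which is
expressed by shifting log A into the response; statsmodels MixedLM (ML)
serves as an independent cross-check in the tests, not as the
implementation. Degenerate (zero-variance) data are handled by flooring
the variance components at 1e−8.

## Main recursion sites

Per animal-season, the top 20% of locations by visit count are selected;
ties at the cutoff are included (slightly inflating the selection —
deterministic and conservative). Two selected locations are linked when
their 200-m circles overlap (centre distance ≤ 400 m, closed at
tangency); connected components with ≥ 15 members are main recursion
sites. Sites common to several animals are found by a second clustering
pass over the union of all animals' selections (union-then-cluster; the
alternative — spatial overlap of per-animal sites — is a documented
variant), and per-animal sites wholly absorbed by a common site are
reported once. Each site is characterized by per-variable means and SDs
over member locations (thalweg as a proportion), a 24-bin histogram of
member fix hours, and flags marking variables whose site mean exceeds the
animal's 95%-home-range mean. Output order is canonical (size descending,
then centroid), so clustering is permutation-invariant.

## Synthetic data

The generator's defaults are the study conditions: five individuals,
50-day windows at 1-h cadence with a small (2%) fix-loss rate in the
seasonal presets, a 30-m shared raster grid (one grid for all layers
avoids resampling semantics), and near-daily steered evening water trips
in summer (daily Bernoulli probability 1.0 in summer, 0.08 in winter;
steering hours 19:00–23:00, matching a dusk visitation peak).

Elevation is smoothed Gaussian noise rescaled to 600–1000 m; streams are
steepest-descent traces from high ground; the thalweg mask is the 25-m
buffer of that network; NDVI is a base level (0.10 summer, 0.13 winter)
plus an in-thalweg contrast (0.08 summer, 0.03 winter — summer vegetation
concentrates along streambeds, winter vegetation is more uniform) plus
smooth noise. Water points sit on the network, preferentially near the
landscape centre so that ranges can contract around them.

Trajectories are biased correlated random walks: 24 candidate headings
per hour (wrapped-normal turns, gamma step lengths with a diel
multiplier — crepuscular peaks, long night moves, short midday resting
steps), chosen by softmax over the hour's habitat score (z-scored
elevation and NDVI, binary thalweg) plus a soft territorial pull. The
candidate-set softmax bounds runtime compared with continuous rejection
sampling. The attraction schedule defaults to elevation by day
(08–16 h) and NDVI + thalweg by night (20–04 h), strong enough to
reproduce the qualitative diel selection signature. All randomness flows
from one seed through named substreams (landscape, per-animal walk, water
days, fix loss), so every stage is independently regenerable and runs are
deterministic per seed.

What the generator does **not** emulate: GPS positional error, group
dynamics and multi-animal interaction, energetics, seasonal terrain
change, and any behavioural feedback between recursion and resource
renewal. Passing tests therefore establish the correctness and internal
consistency of the estimators on data with the assumed structure — not
that real telemetry satisfies that structure.

## Numerical and scale choices

- Problem sizes in tests and examples are scaled for quick runs (grids of
  100–150 cells squared, 2–3 animals, 10–50 day windows); the estimators
  are O(n²) in fixes only in `recursion_table` (a 1,200-fix season takes
  well under a second).
- Poisson GLM convergence: IRLS with tol 1e−10, 200 iterations max;
  duration sampling guards against rate overflow and names the offending
  hour.
- The isopleth tie-break, cluster ordering, KM median rule and AIC
  tie-breaks are all deterministic; two runs with one seed produce
  byte-identical CSVs.
- Raster semantics: row 0 is the southernmost row in memory; ASCII-grid
  files store north-up and are flipped on I/O. The outer grid boundary is
  closed for point sampling (a point exactly on the maximum edge belongs
  to the border cell).

## Known limitations

- The simplified movement kernel underestimates UD spread along fast
  steps relative to the time-dependent-bandwidth estimator; isopleth
  areas are therefore comparable within this package but not directly
  against published areas from other estimators.
- The visit-radius rounding rule is inferred from three printed pairs; it
  is exposed as a plain function and overridable per water point.
- With hourly fixes, residence/recursion times are integer hours;
  sub-hour revisits are invisible by construction.
- Detection of *unknown* attraction points (how one discovers an unmapped
  water source from trajectory convergence) is not implemented; water
  points must be supplied or generated.
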