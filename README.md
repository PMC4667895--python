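# khulan

Space-use analysis of hourly GPS telemetry for large herbivores in
heterogeneous (arid) landscapes — built around the movement ecology of the
Asiatic wild ass (*Equus hemionus*, "khulan"), a water-dependent desert
equid tracked at a 1-h fix cadence over 50-day seasonal windows.

The package combines three complementary views of how an animal uses its
landscape, for movement ecologists who have a relocation table and a few
GIS layers:

- **Displacement** — mean distance travelled per hour of day
  (per-individual profiles, two-stage cross-animal summaries, Spearman
  correlation with scan-sampling activity data).
- **Habitat selection** — movement-kernel utilization distributions,
  95%/50% isopleth home ranges, and the hourly selection coefficient

  ```
  SC = (mean at used locations − mean at availability nodes) / SD at nodes
  ```

  for five habitat variables: thalweg (25-m streambed buffer), NDVI,
  elevation, slope, and northern exposure `E_N = sin θ · cos α` (θ slope,
  α aspect clockwise from north; −1 south-facing vertical, +1 north-facing
  vertical).
- **Recursion movement** — for every fix, the residence time inside a
  200-m circle, the (right-censored) recursion time until return, and the
  number of visits over the window; Kaplan–Meier median recursion times; a
  Poisson-GLM family scanned over an integer phase k

  ```
  log λ(t) = α0 + α1 t + α2 log t  [+ α3 cos(2π(t+k)/24)  or
                                    + α3 log(cos(2π(t+k)/24) + 2)]
  ```

  ranked by AIC to detect 24-h periodicity in recursion times (a best
  phase k means rate maxima every 24 h minus k hours); Gaussian
  random-intercept models of log ñ (mean visits per location) against log
  home-range size ranked by AICc, including fixed −log A offset models for
  the inverse-proportionality hypothesis; and clustering of the
  most-revisited locations into characterized "main recursion sites".

Because telemetry like this is rarely shareable, a first-class synthetic
module generates landscapes (elevation, slope/aspect, NDVI, thalwegs,
water points) and biased-correlated-random-walk trajectories with the
diel structure the analyses assume — high ground by day, vegetated
thalwegs by night, steered evening water trips — so the entire pipeline is
testable and demonstrable offline.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/05_recursion_periodicity.py` simulates three animals for
50 days and prints:

```
A1: n-tilde (mean visits/location) 9.8; mean residence 2.7 h; median recursion 122 h (20% censored)
A2: n-tilde (mean visits/location) 10.0; mean residence 2.6 h; median recursion 120 h (20% censored)
A3: n-tilde (mean visits/location) 10.6; mean residence 2.8 h; median recursion 131 h (20% censored)

model  df    AIC   (best k)
M1      2   1439.4   -
M2      2   1538.3   -
M3      3   1436.3   -
M4      4   1106.1   3
M5      4   1079.9   15

best model: M5-15 -> recursion-time peaks every 24 h minus 15 h,
i.e. the animals return to the same places at about the same time of day.
```

Residence times of ~3 h, a large censored fraction handled by
Kaplan–Meier, and a decisive AIC gap between the aperiodic models
(M1–M3) and the 24-h periodic ones (M4-k/M5-k) — the signature of daily
revisitation. `examples/03_habitat_selection.py` prints the hourly SC
table showing elevation selected at midday (SC ≈ +1.1 at 12:00) and
NDVI/thalwegs at night (SC ≈ +3 and +6 at 22:00); `examples/06_full_pipeline.py`
runs both seasons end to end and prints a per-animal summary.

A thin CLI wraps the pipeline:

```bash
khulan run --seed 1 --outdir run1           # synthetic two-season run
khulan summarize run1
khulan run --mode files --fix-table fixes.csv --landscape-dir gis/ \
       --window-start 2013-08-12T00:00:00+00:00 --outdir run2
```

## Layout

```
src/khulan/
  trajectory.py    fix tables, analysis windows, steps, diel binning
  raster.py        planar grid + ASCII-grid I/O
  synthetic.py     landscape and trajectory generator, duration sampler
  displacement.py  hourly distance profiles, activity correlation
  homerange.py     movement-kernel UD, isopleths, SC machinery
  water.py         passing series, visit radius rule, visit detection
  recursion.py     recursion records, Kaplan-Meier, model families
  sites.py         top-visited selection, clustering, characterization
  pipeline.py      end-to-end orchestration and manifests
  cli.py           khulan simulate | run | summarize
docs/methods.md    model and design notes
examples/          one narrative script per capability
```
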