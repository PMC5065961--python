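# plumetrace

Could a displaced migratory bird find its way back to its population's
migratory corridor by following wind-borne odors? `plumetrace` is an analysis
pipeline for testing that *plume-following* (chemotaxis) hypothesis with a
particle dispersion model: for every position along a bird's GPS track it
reconstructs, backward in time, where the air arriving at the bird came from,
and then asks three questions the hypothesis hinges on:

1. **Persistence** — is the spatial pattern of potential odor sources stable
   long enough to be followed? (a time-lag *correlogram* of the modeled
   source fields)
2. **Exposure** — how much modeled plume material would each bird have
   "collected" along its journey, and do birds that can smell collect less
   than anosmic birds? (the per-bird *accumulation score* with a Wilcoxon
   rank-sum comparison)
3. **Reorientation** — after air from the corridor reaches a bird, does it
   turn toward where that air came from? (corridor-exposure classification,
   plume-arrival bearings, before/after turn analysis, V test, paired
   Hotelling test, chi-square contingency test, and the regression of turn
   magnitude on the plume-relative arrival angle)

The pipeline is exercised end-to-end on synthetic data: a seeded smooth wind
field, a corridor/goal geometry, and agent tracks that either do (smell-intact
"ION" group) or do not (anosmic "ONS" group) reorient when plume information
reaches them. The package is aimed at movement ecologists who want a
transparent, fully testable desk-scale implementation of this analysis chain.

## The model

**Backward dispersion.** A receptor is a bird location `(λ, φ)` at time `t`
with a 5-minute reception window in the 0–30 m air layer. `N` massless tracer
particles are released there and stepped *backward* with step `Δt`:

    x_{k+1} = x_k − u(x_k, t_k) Δt + ξ,   ξ ~ N(0, 2 K_h Δt)  per horizontal axis

(vertically `K_z` with reflection at the ground), up to a maximum age of
3 days. Binning each particle-step's position on a 0.2° output grid and
multiplying by a spatially uniform emission rate `q` gives the
source-contribution raster `S(cell) = q · (residence time in cell)` — the
source–receptor-sensitivity reading of a backward run: how strongly each cell
could have contributed material to the air the bird met. Altitude layers
(tops at 100 / 3,000 / 50,000 m) are accumulated separately and summed.

**Statistics.**
- correlogram: Pearson correlation over raster cells for up to 50 random
  pairs of a bird's rasters at each lag 1–48 h, averaged per bird, then mean
  ± sd across birds;
- accumulation score: for each hourly raster at time `t`, the raster sampled
  at the bird's *later* positions that pass a 2 m/s activity filter, summed
  over rasters and divided by the bird's number of locations;
- exposure: fraction of raster mass inside the corridor polygon ≥ 0.05;
- plume bearing: circular mean, over particles, of the bearing from the
  receptor to each particle's position when it was last ≥ 30 km away on its
  approach;
- turns: endpoint bearings of 500 km before / 200 km after path windows
  around the first exposure, `Δ = wrap(after − before)`;
  V test `V = n·r·cos(ᾱ − μ₀)`, paired Hotelling `F = (n−2)/(2(n−1))·T²`
  on unit-vector differences, Pearson chi-square on the group × reoriented
  table, and OLS of `Δ` on the plume-relative arrival angle.

## Worked example

```sh
plumetrace demo --seed 1 --out results/demo --particles 200
```

generates the reference scenario (20 agents, 10 per group), runs the full
pipeline, writes tables plus a summary, and prints:

```
tracks: 20  hourly particle clouds: 1400
correlogram grand mean r: lag 1 h = 0.555, lag 24 h = -0.001
accumulation score medians: ION = 1.39e+04, ONS = 9.37e+04; Wilcoxon U = 0.0, p = 1.08e-05
reoriented fraction: ION = 1.00, ONS = 0.00
contingency X2 = 20.00 (df = 1), p = 7.74e-06
V test vs plume direction: n = 10, r = 1.00, mean = 31 deg, u = 3.83, p = 6.43e-05
paired Hotelling: F = 12843.6, p = 9.4e-15
turn ~ plume-relative angle: slope = 0.90, r = 0.96, p = 1.28e-05
```

Reading this: the modeled odor field decorrelates within a day (lag-24
correlation ≈ 0); every smell-intact agent is classified as having reoriented
after corridor-plume exposure and no anosmic agent is (chi-square rejects
independence); reoriented agents end up flying essentially along the
plume-arrival direction (V test), their before/after bearings differ strongly
(paired Hotelling), the turn magnitude grows ~1:1 with the angle at which the
plume information arrived, and smell-intact agents accumulate *less* plume
material per location than anosmic ones — the full qualitative signature the
plume-following hypothesis predicts.

The same analysis can be driven step by step with the numbered scripts in
`analysis/` (01 scenario generation → 02 dispersion + tables → 03/04/05
correlogram, accumulation and reorientation statistics with figures), or from
the library API (`plumetrace.pipeline.run_pipeline`) on your own wind NetCDF,
track CSVs and region GeoJSON.

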