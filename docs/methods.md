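# Methods

## The question and the pipeline

Displaced migratory birds with intact olfaction often rejoin their
population's migratory corridor; birds with sectioned olfactory nerves often
do not. One candidate mechanism is plume-following: when wind happens to
carry volatiles from the (familiar) corridor to the displaced bird, the bird
turns toward the direction the air came from. `plumetrace` implements the
analysis chain needed to examine that mechanism with a transport model:
backward particle dispersion from every bird position ("where could the
arriving air have picked up material?"), a persistence correlogram of those
source fields, a per-bird accumulated-exposure score, and the
exposure/reorientation statistics.

Because real wind reanalyses and real gull tracks are heavy, proprietary and
noisy, the package ships a synthetic-data generator that produces the same
study *structure* at desk scale, with known ground truth, so every stage of
the pipeline is testable end to end.

## Backward dispersion model

A receptor is one (possibly interpolated) hourly bird position with a
reception window `W` (default 300 s) in the 0–30 m layer. `N` particles are
released at the receptor, at reception times uniform in the window and
heights uniform in the receptor layer, and stepped backward in time:

- advection: `−(u, v, w)·Δt` with `u, v, w` multilinearly interpolated in
  lon × lat × level × time from the gridded wind field;
- turbulence: a constant-diffusivity Gaussian random walk, per-axis standard
  deviation `sqrt(2·K_h·Δt)` horizontally and `sqrt(2·K_z·Δt)` vertically,
  reflecting at the ground. This replaces a full boundary-layer turbulence
  parametrization; at the scales analyzed here only the lateral spread of
  the retroplume matters, and a constant-K walk gives it in closed form
  (variance `2Kτ` at age `τ`), which the tests exploit;
- meters → degrees via the local metric (111,195 m per degree latitude,
  × cos φ for longitude);
- termination at a maximum age (default 72 h) or on leaving the domain
  (options: reflecting walls for closed-domain experiments, longitude wrap
  for global grids).

Gridding each post-step position into half-open 0.2° cells (cell centers at
`(k + ½)·res` from the domain origin) and adding `Δt × q` per deposit, with
`q` the spatially uniform emission rate, yields the source-contribution
raster; altitude layers (tops 100 / 3,000 / 50,000 m) are binned separately
then summed. Two exact identities pin the implementation down: the raster
total equals `q ×` total in-domain residence time, and with zero diffusion
the raster is the advected back-trajectory line. The forward/backward
duality is verified against an independently coded forward simulator on a
closed domain (source–receptor symmetry of the diffusion process).

Defaults: `Δt = 600 s` (Courant-safe for 10–20 m/s winds on 0.2° cells),
`K_h = 5,000 m²/s`, `K_z = 10 m²/s`, `N = 10,000` for tests (the reference
configuration of such studies uses 100,000; results scale with `1/sqrt(N)`
Monte-Carlo noise only). Per-receptor RNG streams derive from
`(seed, receptor index)` so results are independent of execution order.

## Track handling

Tracks are Movebank-style CSVs (one individual per file, ISO-8601 UTC).
Hourly interpolation is linear independently in lon and lat — a straight
line in coordinate space, not a great circle — preserving observed points
exactly. Distances are haversine on a 6,371 km sphere; bearings are initial
great-circle bearings. The activity filter marks a point active when the
speed to the next point is ≥ 2 m/s. Before/after windows around an exposure
are measured along the path (cumulative segment lengths), 500 km before and
200 km after by default; both are parameters because either reading
(path length vs displacement; 200 vs 500 km after) is defensible.

## Statistics

- **Correlogram**: Pearson correlation over all raster cells for up to 50
  randomly sampled (without replacement) ordered pairs per lag 1–48 h per
  bird; zero-variance rasters are skipped (Pearson undefined). Grand mean
  ± sd across birds.
- **Accumulation score**: for each raster at time `t`, the raster is sampled
  (bilinear; nearest-cell available for conservation checks) at all *active*
  track positions later than `t`; total divided by the bird's total number
  of locations. The future-positions reading is the default; a
  current-position variant is provided since the verbal definition admits
  both.
- **Exposure**: corridor fraction = mass in cells whose centers fall inside
  the corridor polygon / total mass; exposed when ≥ 0.05. The threshold is
  an explicit parameter because "received particles from the corridor" has
  no canonical quantitative form.
- **Plume bearing**: per particle, the bearing from the receptor to the
  particle's position when it was last ≥ 30 km away on its approach;
  circular mean across particles, with the resultant length reported as a
  confidence measure (near 0 under pure diffusion).
- **Turn analysis**: endpoint-to-endpoint bearings of the before/after
  windows around the *first* exposure event; `Δ` on the signed (−180, 180]
  branch, positive clockwise. A bird is classified *reoriented* when it was
  exposed, `|Δ| ≥ 30°`, and the turn has the same sign as the
  plume-relative arrival angle.
- **Tests**: V test (`V = n·r·cos(ᾱ−μ₀)`, `u = V·sqrt(2/n)`, upper-tail
  normal p); paired Hotelling on unit-vector differences
  (`F = (n−2)/(2(n−1))·T²` with `(2, n−2)` df; all-zero differences reported
  as p = 1); two-sided Wilcoxon rank-sum, exact for combined n ≤ 20 without
  ties; Pearson chi-square without continuity correction (zero margins are
  an error at the function level; the pipeline reports a degenerate-table
  run as p = 1, "no variation"); OLS of `Δ` on the plume-relative angle.

One caution established during development: the paired Hotelling statistic
has essentially no power against a pure rotation of a circular-*uniform*
before-sample (the difference vectors then have zero mean by symmetry). Its
power properties are therefore demonstrated on concentrated before-samples —
the realistic migratory regime.

## The synthetic study

`demo_spec()` defines the reference scenario. Wind: hourly 0.5° field over
lon 2–20°E, lat 34–60°N for 120 h; mean flow 12 m/s initially westerly,
rotating +9°/h starting at hour 36 (when tracks begin), plus a zero-mean
pair of traveling sinusoidal waves (total amplitude 1.5 m/s, wavelength 8°,
periods 30 h and 30/φ h with seeded random phases, φ the golden ratio, so
the perturbation never exactly repeats). The rotation sweeps the arrival
direction through north (no corridor air), east (corridor plume reaches the
displaced agents ≈ a day into their journey — late enough that a 500 km
before-window exists) and then south (corridor air arrives along the
migration axis, repeatedly exposing the still-moving anosmic agents without
deflecting anyone eastward).

Agents: 10 reactive (ION) + 10 non-reactive (ONS), cruise 10 m/s on
great-circle steps, baseline headings 177–183°, starting in a band at
8–9°E, 54.5–56.5°N — displaced west of a meridional corridor at 11–14.5°E
(goal region at its southern end). A cheap kinematic oracle (single
backward trajectory, pure advection) supplies exposure during track
generation; the analysis pipeline re-derives exposure independently from
the full particle model. Reactive agents rotate their heading toward the
plume-arrival bearing by `turn_gain = 0.6` per exposed step; an agent
reaching the corridor or goal settles there and keeps logging stationary
hourly fixes — the analog of resting at a familiar stopover site, which the
2 m/s activity filter then treats as inactive. Leaving the domain terminates
a track.

What the generator does *not* emulate: mesoscale meteorology, land/sea
contrast, GPS noise, stopover/foraging loops, wind drift of the flying
bird, and altitude-resolved flight. Passing tests therefore show that the
pipeline recovers a planted behavioral difference under clean transport
assumptions — not that the real-data effect sizes would reproduce.

## Problem sizes and numerical choices

Desk-scale runs use 150–600 particles per receptor, `Δt = 900 s` and a 36 h
maximum age (the full demo is ~1,400 receptor simulations and runs in a few
minutes on one CPU); closed-form and duality checks use 10,000–50,000
particles where Monte-Carlo error must be small. Exposure classification
and the group-level statistics are insensitive to particle count well below
these values because they threshold raster mass *fractions*. Degenerate
inputs are handled explicitly: zero-variance rasters (skipped in
correlograms), zero-mass rasters (exposure 0), all-zero paired differences
(p = 1), zero-margin contingency tables (pipeline reports p = 1 with a
degeneracy flag), coincident points (bearing undefined, error).

## Known limitations

- The constant-K random walk under-disperses relative to convective
  boundary layers; absolute raster values are in relative units and only
  comparisons within a run are meaningful.
- Linear lon/lat interpolation of tracks and straight-segment agents are
  poor near the poles; the analysis domain should stay in mid-latitudes.
- The correlogram of a *stationary* receptor under a periodically rotating
  wind is itself periodic (it rebounds at the rotation period); decay
  curves like the migrating-bird case requires either moving receptors or
  aperiodic wind histories.
- The exposure threshold (0.05) and reorientation criterion (30°,
  sign-matched) are explicit, documented conventions; sensitivity sweeps
  are supported via `AnalysisParams`.
- The angle–turn regression is only as informative as the variance the
  scenario plants in the plume-relative arrival angle. When all agents'
  exposure onsets fall at nearly the same wind-rotation phase (this happens
  at some seeds), the predictor spans only ~15° and the slope estimate at
  n = 10 is noise-limited; the group-level classification and tests are
  unaffected.
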