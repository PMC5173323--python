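# Methods

## Scope and data model

`ivtrack` analyzes cell-track tables — one row per (cell, timepoint) with
coordinates in µm and times in minutes — as exported by commercial tracking
software from intravital time-lapse microscopy.  Segmentation and
frame-to-frame linking happen upstream; this package never touches images
or pixels.  Tracks carry optional string labels (group, day, region,
phenotype) used for stratified summaries and comparisons.

3-D tracks (z-stack acquisitions) are accepted; by default the z
coordinate is dropped before metric computation (`project_2d=True`),
because displayed intravital motility analyses are conventionally planar
and source tables do not always state which convention was used.  The flag
is exposed everywhere metrics are computed.

Timestamps are written values rather than measurements, so the uniform
frame-interval check uses a tight tolerance of 1e-6 min.  Table reading
uses round-trip float parsing so that write → read is bit-exact.

## Motility metrics

* **Mean velocity** is defined as path length / elapsed duration.  At
  uniform sampling this equals the arithmetic mean of instantaneous
  speeds — a provable identity the test suite asserts on random tracks —
  so the two common conventions coincide wherever sampling is regular.
* **Arrest coefficient** uses a strict `<` at the 2 µm/min threshold and
  weights each step by its own Δt, which generalizes correctly to
  irregular sampling.  Single-frame speeds are used (no smoothing window).
* **Maximum displacement** is measured from the track's first position,
  matching the convention of trajectory plots aligned at their starting
  positions.
* **Confinement ratio** is undefined (NaN), not zero, for a cell that
  never moved: 0/0 has no meaning and silent zeros would bias cohort
  means.  Such cells are excluded from the confinement summary with a
  reported count.
* Cohort summaries treat each cell as one data point and report mean, SD,
  SEM and n per metric with explicit column names, since published figure
  legends mix mean ± SD and mean ± SEM.

## Mean displacement and the random-walk criterion

The cohort MD curve averages each cell's displacement from its own origin
over the common grid of frame-interval multiples; cells contribute only
while observed (no imputation), so the per-point cell count is
non-increasing.  The fit of MD against √t is ordinary least squares with a
free intercept — the conventional default, and what standard R²
presumes — with the t = 0 point excluded (MD ≡ 0 there would anchor the
fit artificially) and grid points supported by fewer than 5 cells dropped
(configurable).  R² strictly above 0.95 classifies the population as
random-walking.  If the retained MD values have zero variance, R² is
reported as 0 and the classification is negative (degenerate-case guard).
Whether published fits of this kind include an intercept or average
overlapping lags is generally unstated; slope, intercept and R² are all
reported so alternative conventions remain recoverable.  A full
MSD-over-all-lags analysis and anomalous-diffusion exponents are out of
scope.

An analytic cross-check used in tests: a 2-D fixed-step random walk with
step s has mean displacement ≈ s·√(πk)/2 after k steps (Rayleigh limit).
The Monte-Carlo verification runs 3 000 tracks of 31 frames, where the
asymptotic formula is accurate to well under the 3% test tolerance.

## Synthetic cohorts

The simulator emulates the statistical structure of intravital track
exports: frame interval 0.5 min, 31 frames (a 15-minute movie) and cohort
sizes matching published cell counts.  Four motion models are provided
(fixed- or uniform-step random walk, mean-reverting tethered walk,
drifting walk, two-state stop-and-go Markov chain over per-frame speeds);
directions are uniform on the circle, or on the sphere for the 3-D
option.  One SeedSequence per simulate call spawns independent per-track
substreams, so output is reproducible regardless of track order or
platform.

What the generator does **not** emulate: persistence (directional
autocorrelation), cell–cell and cell–tumor interactions, spatial
heterogeneity of the microenvironment, tracking noise and track
fragmentation.  Passing tests therefore demonstrate correctness of the
*analysis* under the stated sampling conditions, not fidelity of any
biological mechanism.

### Regime presets

Fourteen presets name published intravital motility regimes (adoptive
CTLs at tumor periphery/parenchyma on Days 1–6 of combined
cyclophosphamide + adoptive-transfer therapy; tumor-infiltrating
immunocytes on Days 0–4; endogenous GFP T cells in the two treatment
arms).  Calibration is analytic:

* mean-velocity-only regimes use a constant-step random walk with step
  v·Δt (mean velocity exactly v);
* regimes with a published (velocity, arrest) pair use the stop-and-go
  chain with slow speed 0.5 µm/min, stationary slow occupancy π = AC/100
  and fast speed solved from v = π·0.5 + (1 − π)·v_fast; transition
  probabilities share a per-frame switch rate of 0.6 so the chain mixes
  within a track while keeping the stationary occupancy at π.

A single published (velocity, arrest, confinement) triple over-determines
these one- and two-parameter models, so presets match velocity and arrest
in expectation and record the published confinement ratio for reference
only; the achieved confinement ratio of the calibrated models is ~0.2–0.3.
Tests verify recovery at the published cohort size, averaging over five
seed replicates because a single cohort of ~100 cells carries ~3–4%
Monte-Carlo error in its mean.  The GFP T-cell regimes publish no cell
count; those presets default to 200 cells, mid-range of the other cohorts.

### Point patterns

`simulate_point_pattern` draws Poisson-distributed labeled points in three
compartments — a central tumor disc, a surrounding annulus ("ring"), and
the exterior field — with per-label intensities in cells/mm².  The disc
plus annulus must lie inside the rectangular field.  Sampling is exact
(polar inverse-CDF inside disc/annulus; rejection sampling outside).

## Spatial quantification

Densities are exact count/area arithmetic with named constants for the
common field sizes (0.18 mm² frozen-section fields, 0.40 mm² intravital
regions of interest, 12 mm² stitched large fields).  The radial ring
profile bins cells by signed distance to the tumor boundary (negative =
interior); bin areas come from polygon offsetting (discs are discretized
at 512 segments per quarter circle, area error < 1e-5 relative) clipped
to the field rectangle, which makes the conservation identity
Σ density·area = total count exact by construction.  The **ring index** —
density in the [0, bin width) band just outside the boundary divided by
the interior density, `inf` when the interior is empty — is this
package's own construct for quantifying peri-tumoral accumulation; no
quantitative published definition of the "immunosuppressive ring" exists,
and outputs label the index accordingly.

## Group statistics

Two groups: two-tailed unpaired t-test (equal variances).  Three or more:
Kruskal–Wallis with mid-rank tie correction (motility data tie heavily at
zero), followed by Dunn's pairwise z-tests on pooled mean ranks with the
same tie correction.  Multiplicity adjustment is Bonferroni over all
pairs by default — reproducing the common Prism convention when only
"Dunn's multiple comparison tests" is specified — with Holm and
unadjusted options.  Significance bands: * p<0.05, ** p<0.01,
*** p<0.001.  A group of one observation reports SD 0 with an explicit
`sd_defined=False` flag.

## Bench formulas

Specific lysis is `100·(E − S)/(1 − S)` on dead-target-cell *fractions*
(the CLI accepts percentages and converts); S must be < 1, and negative
results (experimental below spontaneous) are reported and flagged rather
than clipped.  Caliper tumor volume is `L·W·H/2` in mm³.

## Pipeline and problem sizes

The `run` pipeline validates a versioned YAML config with all
paper-derived defaults surfaced explicitly (2 µm/min threshold, 0.95 R²
criterion, 0.5-min frame interval), derives independent per-cohort seeds
from the run seed, refuses to overwrite outputs without an explicit flag,
and writes a SHA-256 manifest plus a mean ± SD (n = …) report.  Full-size
cohorts (up to ~480 tracks × 31 frames) simulate and analyze in well
under a second each; the acceptance script's 20-seed replications run in
a few seconds total.

## Known limitations

* Presets reproduce velocity and arrest statistics, not confinement
  ratios or spatial trajectories; they are calibration targets, not
  digital twins.
* No persistence/turning-angle statistics, directionality indices or
  chemotaxis metrics.
* Irregularly sampled cohorts must be resampled upstream before MD
  analysis (per-track metrics handle irregular sampling natively).
* The ring index depends on the supplied boundary geometry; boundaries
  are never inferred from data.
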