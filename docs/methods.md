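# Methods

## The assay being modeled

`larvascreen` analyses high-throughput behavioral recordings of 5-day-old
zebrafish larvae imaged one per well in four 96-well plates (384 wells per
session, one image every 6 s for 3 h). The 3-h recording is divided into
eighteen 10-min periods: periods 1–6 and 15 have no stimuli, periods 7–14
show moving lines projected through the plate bottom (red, green, blue and
16×-faster red; each color moving down then up in consecutive periods), and
periods 16–18 deliver acoustic pulses (20-s, 1-s, 20-s inter-pulse
intervals). From the per-frame movement and location of each larva, ten
outcome measures are computed:

| key | name | definition |
|---|---|---|
| `act_1h` | 1h | mean % of frames with movement over periods 1–6 |
| `act_p15` | P15 | % movement in period 15 |
| `hab` | Hab | first − second 5 min of period 17 (% points) |
| `startle` | S | period 16 − period 15 activity (pp) |
| `excit` | E | period 17 − period 16 activity (pp) |
| `omr_red` … `omr_fast_red` | R/G/B/FR | % time in the upper well half, up-moving minus down-moving period of that line class (pp) |
| `omr_rgb` | RGB | combined optomotor response (pp) |

Exclusions mirror the assay's data-processing templates: larvae moving in
< 1% of all frames are dropped entirely; a larva moving < 5% of the time in a
period contributes no optomotor measurement using that period. The "up" state
is evaluated after each movement and carried forward between movements; it is
undefined before the first movement, and %up is a time fraction over defined
frames (an events-only variant is available via `up_mode`/the scalar API).
Period 17 halves split 50/50, with the extra frame going to the first half
when the count is odd. `omr_rgb` defaults to the unweighted mean of the
defined per-class optomotor responses (a pooled location comparison across
all valid visual periods is available as `omr_rgb_mode="pooled"`); the mean
keeps the statistic in percentage points and degrades gracefully when a
class is undefined.

Treatment groups are compared to the DMSO vehicle control per behavior as
mean differences in percentage points (a *behavioral profile*), tested with
Welch's unequal-variances t-test (two-sided; the larva is the statistical
unit) against tiered Bonferroni thresholds α/m, α ∈ {0.05, 0.01, 0.001}
— m = 190 for the primary screen, 11 for validation experiments, 3 for a
concentration series. Profiles are clustered hierarchically (below).

## Synthetic data generator

Because raw plate videos are large and external, every stage is exercised
against a generator with known ground truth. The behavior model is a
*linear-probability* model chosen so expected outcome measures are closed
form wherever possible:

* per frame the larva moves with probability
  `clip(p_move_base + startle_gain·[20-s acoustic period]
  + (startle_gain + excitability_gain)·[1-s acoustic period]
  − habituation_drop·[second half of the 1-s period], 0, 1)`;
* on movement it takes a step of length uniform in
  `[step_min_mm, step_max_mm]` (default 0.5–1.5 mm) and random direction; the
  *sign* of the vertical component matches the direction of line motion with
  probability `(1 + g)/2`, where `g ∈ [−1, 1]` is the optomotor gain of the
  active line class;
* positions reflect at a circular boundary inset half a body length from the
  well wall (inner diameter 7.15 mm, larva 4 mm), so the rendered body stays
  inside its well.

Hence `E[S] = 100·startle_gain` pp, `E[Hab] = 100·habituation_drop` pp, and
`E[E] = 100·(excitability_gain − habituation_drop/2)` pp (the habituating
second half of period 17 enters the period mean). Optomotor expectations have
no closed form under the reflecting boundary; `expected_vector` computes them
with a seeded Monte-Carlo oracle, and `calibrate_omr_gain` inverts that
expectation by bisection with common random numbers (the response is pathwise
monotone in the gain). The optomotor expectation grows with the movement rate
— more repositioning brings the occupancy closer to the biased stationary
distribution — so gains must be calibrated on the phenotype they will be
applied to.

The default baseline phenotype (`dmso_phenotype`) moves in 20% of frames,
gains 10 pp under 20-s pulses and a further 15 pp under 1-s pulses with a
5 pp within-period habituation drop, and has uniform optomotor gain 0.5
(≈ +50 pp optomotor response) — robust but unsaturated responses typical of
healthy vehicle-control larvae. Per-well randomness derives from
`SeedSequence([master_seed, plate, row_index, column])`, so screens are
bit-for-bit reproducible independently of well iteration order or batching.

What the generator does *not* emulate: swim-bout kinematics, thigmotaxis and
edge preference, larval death or fatigue drift, inter-well optical cross-talk
and illumination gradients, and session/plate batch effects. Tests passing on
synthetic data therefore validate the bookkeeping, statistics and geometry of
the pipeline, not biological effect sizes.

## Rendering and the contrast budget

Rendered frames emulate acquired images: gray background (210,210,210),
horizontal stimulus lines of the active period's color composited at opacity
0.7 (the projection is diffused by the opaque plate bottom), and each larva
as a dark 4×1 mm horizontal ellipse. The larva gray level (20) and line
opacity were chosen as a contrast budget around the analysis threshold of 40:
any pixel newly covered by a larva darkens by ≥ 40 in *every* channel (the
darkest non-larva pixel is an off-channel line at 63), while moving lines
never change the selected channel by ≥ 40 (line-vs-background contrast there
is ≤ 32). Stimulus motion is therefore exactly invisible to the tracker and
larval motion exactly visible.

## Tracking

For each consecutive image pair the tracker selects the channel in which the
active stimulus and the background are most alike (ties to the lowest
channel), thresholds the channel difference at 40 (inclusive), and measures
changed-pixel area and centroid inside each well's circular ROI. A larva
"moved" when ≥ 3 px changed (the source assay does not state this minimum;
it is configurable). "Up" means the detection centroid is strictly above the
well's horizontal midline (centroid exactly on the boundary row counts as
lower half).

Differencing modes: the pipeline default is `signed` (`prev − curr ≥ 40`,
i.e. pixels that darkened — the larva's newly occupied position), because
its centroid tracks the new location and it is immune to the one-frame
stimulus-color transition artifact; `abs` (`|curr − prev| ≥ 40`) marks
vacated and occupied pixels alike, is sign-symmetric, and is available via
`TrackingConfig(diff_mode="abs")`. With the signed mask, the measured
centroid equals the centroid of the *change* region: it coincides with the
new blob centroid whenever the displacement exceeds the blob extent along
the displacement direction, and sits on the leading crescent otherwise —
adequate for half-well location calls, exact in the rendered-fixture tests.

The first image of a recording has no predecessor, so a 384-well 1800-frame
session yields 384 × 1799 observation pairs; `include_first_frame=True`
books an extra moved=False row per well for results files that count one row
per image (384 × 1800). All fractions are computed over the rows actually
present.

## Screen statistics

Welch's statistic is computed from the group moments
(`t = (m_x − m_y)/√(s²_x/n_x + s²_y/n_y)`, Welch–Satterthwaite df, two-sided
p from the t distribution); `scipy.stats.ttest_ind(equal_var=False)` is used
only as an independent oracle in the tests. Degenerate zero-variance
comparisons return p = 1 (equal means) or p = 0 (unequal) with a warning
rather than failing a whole screen. Optomotor sample sizes count only larvae
with that measure defined; exclusion is per measure, not per larva.
Profile tables are color-coded on a diverging gradient clipped at ±25 pp
(green = decrease, red = increase; zero is white in the screen style and
black in the cluster/tree-viewer style) with unrounded values used for all
comparisons.

At reduced simulation scale (10 frames per period, n = 12 per group) the far
tail of Welch's test is slightly inflated for single-period activity measures
— 10-frame percentages at n = 12 are coarsely discrete, so the sample
variance is occasionally far too small — giving a realised per-comparison
rate of ≈ 3.5×10⁻⁴ at the nominal 2.6×10⁻⁴ threshold, within the 99%
Monte-Carlo interval once the between-screen clustering induced by the shared
control group is accounted for. At full scale (100 frames, larger n) this
discreteness vanishes.

## Clustering

Profiles are clustered agglomeratively with complete linkage on the weighted
dissimilarity `d(x,y) = Σ wᵢ(xᵢ−yᵢ)² / Σ wᵢ` over mutually defined features
— the convention of the Cluster 3.0 program (no square root; pairwise
missing-value handling with weight renormalisation; "Eweight" 0.5 on the
five optomotor columns, 1 elsewhere). No centering, scaling or other
transform is applied before clustering. Ties in the minimum inter-cluster
distance are broken toward the lexicographically smallest pair of cluster
representative labels, making merges deterministic. `d` is symmetric,
non-negative and zero on identical rows, but being a mean *squared*
difference it does not satisfy the triangle inequality — only merge order
matters. A √d variant and scipy's linkage (on complete data) agree with the
merge heights in tests.

Additive-inverse rows (every delta negated, label suffixed `-inv`) implement
the hypothetical-compound search: the inverse of a profile from one
functional class should join the cluster of the opposite class. Cluster
"cohesion" is reported as the mean pairwise Pearson correlation of member
profiles over mutually defined behaviors (minimum pairwise correlation is
available as a conservative alternative); published per-cluster correlation
values do not state their formula, so this statistic is a reconstruction.
CDT/GTR files written by `write_cdt_gtr` follow tree-viewer conventions
(GID/UNIQID/NAME/GWEIGHT header, EWEIGHT row carrying the column weights,
one `NODEkX` line per merge with the merge height as score).

## Problem sizes used in tests and the acceptance script

Oracle-equivalence suites run 1,000 random small instances per operation
(180-frame tracks, 3–6-row matrices). Parameter recovery simulates
validation-sized experiments (160 larvae per group, full 1800-frame
schedule); the test uses 100 replicates and asserts the replicate-averaged
deltas within ±3 pp (activity family) and ±5 pp (optomotor family) — a
single replicate's optomotor delta has sampling error of the same order as
the band — and the m=11 significance flag in ≥ 95% of individual replicates.
Null calibration runs 200 screens of 190 null groups (n = 12, 10 frames per
period). The tracking round trip renders one 96-well plate at 5 px/mm for
108 frames (6 per period). `scripts/acceptance.py` recomputes the same
quantities with 40 recovery replicates and 60 null screens.

## Known limitations

* The generator's behavioral repertoire is the ten measured statistics; it
  cannot reveal analysis errors that only manifest on richer kinematics.
* Fixture baselines (the DMSO phenotype, the CsA-like/INDY-like profile
  magnitudes) are package parameters, not values calibrated to any recorded
  dataset; drug-specific effect sizes are out of scope.
* One larva per well is assumed throughout; multi-larva wells would corrupt
  the change-mask measurements silently.
* The per-cluster cohesion statistic is a reconstruction (see above).
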