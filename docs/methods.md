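# Methods

This note documents the generative model, the measurement operators, the
statistical contracts and the calibration and design choices behind
`nephrotrack`. It is the package's own account of its science; every
empirical number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## 1. Cohort model

**Topology.** A cohort is a set of mice, each carrying nephrons assigned to
one injury region (IR, Mid, Not-IR; all-Sham for control cohorts). A
nephron is a 1-D flow path of tubule segments in fixed order
PT-S1 → PT-S1 → PT-S2 → PT-S2 → DCT/CD, with strictly increasing axial
coordinates (µm) and 40 epithelial cells per segment at evenly spaced axial
positions. Cross-sections are treated as discs; all quantities the study
defines (25-µm proximity radius, cast-area fraction, counting planes)
reduce to 1-D or per-area quantities, so no 3-D anatomy is modelled. The
default cohort sizes match the study structure: 53/67/25 nephrons
(265/335/125 segments) in IR/Mid/Not-IR across 7 mice.

**Day-0 necrosis.** Day 0 is the 2-h post-reperfusion imaging session.
Every nephron in IR is ischemic; a Mid nephron is ischemic with probability
0.50 (the border region is a spatial mixture of perfused and non-perfused
tissue); Not-IR nephrons are never ischemic but carry rare scattered 1-2
cell necrosis (4.88% of segments). Within an ischemic nephron each segment
is necrotic with class probability (PT-S1 0.85, PT-S2 0.78, DCT/CD 0.55)
and draws a severity from a two-component Beta mixture — a moderate body
(means 0.35 / 0.195 / 0.053 by class) plus a severe spike (weight
0.085 / 0.15, means 0.78 / 0.64) — scaled by the region factor (Mid 0.575)
and a per-mouse log-normal factor (σ = 0.10) that provides the clustering
the mixed models are built for. PI⁺ cells form one contiguous patch per
segment (ischemic death is spatially coherent). The severity mixture was
calibrated so that the emergent day-0 means reproduce the reported cohort
values (IR 21.78%, Mid 6.21%, classified PT-S1 26.19%); the severe spike is
what the classifier later rejects as unclassifiable.

**Shedding and cast transport.** Attached necrotic cells shed into the
lumen beginning 6 h after reperfusion. In post-ischemic kidneys shedding is
staggered uniformly over days 1-3 (casting is observed to continue over the
first days); laser ablation (below) sheds at once. Each shed cell becomes a
parcel of solid luminal area (97 µm² per cell after a log-normal production
factor, σ = 0.35) at the cell's axial position. Parcels advect downstream
at 185 µm/day (post-ischemic, low-flow kidneys; 300 µm/day in the healthy
laser kidney) and deposit along the way with per-µm rates strongly
preferring PT-S2 (5.2×10⁻³) and DCT/CD (1.2×10⁻³) over PT-S1 (2×10⁻⁵); a
log-normal stickiness factor per segment-day (σ = 1.2) represents luminal
flow-state variability and produces the heavy-tailed cast distribution the
fate layer requires. Freshly shed debris does not settle in its segment of
origin (it is carried out before deposition); this is what makes cast
accumulation in non-necrotic and necrotic PT-S2 comparable, as observed.
Segment cast fraction is deposited area over cross-sectional area, capped
by the luminal area fraction (0.40 of the cross-section for PT, 0.45 for
DCT/CD). Mass is strictly accounted: produced = deposited + in transit +
outflow + cleared, an invariant the tests check every run. Non-atrophic
tubules clear their casts exponentially (0.35/day) after the fate-decision
window.

**Cell cycling.** A surviving cell commits to cycle with per-day
probability

    base + ramp(t) · [ p_near · 1{near} + p_max · c^h / (c^h + K^h) ]

with `near` meaning strictly < 25 µm (axial distance) of any day-0 PI⁺
nucleus, active days 1-4; `c` the segment's cast fraction on the previous
day (the dose acts ~24 h after cast arrival); and a baseline of 0.46%/day
that also sets the flat sham level. Committed cells display the transient
reporter for one day (the S/G2/M window) and then rest; cumulative unique
reporter counts over days 1-3 are therefore sums of daily counts.

Two deliberate model choices here:

* the **cast dose response is a Hill function** (p_max 0.087/day, K 0.17,
  h = 4) rather than linear. A linear response cannot simultaneously
  produce the weak distant cycling at the small days-1-3 casts (~1.6%
  cumulative far fraction) and the strong day-2 response of heavily casted
  PT-S2 after laser injury (~8.4%); a cooperative, near-threshold response
  to luminal obstruction does. The observable cast→cycling relation remains
  monotone and yields significant linear regressions.
* commitment hazards carry a **post-ischemic remodeling-capacity ramp**
  (0.25, 0.35, 0.6, 1.36, 0.7 on days 1-5, decaying to ~0 after day 7):
  the repair program ramps up over the first days after whole-kidney
  ischemia, peaks around days 3-4 and shuts down as the epithelium
  re-differentiates, which returns cohort GFP to sham level by days 14-21.
  Focal laser injury in an otherwise healthy kidney is exempt and responds
  at full capacity immediately.

**Fate.** At day 4 each segment draws its terminal fate from
`logit P(atrophy) = −5.7 + 21·c(day 3/4)`; non-atrophic segments with
day-0 PI⁺ > 1% become `recovered`, the rest `uninjured`. Decision days are
sampled from the study's timing distributions (recovered: 77/21/2% on days
7/14/21; atrophic: 55/34/11%) and realised in the morphology trajectory
(granular while casts are present, flattened for moderately necrotic PTs —
the ATN/ATI distinction — then terminal atrophic/normal from the decision
day). The fate classifier reads only the morphology trajectory and the
day-0 PI fraction back, and recovers the generator's fates >99% exactly.
Necrosis enters the fate model only through the cast cascade (no separate
coefficient): the cast-only logistic is the regression the study reports,
and the atrophic-vs-recovered difference in day-0 necrosis still emerges
through the upstream-production correlation.

**Laser injury.** The focal-injury experiment uses per-mouse fields of
view: 10 full healthy nephrons per mouse whose PT-S1 is ablated (35
contiguous cells), plus 65 bystander single-segment tubules placed at
area-uniform radial distances up to 135 µm from the injury. Downstream
PT-S2 of injured nephrons accumulate casts within a day; bystanders see
only the baseline cycling rate, which is what the distance-zone control
(0-35 / 35-85 / 85-135 µm, area-normalised) verifies.

**Albumin reuptake.** PT-S1 function is summarised as the apical/capillary
labelled-albumin intensity ratio, drawn from fate-conditioned trajectories:
uninjured ≈ 1.8 throughout; recovered start at ~0.5 and regain the sham
band by day 7; atrophic stay ≤ 0.45 and never recover.

## 2. Imaging model

`imaging.render_segment` draws a segment as a cylinder along x in a
two-track (750/940 nm), three-channel, 60-plane z-stack at 1 µm z-step.
Epithelial cytoplasm carries class-specific green/blue autofluorescence
(PT-S2 > PT-S1 > DCT/CD in both channels, class-separating green/blue
ratio); nuclei are negative-stain ellipsoid voids; PI⁺ cells add nuclear
red and attenuate their cytoplasmic blue by 95% (NADH depletion) and green
by 25%; the cycling reporter is green on the 940 nm track only; casts are
bright granules filling the configured solid fraction of the lumen at the
widest plane, on the 750 nm track only (this separability is what makes
GFP counting on the 940 track clean). Cells occupy the central 25-µm band
with deterministic wall/depth placement so that the five counting planes
(offsets 0, 6.25, …, 25 µm) see every nucleus and xy-overlap linking can
deduplicate across planes; the closed loop render → count is exact at zero
noise, within one nucleus for ≥95% of segments at a read-noise SD of 2
intensity units, and degrades monotonically beyond that. Nucleus detection
uses two intensity bands (voids in bright vs in necrosis-darkened
cytoplasm) with nuclear red taking precedence for PI⁺ cells, a 3×3 median
filter for speckle, and size gating so that shed-cell cytoplasm territories
are not mistaken for nuclei. Quantification always runs on unprocessed
intensities; the denoising/registration slots of the original acquisition
workflow are explicit no-op hooks.

## 3. Statistics

* `linear_fit` — OLS with slope/intercept t-tests, 95% CIs, R² and
  Pearson r; two-group slope/intercept contrasts via the interaction
  parameterisation; cluster-robust (mouse) standard errors on request.
* `binary_fit` — maximum-likelihood logistic regression; odds ratio per
  unit predictor; the headline R² is the response-scale coefficient of
  determination (1 − SSE/SST of the 0/1 outcome against fitted
  probabilities) with McFadden's pseudo-R² secondary — the response-scale
  definition is the only one that plausibly reaches ~0.8 with an 87/13
  split at high doses. Complete separation is detected and flagged, with a
  weak-ridge fallback.
* `group_compare` — linear mixed model with a random intercept per mouse,
  fitted by ML (not REML, for cross-model comparability), reporting the
  group difference Δ with 95% CI, t(df) under a residual-df approximation
  and a two-sided p; a cluster-robust OLS fallback handles degenerate
  clustering (a group confined to one mouse is additionally flagged as
  confounded). Under a null clustered simulation its type-I error is
  ~5% (checked at 1000 replicates); a known-effect simulation shows ≥93%
  CI coverage.
* `paired_compare` — two-sided paired t-test, segments paired across
  conditions.

Multiple comparisons are not adjusted for regressions and pre-specified
contrasts, matching the study's convention.

## 4. Calibration

Default parameters are calibrated so that the emergent cohort statistics
match the study's printed values; they live in one versioned file,
`src/nephrotrack/data/default_config.yaml`, and are never hard-coded.
Calibration was performed by iterating the forward model against twelve
cohort statistics (day-0 necrosis means by region and class, the 25-µm
near/far split, cast-area fractions, the laser contrast, and the fate
structure including the cast→atrophy R²). Two constraints shaped the
model: the cast→atrophy logistic must be steep (slope 21 per unit cast
fraction ≈ a ~7-percentage-point transition width) for the binary
regression's response-scale R² to reach ≈0.8, and ischemic-region casts
must sit deep in the lumen-capped saturation regime for the Mid region to
contribute its share of atrophic tubules (about a third of IR's) despite
its 3.5-fold lower necrosis.

## 5. What the generator does and does not emulate

The synthetic cohorts reproduce the *structure* of the study data — region
and class gradients, within-mouse clustering, contiguous necrotic patches,
downstream cast timing, transient reporter kinetics, fate timing, missing
field-of-view dropout — and the cohort-level magnitudes listed above. They
do not emulate: real two-photon noise and scattering (the renderer uses a
simple Poisson-Gaussian model and a linear depth-free geometry), tubule
tortuosity and 3-D packing, PT-S3 (inaccessible to intravital imaging and
excluded here too), interstitial and immune compartments, mechanistic
biochemistry of necrosis or DAMP signalling, and real segmentation error
(masks are known by construction). Passing tests therefore demonstrate
that the pipeline's operators and statistics recover the structure they
were built to measure — not that the biological model is validated against
raw images.

## 6. Numerical and boundary conventions

Fractions are stored in [0,1] and reported as percentages. A tubule is
*necrotic* iff day-0 PI⁺ > 1% strictly; *severe* necrosis is > 20% strictly
(20% itself is moderate); *near* is strictly < 25 µm; *lumen-filling* casts
are ≥ 25% of the cross-section (≈ 60% of the lumen). The proximity
analysis set is segments with at least one day-0 PI⁺ nucleus, since the
near zone is undefined otherwise. The five counting planes are evenly
spaced over the central 25 µm; widest-plane ties break toward the stack
middle. Cumulative reporter counts over days 1-3 count unique cells (exact
with the one-day-visible reporter). Segment classification uses the
green/blue ratio with brightness as a secondary axis; guards (blue below
42 intensity units, ratio above 2.15, non-positive blue) mark severely
necrotic segments unclassifiable, which excludes them from class-stratified
analyses only. Random numbers derive from a single root seed through named
child streams; identical (config, seed) runs are byte-identical end to end.

## 7. Known limitations

* The simulator's proximity distance is axial (1-D); the image path uses
  in-plane Euclidean distance. Both use the same 25-µm radius.
* The PT-S1 regression intercept (cumulative cycling at zero necrosis) sits
  slightly above zero because the baseline cycling rate is calibrated to
  the uncasted laser group (0.46%/day); in the study this intercept was not
  distinguishable from zero at its smaller sample size.
* Fate-decision days are drawn from the reported timing distribution rather
  than emerging from a mechanistic repair clock; the morphology trajectory
  realises them, so trajectory-based classification recovers them by
  construction.
* Mixed-model degrees of freedom use a residual-df approximation; exact
  small-sample corrections (Satterthwaite/Kenward-Roger) are out of scope.
* Cast transit speed is not reported by the study; the defaults (185 and
  300 µm/day) satisfy the qualitative constraint that non-necrotic
  downstream segments acquire casts within 1-2 days.
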