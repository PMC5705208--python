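# Methods

This note documents the models, numerical choices and limitations behind
`periflow`.  It covers (1) the vessel-graph representation and distance
computations, (2) the exact random-placement null model, (3) blockage
detection on lumen profiles, (4) perfusion and diameter quantification,
(5) the statistical protocol, and (6) the synthetic-data generator — what
it emulates, what it does not, and therefore what passing tests do and do
not show about real data.

## 1. Vessel graphs and distances

A capillary bed is a set of polyline segments in continuous μm
coordinates (2-D or 3-D; no pixel grid is assumed, because the distance
analysis is sub-μm sensitive).  Segment ends that meet at a branch point
or junction are declared in an explicit adjacency list — connectivity is
never inferred by geometric snapping.  Segments are partitioned into
named *capillaries*: an unbranched vessel split by junctions keeps one
capillary id across its pieces.

Pericyte somata are annotated by their mid-point arc position; a
`visible` flag marks somata inside the imaged field, and only visible
somata participate in any nearest-soma search.  All distances are
geodesic (shortest along-vessel path), computed by Dijkstra on the node
graph whose edge weights are segment arc lengths, plus the exact offsets
of the query points within their segments.  `arc_distance` is a metric on
each connected component (property-tested); disconnected queries raise
rather than returning infinity.

`nearest_soma_distance` restricts the search to the query point's named
capillary by default, mirroring a measurement made "on the same
capillary"; a flag widens it to the whole reachable network.
`intersoma_distances` reports distances between *adjacent* visible soma
pairs — a pair is adjacent when no third soma lies on a shortest path
between them — and offers a Euclidean-chord variant for measurements made
within an imaging plane.  Geodesic is the default because on-network
spacing is the quantity the null model consumes; on the generator's
straight vessels the two coincide.

## 2. Exact random-placement null model

If a blockage were placed uniformly at random along the imaged arc length
*L* of its capillary, the induced distribution of the nearest-soma
distance would be fully determined by geometry.  The nearest-soma
distance along a segment is the lower envelope of finitely many affine
functions of arc position, each with slope exactly ±1 (distance through
either segment end to each soma, plus the two branches of |t − a| for an
on-segment soma at arc a).  The implementation therefore:

1. collects the candidate intercepts per segment;
2. forms the candidate kink set: segment ends, on-segment soma positions,
   and all pairwise intersections of opposite-slope candidates
   (same-slope candidates are parallel and never cross);
3. evaluates the exact pointwise minimum at consecutive kinks; between
   kinks the envelope is a single affine piece with slope ±1, so an
   interval of length ℓ contributes probability mass ℓ/L uniformly over
   the distance range it sweeps;
4. accumulates the piecewise-constant density over the union of interval
   endpoints and integrates it into a piecewise-linear CDF.

This is exact up to floating-point rounding; the final CDF value is
renormalized to exactly 1 (residue < 1e-9).  The test suite checks it
against an independent brute-force oracle (0.01 μm discretization of the
capillary, point distances via `nearest_soma_distance`, cell mass spread
linearly between endpoint distances) at 1e-4 sup-norm on 200 random
geometries.  Test geometries record annotation positions at 0.01 μm
precision — the resolution at which confocal annotations are realistically
stored — which keeps the *oracle's own* kink-cell discretization error
below the comparison tolerance.

Truncation at the image border is handled exactly as acknowledged by the
measurement it models: only the imaged extent contributes to *L*, and all
imaged visible somata compete.  When a capillary leaves the field, the
true nearest soma may be outside the image; both the observed measurement
and the null inherit that censoring consistently.

**Pooling.**  Per-image CDFs are averaged pointwise at the union of
breakpoints.  Two weightings are provided: equal weight per image (the
convention when each imaged stack contributes one blockage) and weight
proportional to the number of blockages per image.  The second is the
exact generative mixture when images carry several blockages — it makes
"uniform placement on each blocked capillary" and "draw from the pooled
null" the same distribution — and is the pipeline default; with one
blockage per image the two coincide.  A blocked capillary with no visible
soma is excluded from the null exactly as its observed distance is
excluded from the data (the exclusion is placement-independent, so no
bias is introduced).

**Equi-probability sampling.**  The pooled CDF is reduced to *n*
quantiles at probabilities (i − ½)/n, i = 1…n.  The midpoint convention
keeps the top point finite for approximations with unbounded support; the
i/n convention is available as a switch.

**Idealized null.**  `linear_null(h)` is the evenly-spaced-somata limit:
CDF(x) = x/h on [0, h].  For 60 μm inter-soma spacing it reaches 1 at
30 μm, and the exact computation on a long capillary with 60 μm-spaced
somata converges to it.

## 3. Blockage detection on lumen profiles

The source measurement is tracer intensity sampled at uniform steps along
a capillary centreline.  Detection operates on the background-subtracted
profile clamped at zero and normalized to the upstream plateau (median of
the first 25% of samples).  A block is called when the normalized signal
falls from ≥ 0.8 to ≤ 0.2 within ≤ 5 μm; the reported position is the
first (most upstream) 0.5-crossing, localized by linear interpolation.
These thresholds are operational definitions of an "abrupt termination"
— the underlying observation is only that the drop occurs over a few
microns — and all are exposed in `DetectionParams`.  A short moving
average (default 0.6 μm) suppresses single-sample noise crossings; at the
generator's noise level (s.d. 0.05 of plateau) it brings the localization
error comfortably under ±0.5 μm.  Detection is translation-equivariant.
When several drops qualify, the most upstream is returned and the rest
are logged: downstream of the first cessation the vessel is unperfused,
so later structure is treated as artefact.

Aggregation aligns normalized profiles at their called positions
(offset 0 = half-maximum crossing), resamples them onto the common
overlapping grid and reports mean ± s.e.m. per point (s.e.m. undefined at
n = 1 and returned as NaN).

## 4. Perfusion and diameter quantification

**ROI maps.**  Twelve regions of interest are indexed clockwise around
the left ventricle from the mid-septum; ROIs 7–10 form the risk zone,
ROIs 4–6 the posterior wall, ROIs 1–3 the reference region outside the
risk zone.  Each heart is divided by its own maximum ROI intensity
(removing staining-brightness differences — per-heart scale invariance is
unit-tested), hearts are averaged within condition, and each condition's
curves are rescaled by that condition's own ROI 1–3 mean.  The
per-condition reference was chosen because ROIs 1–3 lie outside the risk
zone in every condition, so the rescale cancels residual global
differences without touching the contrast of interest; a shared-reference
option (one condition's factor applied to all) is available for
sensitivity analysis.  The headline contrasts are percent changes of the
per-condition means of per-heart risk-zone averages; the accompanying
tests compare per-heart means (hearts, not ROIs, are the experimental
units).

**Transect counting.**  The transect is the line through the field centre
perpendicular to the main capillary axis.  A crossing capillary counts as
blocked when it carries a blockage annotation — i.e. its tracer signal
terminates somewhere within the image.  Condition percentages are
unweighted means of per-image fractions with s.e.m. over images,
matching reporting of mean ± s.e.m. with image counts.

**Diameters.**  For each pericyte site the ratio r = d_soma / d_upstream
is formed (upstream = 10 μm from the soma, the span of most
circumferential processes).  Per condition the analysis reports mean
ratio ± s.e.m., mean soma-site diameter ± s.e.m., a one-sample test of
the ratio against 1, and across conditions the percent change of mean
soma-site diameter — exact algebra on the condition means — plus
two-group tests on the ratios.  Pairs with zero upstream diameter are
excluded and logged.

## 5. Statistical protocol

Two-group comparisons are gated: Shapiro–Wilk per group at p ≥ 0.05
(gate level configurable; the protocol specifies the test, the threshold
is the conventional choice), then a two-sided F test on the variance
ratio at the same level choosing Student versus Welch; any normality
failure falls through to Mann–Whitney (mid-rank ties, scipy's exact or
asymptotic p as appropriate).  A group with no spread cannot be assessed
by Shapiro–Wilk and falls through to the rank test.  Every result carries
a selection trace for audit.  One-sample comparisons (ratio vs 1) gate
between the one-sample t and Wilcoxon signed-rank the same way.

The multiple-comparison correction is the sequential Bonferroni rule in
its literal multiply-and-clamp form: the most significant of N p-values
× N, the next × N−1, …, clamped at 1, reported in input order.  The
literal rule can leave corrected values non-monotone along the sorted
order; a flag enforces the running-maximum (step-down) refinement, off by
default to match the stated rule.  Corrected values are computed within
each reported panel family (e.g. the three pairwise condition contrasts
of one panel).

`min_sample_size` searches the smallest integer n ≥ 2 per group whose
two-sided two-sample t-test power — noncentral-t with noncentrality
(δ/σ)·√(n/2) and 2n − 2 degrees of freedom — reaches the target; a
Monte-Carlo power oracle cross-checks the search in the tests.  For a 50%
effect against s.d. 25% at α = 0.05 and 80% power it returns 6 per group.

## 6. Synthetic-data generator

The generator emulates the measured structure of the study system; every
default is a printed value or derived from one (s.d. = s.e.m. × √n), and
the defaults *are* the study conditions — they are not tuned.

- **Field and bed**: 160 μm square field; 26 parallel capillaries
  spanning it (≈ 366 capillaries / 14 images), joined by occasional
  orthogonal connectors (probability 0.12 per adjacent pair, ~3 per
  image, a convenience default for "occasional"); junctions are true
  shared nodes splitting the parallel vessel into segments of one
  capillary id.
- **Pericytes**: a vessel is "covered" with probability 0.92 (parallel)
  or 0.66 (connector); covered vessels carry somata from a seed position
  placed uniformly and extended both ways with gamma-distributed gaps
  (mean 60 μm, CV 0.35).  The gamma family is a positive,
  CV-parameterized choice; the data show variability around the mean
  without naming a distribution.  Within a finite 160 μm window the
  *observed* gap mean is length-biased a few μm below the population
  mean (long gaps are less likely to fit entirely in the field) — the
  same censoring affects the real measurement, and the validation test
  accounts for it only through its sampling tolerance.
- **Blockages**: each parallel capillary blocks independently with the
  condition probability (sham 0.03, ischaemia 0.40,
  ischaemia + adenosine 0.30, terazosin arms 0.488 / 0.447).  In
  *associated* mode the blockage sits at a half-normal arc offset from a
  randomly chosen soma, scale set so the offset median is 3.6 μm
  (σ = 3.6 / z₀.₇₅ ≈ 5.34 μm; an exponential alternative is provided —
  only the observed median constrains the choice), direction random,
  clamped to the vessel; capillaries without somata fall back to uniform
  placement.  In *random* mode placement is uniform over the capillary —
  exactly the generative counterpart of the null model, which is what
  makes the calibration test meaningful.
- **Profiles**: one per blocked capillary; plateau 1, logistic drop at
  the blockage with 10–90% width 3 μm, additive Gaussian noise
  s.d. 0.05, on a 0.2 μm grid, scaled to arbitrary fluorescence units
  over a constant background.
- **Diameters**: soma-site diameter normal with condition mean (sham
  5.38 μm; ischaemia −37%: 3.39 μm; adenosine +21% over ischaemia:
  4.10 μm) and a shared CV of 0.232 (sham s.d. 1.25 = 0.28 × √20; no
  spread is printed for the other conditions, so the sham CV is carried
  over); ratio normal with condition mean/s.d. (1.058 / 0.067,
  0.822 / 0.170, adenosine 0.995 — 0.822 × 1.21, i.e. the upstream
  diameter assumed unchanged from ischaemia — with the ischaemia s.d.);
  upstream diameter = d_soma / ratio.  Draws are truncated away from
  non-physical values (< 0.2 μm), a negligible-mass correction.
- **ROI maps**: shape 1 with posterior elevation 1.2 on ROIs 4–6 (a
  "somewhat higher" default) and the condition risk-zone multiplier on
  ROIs 7–10 (sham 1.0; ischaemia 0.51, the 49% deficit; adenosine
  0.51 × 1.57, the 57% rescue), times log-normal heart-level and
  per-ROI noise (both σ = 0.10, invented plumbing at a magnitude that
  reproduces study-like scatter).  Heart-level noise cancels in the
  per-heart max normalization by design.
- **Cohorts**: 5 sham, 6 ischaemia, 8 adenosine hearts; 3 image stacks
  per heart (19 hearts × 3 = 57 stacks, the same order as the study's 75
  stacks in 12 animals).

Randomness is handled through one spawned `SeedSequence` stream per
artifact, so regenerating with the same configuration and seed is
byte-identical and adding one output never perturbs another.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: optical blur, segmentation error and annotation
misplacement; tortuous or 3-D vessel paths (vessels are straight and
planar); within-heart correlation of blockage events and diameters
(capillaries and pericyte sites are independent given the condition);
flow directionality and haemodynamics; pericyte process anatomy beyond
the soma point.  Recovery tests demonstrate that the pipeline's
estimators are unbiased and correctly calibrated *under the stated data
model at the study's sample sizes*, not that the biological effects are
real — that evidence belongs to the original measurements.

## Calibration notes and known limitations

- In the observed-vs-null comparison each blockage is drawn from its own
  capillary's null, one draw per capillary — a stratified rather than
  i.i.d. sample from the pooled mixture.  Stratification lowers the
  dispersion of the empirical CDF, so the one-sample KS test is mildly
  conservative: its measured rejection rate under random placement is
  ≈ 0.035 at nominal 0.05 (1500 replicates).  This conservatism is
  inherent to the design (the null is built from the same images that
  yield the observations) and is left uncorrected; the test is anti-
  conservative in no regime we measured.
- The two-sample variant against the n-point equi-probability reduction
  is substantially more conservative still (the reduction has no
  sampling noise) and is co-reported for figure parity, never used as
  the primary inference.
- Kink detection in the null model relies on exact pairwise
  intersections of slope-±1 lines; degenerate coincident candidates cost
  only spurious zero-length intervals, which are dropped.  Distances and
  masses are exact up to float rounding; no tolerance enters the
  construction itself.
- The blockage-detection thresholds are operational conventions; on real
  data with different noise spectra the smoothing window and the
  0.8/0.2/5 μm criterion should be re-examined against annotated
  examples before use.
- `intersoma_distances` is quadratic in the somata per capillary (pair
  adjacency via triangle checks); fields with hundreds of somata per
  vessel would need a chain-ordered implementation.
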