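# Methods

This note documents the models and procedural choices behind `shorefid`:
what each stage assumes, which parameters matter, what the synthetic data
emulate (and do not), and where the design was genuinely open.

## Geometry

All distances are great-circle distances on a sphere of mean radius
6371.0088 km.  At the scales that drive the analysis (5 km/h stationarity,
25 km site radius, 50 km merge/revisit distance) the < 0.5 % deviation from
an ellipsoid is immaterial, and spherical formulas are robust for
dateline-crossing tracks to the East Russian Arctic.  Centroids are
normalized means of unit vectors ("spherical centroids"); they are
undefined (and raise) for antipodally balanced point sets, which cannot
occur for the ≤ 50 km clusters this pipeline builds.  The smoother works in
a local azimuthal-equidistant plane centred on each track's median
position, which preserves distances and bearings from the centre.

## Argos filtering

Standard Argos classes 3/2/1 (nominal 68th error percentile < 2.5 km) are
always retained.  An auxiliary-class fix (0/A/B/Z; 10–30 km) is retained if
it is *redundant* — within `maxredun_km` = 10 km of a temporally adjacent
retained fix — or if both implied segment speeds to its adjacent retained
fixes are ≤ `vmax_kmh` = 120 km/h.  Unlike single-pass filters, violations
are resolved iteratively: the fix with the largest minimum implied speed is
removed first (ties broken by earlier timestamp) and speeds are recomputed,
which makes the result independent of scan order and guarantees
termination.  Published hybrid Argos filters add angle heuristics and
internal state beyond these two criteria; this implementation deliberately
uses only the two parameters above, which is the entire behaviour the
analysis depends on.

## Ground speed and stationarity

A fix's ground speed is the **maximum of its two adjacent segment speeds**
(terminal fixes use their single segment); a fix is stationary when that
speed is strictly below 5 km/h.  The two-sided definition matters under a
duty cycle: after a 25 h off period *any* fix has a near-zero
preceding-segment speed, so a one-sided (preceding-segment) definition lets
15 km-class auxiliary error outliers through the stationarity gate.  Those
outliers form small satellite clusters 30–45 km from a genuine site, are
merged under the 50 km rule and then violate the 95 %-within-25-km site
containment guarantee.  A genuine stay has slow segments on both sides, so
the max rule keeps true stationary fixes while rejecting one-sided
artefacts; in simulation it removes all containment violations over 200
replicate tracks at no cost in site-count recovery (200/200).  The price is
that the single boundary fix at each end of a stay can be classified as
moving, which the arrival/departure extrapolation step absorbs.

## State-space smoother

Position error is optionally reduced before stop detection with a
continuous-time random-walk model: state is true position in the local
plane, process covariance σ²Δt·I between consecutive fixes (irregular
sampling enters through Δt; no interpolation to a grid), and per-fix
observation covariance taken from the Argos error ellipse (semi-axes
treated as 1-σ extents, rotated by the orientation) or, without an ellipse,
an isotropic class default calibrated so the implied radial 68th percentile
matches the class accuracy (3/2/1 → 0.25/0.5/1.5 km; 0/A/B/Z → 5/8/15/15 km;
for an isotropic bivariate normal the radial 68th percentile is
σ·√(−2 ln 0.32) ≈ 1.51 σ).  σ is estimated by maximizing the innovations
log-likelihood with a bounded golden-section search on log σ over
[0.01, 100] km/√h (relative tolerance 1e-4); fitted positions come from the
RTS smoother.  The first innovation is excluded from the likelihood (diffuse
start).  Tracks with fewer than 4 fixes pass through unchanged.

This is a position-only model.  Velocity-state (correlated random walk)
models fitted by purpose-built telemetry packages are more faithful during
directed flight, but at the 25–50 km scale of site assignment the
position-only smoother is sufficient, and a single σ shared between
residency and migratory flight limits how much it can shrink outliers —
which is why smoothing is optional and the stop-detection stage is designed
to be robust on raw filtered tracks.

## Stop-site identification

Per individual and migration season (northward: fixes dated 1 Mar–30 Jun;
southward: 1 Jul–30 Nov; both configurable), stationary fixes inside the
staging region are clustered by complete-linkage agglomeration on the
great-circle distance matrix.  The cluster count k is chosen by mean
silhouette width over k = 2…min(n−1, 15), ties to the smallest k.  The
silhouette is undefined at k = 1, so the one-cluster case is decided by the
site notion itself: if ≥ 95 % of all points lie within 25 km of their
common centroid, a single cluster is returned without consulting the
silhouette.  While any cluster has > 5 % of members beyond 25 km of its
centroid, clustering is repeated with k+1 (capped at n−1, with a warning if
the cap is hit) — a deterministic operationalization of "re-cluster until
compact" that makes monotone progress.  Sites with centroids closer than
50 km are then merged, closest pair first, with member-weighted spherical
centroids, until all pairwise distances are ≥ 50 km; sites with fewer than
3 members or spanning less than 2 h are discarded.

Arrival and departure are extrapolated to the crossing of the 25 km site
radius assuming constant speed along the segment between the terminal
member fix and the adjacent track fix:
t_dep = t_last + Δt·max(0, 25 − d_last)/d_seg (clamped to the segment), and
symmetrically for arrival; missing neighbours fall back to the member times.
The extrapolation uses the site radius rather than the centroid so that a
bird photographed mid-departure is not credited with extra residence time.

Everything in this stage is deterministic given input and configuration.

## Fidelity metrics

**Non-breeding (tracking).**  Each individual is windowed from release to
one week before the first departure date of a tracked conspecific
(22 March for Great Knots, 4 April for Bar-tailed Godwits), excluding
pre-migratory movements.  The stop-site machinery runs on the windowed
track with no regional gate; an individual *moved* if it used ≥ 2 sites
(which are ≥ 50 km apart by construction) or a site > 50 km from its
release site.  Note the consequence of the 50 km site scale: excursions
shorter than ~50 km merge into the home site and are not counted as moves.
Post-migration return is assessed on the first stop site of ≥ 7 days after
the track's northernmost point, south of latitude −10°; the 7-day residency
threshold is this package's construction for "settled".

**Migration (tracking).**  From the first tracked migration, a southward
site is a revisit when its centroid is within 50 km of any northward site
centroid; the degree of fidelity is the proportion of southward staging
time (extrapolated arrival→departure) spent at revisited sites.  The
proportion is invariant to splitting a stay into contiguous sub-stays.

**Resighting.**  Records are assigned to periods: staging-region records in
the seasonal windows are northward/southward passage (the staging region
takes precedence over the calendar in November, when the southward and
non-breeding windows overlap); other records dated 1 Nov to a week before
the species' first departure belong to the non-breeding period of the year
containing that 1 Nov.  Only periods with ≥ 2 sightings qualify, and an
individual contributes one datapoint per summary (maximum site count across
its qualifying years) to avoid pseudo-replication.  Two sites match if
their ids are equal or their coordinates are within 50 km, consistent with
the ~50 km resolution at which band resightings are reported; site ids
missing from input are synthesized from coordinates snapped to a 0.25°
grid (~27 km).  Seasonal matches are computed per year and pooled (an
individual matches if any year matches); between-year matches require the
same site in ≥ 2 distinct northward seasons, with single-season individuals
excluded from the denominator.

## Inference

The Fisher test is exact and two-sided by the probability-mass convention:
with both margins fixed, the p-value sums the hypergeometric point
probabilities of all tables as or less probable than the observed one, with
a relative tie tolerance of 1e-7 guarding floating-point comparisons of
mathematically equal weights; computation is via log-gamma.  A zero margin
gives p = 1.  This is the convention of R's `fisher.test`, which the test
suite uses as an independent cross-check alongside an exact-integer
enumeration oracle.

The fractional regression is a quasi-binomial GLM with logit link:
logit E[y] = β₀ + β₁·group, fitted by IRLS, with dispersion estimated by
Pearson χ²/df and normal-based Wald inference for β₁.  Point estimates are
scale-free; the dispersion only inflates the standard errors.  Whether the
original analysis used model-based or dispersion-adjusted errors is not
knowable from the text; the dispersion-adjusted choice is the conservative
canonical reading.  Perfect separation (one group all 0, the other all 1)
has no finite MLE and falls back, flagged, to an exact rank test.  A
perfectly fitted response (e.g. constant y) has zero dispersion and an
undefined Wald test; NaN is reported rather than a fabricated p.

## Synthetic data

The generator draws, per individual: a non-breeding residency at the origin
site (release early–mid October, departure at the species' first-departure
date); with the configured mover probability, one mid-season excursion of
80–920 km (templates matching the observed move distances; movers beyond
900 km settle rather than return); a northward itinerary of 1–4 staging
sites spaced 110–240 km along the staging coast (site-count distributions
giving medians of 2 for godwits and 3 for knots); Arctic breeding
residency; and a southward itinerary that reuses each northward site with
the species' revisit probability (defaults 0.85/0.6), replacing
non-revisited sites with fresh ones 60–95 km off-coast.

Telemetry is emitted only inside the 8 h-on windows of the 33 h duty cycle
(fix interval 2 h, random per-individual phase), with location classes
drawn from a fixed mixture and isotropic Gaussian errors whose radial 68th
percentile matches the class scale; auxiliary-class fixes additionally
spike 200–800 km with probability 0.02 to exercise the filter.  Real Argos
errors are heavier-tailed and anisotropic; a Student-t (df = 4) option
exists and is off by default.  Within-site wander is a 1.5 km-scale
jitter — no tidal or foraging structure.  Transits are great circles at
45–65 km/h with no wind drift.  Resighting surveys visit a configurable
(site, date) schedule (default: weekly at the origin); a bird within 25 km
of a surveyed site on the survey date is recorded with the detection
probability, and never recorded elsewhere.

Passing tests on these data therefore demonstrate that the pipeline's
logic — filtering, clustering, merging, counting, matching, testing — is
correct under realistic error magnitudes and observation schedules; they do
not demonstrate robustness to tide-driven roost rotation, heavy-tailed
error bursts, tag failure mid-season, or behaviourally correlated movement,
none of which the generator emulates.

The study-design preset (`paper_like_config`) fixes the cohort at 24
godwits (no movers) and 41 knots with exactly 7 movers, non-breeding season
only; the test suite and acceptance script run it end to end and require
the recovered single-site percentages (100 % / 83 %) and the exact test
(p = 0.04) to emerge from the telemetry itself.

## Problem sizes

Simulation-based checks use 200 replicate individuals for the site-count
recovery and site-invariant properties, 500 replicate datasets (n = 50 per
group) for the fractional-logit coverage property, 100 simulated cohorts
(n = 25) for the resighting-underestimation property, and the 65-track
preset for the end-to-end check; the exhaustive Fisher oracle covers every
2×2 table with total ≤ 60.

## Known limitations

* The smoother shares one process scale across residency and migratory
  flight; it under-smooths residency on full-year tracks.  Stop detection
  does not depend on it.
* Seasonal splitting is calendar-based; a bird staging outside the
  configured windows would be missed (the net-displacement sign is logged
  as a consistency check but not acted on).
* Sites are hard 25/50 km constructs; biological "sites" with elongated
  coastal geometry may be split or merged differently than an expert would
  draw them.
* The non-breeding mover classification cannot see moves below the 50 km
  site scale, by design.
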