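# shorefid

Site-fidelity analysis for satellite-tracked and mark-resighted migratory
shorebirds.

Long-distance migrant shorebirds such as Bar-tailed Godwits (*Limosa
lapponica*, BTG) and Great Knots (*Calidris tenuirostris*, GK) spend the
austral summer at non-breeding sites in Northwest Australia and stage along
the Yellow Sea coast on their way to and from Arctic breeding grounds.  How
faithful individuals are to these sites — and how that differs between
species facing intertidal habitat loss — can be measured from two very
different data types: Argos satellite-telemetry tracks and resightings of
colour-banded individuals.  This package implements the full analysis
pipeline for both, plus a synthetic-data generator with known ground truth
so that every stage can be validated end to end.

## What it does

1. **Argos quality control** (`shorefid.argos`) — standard location classes
   (3/2/1) are kept unconditionally; auxiliary classes (0/A/B/Z) are kept
   only if within 10 km of a temporally adjacent retained fix (redundant
   distance) or if both implied segment speeds are ≤ 120 km/h (maximum
   sustainable rate of movement), removing worst offenders iteratively.
2. **State-space smoothing** (`shorefid.smoother`, optional) — a
   continuous-time random-walk Kalman smoother in a local
   azimuthal-equidistant plane, with per-fix observation covariances from
   the Argos error ellipse or class-calibrated defaults; the process scale
   σ (km/√h) is estimated by maximum innovations likelihood.
3. **Stop-site identification** (`shorefid.stopover`) — stationary fixes
   (both adjacent segment speeds < 5 km/h, inside the staging region) are
   clustered by complete-linkage agglomeration on great-circle distances
   with the number of clusters chosen by mean silhouette width; clusters
   must hold ≥ 95 % of members within 25 km of their centroid (re-clustered
   at k+1 until they do); centroids closer than 50 km merge; sites need
   ≥ 3 members spanning ≥ 2 h; arrival/departure times are extrapolated to
   the 25 km radius crossing.
4. **Fidelity metrics** (`shorefid.tracking_fidelity`,
   `shorefid.resighting_fidelity`) — non-breeding single-site vs mover
   classification; post-migration return to the origin; seasonal revisit
   (southward site within 50 km of a northward site) and the proportion of
   southward staging time spent at revisited sites; resighting-based site
   counts per period with ≥ 2-sighting filters and
   max-across-years collapse.
5. **Inference** (`shorefid.stats`) — exact two-sided Fisher tests
   (probability-mass convention, log-gamma enumeration) and fractional
   logit (quasi-binomial) regression for proportions.
6. **Simulation** (`shorefid.simulate`) — duty-cycled (8 h on / 25 h off)
   Argos-like telemetry with class-dependent error (68th radial percentiles
   0.25–15 km), outlier spikes, multi-site migratory itineraries, and
   survey-based resightings with imperfect detection — all reproducible
   from a seed, with truth tables as first-class outputs.

## Worked example

Generate the study-design synthetic cohort (24 godwits, 41 knots, 7 of the
knots programmed to move between non-breeding sites) and run the full
tracking + resighting comparison:

```sh
shorefid simulate --preset paper-like --seed 7 --out sim
shorefid report --tracks sim/telemetry.csv --resightings sim/resightings.csv \
    --out-dir rep --no-smooth
```

which prints

```
Tracking data
=============
nonbreeding BTG: n=24, movers=0, pct_single_site=100.0
nonbreeding GK: n=41, movers=7, pct_single_site=82.9
nonbreeding: table [[24, 0], [34, 7]], Fisher p = 0.041 (two-sided, probability-mass convention)

Resighting data
===============
nonbreeding_sites: table [[24, 0], [41, 0]], Fisher p = 1.000
```

Reading this: the pipeline recovered every programmed mover from the noisy,
duty-cycled telemetry — all 24 godwits stayed at a single non-breeding site
while 7 of 41 knots (17 %) moved, a species difference with exact p = 0.04.
The resighting analysis of the same simulated birds, surveyed only at the
origin site with detection probability 0.8, sees *no* movers at all
([[24, 0], [41, 0]]): movements to unsurveyed sites are invisible, which is
exactly why resighting data underestimate movement relative to tracking.

The same machinery is available as a library:

```python
from shorefid import (Contingency2x2, fisher_exact_two_sided,
                      read_tracks, filtered_track, build_itinerary)

p = fisher_exact_two_sided(Contingency2x2(24, 0, 34, 7)).p_two_sided  # 0.0407
for track in read_tracks("sim/telemetry.csv"):
    itinerary = build_itinerary(filtered_track(track))
```

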