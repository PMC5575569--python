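# Methods

## The monitoring model

`streetcount` treats a street survey as a strip transect along public
streets: the buildings bound the strip, observers apply constant search
effort, and the count of roaming dogs divided by route length is a
relative-abundance index (dogs·km⁻¹). Detectability is assumed constant
across surveys — enforced by protocol (same routes, transport mode, speed,
time of day and season) rather than estimated — so the index is valid for
*comparisons*, not for absolute abundance. Absolute totals are supported
only as an optional extrapolation (`extrapolate_total`) from
representative routes with an externally supplied total street length and
detectability, and are refused for hotspot routes, which oversample
high-density areas by design.

Two protocol facts shape the data model. First, every route is surveyed at
least twice on consecutive days within a *survey event*; the replicate
pair is what identifies day-to-day noise. Second, observers classify each
dog at sight into seven exclusive classes (male, female, lactating female,
unknown adult, pup, sterilised male, sterilised female) plus a 1–5 body
condition score and a visible-skin-condition flag.

## Power to detect a density change

With `n` routes and per-route replicate density differences `d_i`, the
mean difference divided by its standard error is Student-t with `n−1`
degrees of freedom. The minimum detectable change at two-sided level α is
`t_{1−α/2,n−1}·SE`, reported both absolute and as a percentage of the
baseline mean. Design choices:

- Events with more than two replicates contribute their earliest pair.
  The statistic is defined for pairs; mixing pairings of unequal variance
  would invalidate the `n−1` degrees-of-freedom claim.
- α is two-sided throughout (a change in either direction matters to a
  programme evaluator).
- `min_detectable_change` also accepts `(n, se_diff)` directly so
  published summaries can be analysed without the raw differences.
- The Monte-Carlo validation of the threshold tests the distributional
  claim itself: for each simulated null survey pair, the observed
  |mean difference| is compared against that pair's own `t·SE` threshold.
  Under the null this is an exact level-α t-test when differences are
  near-normal. Designs that compare a *separately estimated* SE against a
  later survey's change are not exactly pivotal (the numerator either
  shares replicates with the SE estimate or has a different variance), so
  the pairwise form is the one for which the t claim holds and the one we
  calibrate.

## Power to detect a composition change

The pooled two-proportion z test, built from first principles: pooled
fraction `p̄ = (k1+k2)/(n1+n2)`, null sd `√((1/n1+1/n2)·p̄(1−p̄))`,
significance iff `|p̂1−p̂2|` exceeds `z_{1−α/2}` times that sd.
`required_second_sample` inverts the test by ascending integer search on
`n2`, recomputing the pooled fraction at each candidate with expected
counts rounded to the nearest integer (`k2 = round(p2·n2)`); the search is
preceded by a closed-form reachability check at the `n2 → ∞` limit, where
the null sd tends to `√(p2(1−p2)/n1)`. The normal approximation's
adequacy is quantified in the tests: its accept/reject decision agrees
with an exact two-sample binomial null distribution (computed from the
outer product of the two binomial pmfs at the pooled fraction, not by
finite resampling) in ≥95% of random small configurations.

## Between-location and over-time comparisons

- **ANOVA** (dogs/km by location): classical between/within sums of
  squares, df `(k−1, N−k)`. All-identical input returns `F = 0`, not an
  error.
- **Kruskal–Wallis** (percentage indicators by location): mid-ranks with
  the standard tie correction `1 − Σ(t³−t)/(N³−N)` — percentage columns
  tie at 0.0 frequently, so the correction matters. Undefined percentages
  propagate as missing and are excluded before ranking, never coerced to
  zero. The default p-value is the chi-square approximation; an exact
  permutation p (full enumeration of distinct group assignments, capped at
  10 values) is available and is verified against an independent
  enumeration oracle.
- **Trend**: OLS of the event-average index on decimal-year time (repeat
  surveys are unequally spaced, so calendar dates are used, not indices).
- Both location tests operate on route-level event averages — the
  granularity of the bundled indicator table. The bundled table's density
  ANOVA reproduces the published F (10.943) exactly at that granularity,
  and the BCS 1-or-2 H within 0.4%; the published H values for
  % lactating, % skin and % BCS 1 evidently derive from replicate-level
  values that were plotted but never published, so for those the
  route-level H is validated against an independent implementation rather
  than against the printed numbers. Rank statistics are sensitive to this
  granularity choice; density F is not affected because the event average
  is the published quantity itself.
- No multiple-testing correction is applied across the four indicator
  tests; users comparing many indicators should apply their own.

## Indicator conventions

- % lactating is taken over identified females: female + lactating female
  + sterilised female (`females_include_sterilised=False` restricts to
  intact females). Pups count in density and welfare denominators only.
- Within an event, density is the mean of per-replicate densities while
  composition pools raw counts across replicates — pooling stabilises the
  small per-replicate counts behind the percentages.
- A zero denominator makes a percentage *undefined* (`None`/NaN), never 0.
- Abbreviated BCS protocol (used where dog volume makes full scoring
  impractical): observers assess every dog but record a score only for
  emaciated dogs. With `abbreviated_bcs=True` the % BCS 1 denominator is
  all dogs and % BCS 1-or-2 is undefined — matching how such surveys
  report (without the flag, a survey recording only BCS-1 dogs would
  nonsensically report 100% BCS 1 among "scored" dogs).

## Geometry and formats

Route length is the haversine sum on a sphere of radius 6371.0088 km
(IUGG mean radius); the sub-0.5% error versus an ellipsoid is negligible
against day-to-day count variation. Lengths beyond the protocol's usual
20 km maximum raise a warning, not an error. Only the first LineString of
a KML is read (multi-segment routes must be pre-merged). GPX waypoint
names are mapped to (class, BCS, skin) triples through a `LabelMap`; the
bundled default composes the seven class labels with optional `BCS1..5`
and `Skin` suffixes (84 labels) and is overridable via YAML for other
button layouts. Observation logs whose timestamps fall outside the
declared survey date are rejected, guarding against concatenated logs.

## The simulator

Generative model per replicate survey:

```
λ_r = λ · exp(σ_route·Z − σ_route²/2)        route effect (log-normal, mean λ)
N   ~ Poisson(λ_r · L · exp(σ_day·Z − σ_day²/2))   day effect (mean 1)
```

Each of the `N` dogs is placed uniformly along the route polyline with
monotone timestamps and draws class, BCS and skin independently.
Marginally the counts are over-dispersed relative to Poisson, as repeat
street counts are. Routes themselves are smoothly meandering spherical
walks whose haversine length is within 0.1% of the target.

Defaults are the conditions of the replicated 21-route metropolitan
baseline that motivates the power analysis: `n_routes=21`,
`lambda_per_km=10.54`, `route_length_km=20` (the protocol's usual maximum
for vehicle-surveyed routes — at the default λ, shorter routes would make
Poisson counting noise alone exceed the observed day-to-day variation),
`p_lactating_given_female=0.08`, `sigma_route=0.3` (between-route spread
of the order seen across published route tables), and `sigma_day=0.0541`,
calibrated so that the model-implied sd of a replicate density difference
(`predicted_replicate_diff_sd`: `√(2(λ/L + λ²·e^{σ_route²}·(e^{σ_day²}−1)))`)
equals `0.29·√21` — the published standard error of the mean replicate
difference in that baseline. Sterilised classes default to probability
zero (most monitoring locations do not mark sterilised dogs); the
lactation flag is applied to intact females so the pooled lactating
fraction equals `p_lactating_given_female` exactly. `bcs_probs`
defaults to (0.01, 0.14, 0.45, 0.30, 0.10) — emaciation rare, as observed
— and `p_skin=0.08`, mid-range of published skin-condition percentages.

All randomness derives from a single integer seed through per-purpose
child streams (route geometry, replicate draws, route effects), so equal
seeds reproduce datasets bit-for-bit while routes and replicates stay
independent.

What the simulator deliberately does **not** model: dog packs or spatial
clustering (the analysis uses only totals), movement and double-counting
(the protocol is designed to prevent it), seasonal cycles (the protocol
mandates same-season comparison), observer-specific detectability, and
ownership structure. Passing tests therefore show that the procedures are
correct *under the stated sampling model*, not that field data satisfy
that model; in particular, real day effects may be correlated across
routes (weather), which would inflate the SE the power analysis estimates
and is invisible here.

## Problem sizes and numerical choices

The validation studies use: 4000 simulated null survey pairs for the
type-I error envelope (99% binomial envelope around α=0.05), 500 random
configurations for the two-proportion adequacy check, 1000 replicates for
density recovery (2-standard-error band), and full enumeration for the
exact Kruskal–Wallis instances. Statistic comparisons against independent
implementations use relative tolerance 1e-10; geometric comparisons
account for the 7-decimal coordinate precision of emitted KML/GPX
(~1 cm/vertex). Ties in permutation enumeration use a 1e-12 slack on the
`≥` comparison so mid-rank ties do not flip on floating-point noise.

## Known limitations

- The index is only as comparable as the protocol is constant; the
  package checks file-level consistency (dates, labels, route identity)
  but cannot detect effort drift.
- `required_second_sample`'s integer rounding of expected counts makes
  the required `n2` occasionally non-monotone in small neighbourhoods;
  the ascending search returns the smallest qualifying value by
  construction.
- The t-based threshold assumes near-normal replicate differences; at
  very low densities (λL ≲ 5 counts per survey) the discreteness of the
  counts makes it approximate.
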