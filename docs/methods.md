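# Methods

`burplan` models the quantitative design questions behind a spring-projected,
capture-free tagging station ("bur-tagging"): where a projected tag lands on a
moving animal, whether it will stay attached, and how long a station must be
deployed before a target animal presents itself for tagging. This note records
the models, their assumptions, the defaults, and the numerical choices.

## Ballistics and placement error (`gate_ballistics`)

The tag is fired vertically down from a dispenser at height `D_trajectory`
above the animal's back. The canonical flight model assumes **constant tag
speed** over the drop:

- flight time: `T_flight = D_trajectory / S_tag`
- along-track offset (how far behind the ideal spot the tag lands, because
  the animal keeps walking): `D_animal = S_animal · D_trajectory / S_tag`
- radial error from an angular deviation Θ of the trajectory:
  `D_error = D_trajectory · sin Θ`
- impact force over a fur-deformation distance d: `F = ½ m v² / d`

Drops in practice are 0.1–0.5 m and tag speeds several m s⁻¹, so the
constant-speed approximation errs by only a few percent; an optional
gravity-augmented mode (`flight_time(..., gravity=True)`, solving
`D = v₀t + ½gt²`) is available for long drops but is not used for any
reported value. Launch speed from a compression spring uses the energy
balance `½kx² · efficiency = ½mv²`; `efficiency` (default 1.0) lumps barrel
friction and spring-mass losses, and gravity work over the short stroke is
neglected.

The **sensor-placement rule**: for the tag to land on the ideal spot
whichever way the animal approaches, the two trigger sensors must sit
symmetrically about the point under the dispenser, each at the animal's
first-trigger-point-to-ideal-spot distance.

`simulate_landings` composes these pieces into a seeded Monte Carlo. Per
draw: trigger latency ~ Uniform(0, poll interval) (default poll 0.1 s, the
controller's sensor polling period) is added to the flight time before the
along-track offset; Θ ~ Normal(mean, sd) truncated to [0°, 90°]; the landing
sector is categorical over 8 compass sectors; flipping is Bernoulli. Angle
and sector are sampled independently — the simplest model consistent with
separately-reported angle statistics and sector occupancies. Default error
model: mean 4.6°, sd 1.8°, flip probability 0.311, from bench trials of a
small-spring dispenser. Truncation at 0° shifts the sample mean angle up by
less than 0.03° at these defaults — negligible against its sampling error at
the simulation sizes used (n = 10⁴). The total planar miss distance resolves
the radial error into along/across components by sector (sector 1 centred on
the travel direction, numbered clockwise, 45° each) and adds the along-track
offset. Eq `F = ½mv²/d` needs a fur-deformation distance, so the simulator
takes a `fur_deformation` keyword (default 0.01 m, a typical mid-fur
compression). Sign convention: along-track offsets are positive behind the
ideal spot in the direction of travel. Identical seeds give bit-identical
tables (single `numpy` Generator, fixed draw order).

## Retention (`retention`)

Forces are in mN and masses in grams — the natural units of spring-balance
pull-off trials. The dynamic-force rule is Newton's second law with g₀ =
9.81 m s⁻²: a tag of mass m grams on an animal accelerating at a·g
experiences `m·a·9.81` mN; peak accelerations across terrestrial species
span roughly 1–7 g, so a 10 g tag can generate up to 687 mN. A tag is
flagged **at risk of detachment** when this force at the top of the
acceleration range exceeds the measured removal force of the adhesive on
that fur; the report carries the dynamic/measured force ratio.

`fit_retention_model` fits `removal force ~ driver mass + bur count +
substrate + pull direction` by OLS (statsmodels), with treatment contrasts
and the alphabetically first level as reference (recorded in the output so
coefficients are interpretable). A full multi-way ANOVA with interactions on
raw trial data is deliberately out of scope — only the main-effects
structure is reproducible from synthetic trials — but a two-way
`interactions=True` flag exists. Rank-deficient designs raise
`SingularDesignError`, naming the collinear columns found by pivoted QR.
Wet-fur effects are not modelled.

## Deployment planning (`deployment`)

The per-hour probability `P_s` that a target animal is within tagging
distance is estimated as (within-tagging-distance events for the species) /
(deployed hours). Repeat visits count as independent events, since camera
data cannot generally distinguish individuals. Hours are the fixed time
unit; if the estimate reaches 1.0 the estimator raises and instructs the
caller to use a finer unit rather than silently rescaling. The cumulative
tagging-opportunity probability over t hours is geometric,

    P_Tag(t) = 1 − (1 − P_s)^t,

assuming a constant P_s (no habituation drift) and independent hours.
Inversion gives the deployment time to a target probability,
`t = ln(1 − target)/ln(1 − P_s)`, reported both real-valued and rounded to
the nearest hour (half away from zero, so 30.8 → 31). Worked examples use
P_s rounded as displayed (0.01, 0.072) because the printed planning horizons
(229 h, 31 h) follow from the rounded rates.

Baited-vs-unbaited (or any two-condition) rate comparison is a two-sample
Poisson test: conditional on the total count, the first count is binomial
with probability proportional to its exposure, so the exact p-value is a
binomial test (Clopper–Pearson interval mapped through the odds transform
for the rate-ratio CI), with the normal-approximation Z reported alongside.

## Interaction statistics (`interaction_stats`)

Event logs have one row per animal–gate encounter (schema in
`EVENT_COLUMNS`; booleans as 0/1, ISO-8601 timezone-naive timestamps read as
local site time). Behaviour categories (look/pause/sniff) are **not**
mutually exclusive; proportion denominators are total interactions.
Attracted and repelled are mutually exclusive by validation.

Early/late neophobia contrasts split the log at the deployment midpoint;
boundary events go to the late half (arbitrary but fixed and documented).
The passage test is the Yates continuity-corrected chi-square on the 2×2
early/late × passed/not table: expected counts from marginal products, each
deviation reduced by 0.5 and clamped at 0 before squaring. The correction
with clamping is the default because it reproduces the conventional
corrected statistic exactly (verified against an independent brute-force
oracle and scipy's corrected implementation to 10⁻⁹); uncorrected Pearson is
available via `correction=False`. Trail association compares one species'
event counts across chosen trail categories against equal expected exposure
(continuity-corrected at two categories, df = 1; plain Pearson
goodness-of-fit beyond two). No multiple-testing correction is applied
anywhere; raw p-values are reported. Rounded percentage outputs may sum to
100 ± 1.

## Synthetic data (`synthetic`)

The generators emulate the statistical structure of the field and bench
data so every stage is testable end-to-end:

- **Interaction logs**: independent Bernoulli presence per site-hour (at
  most one event per hour, consistent with interpreting P_s as a
  probability, not a rate), with categorical attributes per event. Defaults
  are the reference study conditions: site rates 19/264 h⁻¹ and 1/96 h⁻¹,
  behaviour probabilities 0.29/0.30/0.41, attraction/repulsion 0.30/0.20,
  pass-through 0.74, 264 h windows. `pass_prob_late` enables habituation
  scenarios; a bait multiplier scales presence at baited sites. Real logs
  are clustered in time (nightly activity, revisits); the hourly-Bernoulli
  model is not, so passing recovery tests shows estimator correctness under
  the model, not robustness to clustering.
- **Retention trials**: `force = intercept + 379·(burs−1) + 13·driver_mass
  + direction effect + substrate effect + N(0, sd)`, floored at 0 mN.
  Default noise sd = 1030 mN, calibrated so the fitted model explains ≈22%
  of the variance at the default covariate ranges (signal variance
  ≈3.0×10⁵ mN²) — matching the noise regime of real pull-off trials.
- **Angular errors**: truncated-normal angles (defaults 4.6°/1.8°),
  categorical sectors, Bernoulli flips (0.311).
- **Fur profiles**: Gaussian-truncated-at-zero hair diameter and air-layer
  thickness per species, default layout 4 measurements × 5 individuals ×
  16 species (320 rows). The per-species parameter table is **illustrative
  synthetic configuration**, spanning realistic ranges for temperate
  mammals; it is not measured pelt data.

All generators are pure functions of scenario + seed; there is no global
RNG state.

## Problem sizes and numerical choices

Simulations use n = 10⁴ Monte Carlo draws, 200 replicates for coverage
checks (n = 500 per fit), and 264-hour deployment windows — sizes at which
the 3-standard-error acceptance bands are meaningful while runs stay
interactive. The inversion identity `P_Tag(P_s, t(q)) = q` holds to 10⁻¹²
relative tolerance via `log1p`-based evaluation. Display rounding is half
away from zero (integer mm, mN, hours, percent). Degenerate inputs fail
loudly: zero tag speed, empty logs, zero marginals, both-zero counts, and
rank-deficient designs all raise informative errors rather than returning
NaN.

## Known limitations

- No aerodynamics, spin or drag; the angular-error model is empirical, not
  mechanistic, and the spring model omits stroke-dependent losses.
- P_s is constant over deployment; habituation/neophobia drift is only
  representable through the generator's early/late pass probabilities, not
  the planner.
- The retention fit is fixed-effects only; no mixed-effects structure for
  repeated measures on individuals.
- Printed field percentages beyond the count tables (e.g. species-specific
  behaviour breakdowns) are emulated by generators, not reproduced from raw
  data.
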