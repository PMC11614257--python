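# Methods

This note documents the models, conventions and design choices behind
`mdsreval`, in the package's own terms.

## Readiness scoring

A facility's readiness is measured on four dimensions of a surveillance
system — structure (7 yes/no items), core function (11), supportive
function (10) and system attributes (26 items partitioned 7/2/5/8/4 into
simplicity, flexibility, acceptability, usefulness and stability). Each
dimension score is the raw percentage of yes answers; items are
unweighted within a dimension, and a missing response is an error, never
imputed — the scoring assumes a fully administered questionnaire. The
attributes score pools all 26 items rather than averaging subcategory
means, so subcategories with more items carry proportionally more weight;
subcategory percentages are additionally reported for inspection.

The overall composite is the weighted sum of the four dimension
percentages. Weights default to 0.25 each (the composite is then the
plain mean of the four) and must sum to 1 to within 1e-9.

**Functionality ratings.** Scores map to five bands with closed upper
bounds: ≤ 20 not functioning, (20, 50] less, (50, 75] fairly, (75, 90]
effectively, (90, 100] very effectively functioning. The conventional
integer band labels (21–50 %, 51–75 %, …) leave fractional scores such
as 50.4 unassigned; the half-open construction covers all of [0, 100],
is monotone, and agrees with the integer labels at every attainable
boundary (in particular a score of exactly 20.0 rates *not functioning*).

**Group summaries.** Group means are reported with the standard error
(sample SD / √n) and a normal-approximation 95 % interval (mean ± 1.96
SE). The normal interval, not a t-quantile, is deliberate: it is the
convention of the published summary tables this layout mirrors, and at
the group sizes involved (n ≥ 25 for every group with a reported CI)
the difference is below display resolution. With n < 2 the SE and CI
are reported as NA.

**Display rounding.** All internal arithmetic is unrounded; one-decimal
display rounding uses round-half-away-from-zero (`display_round`),
matching how published tables round, rather than Python's banker's
rounding.

## The performance index

Five indicator rates are computed per region from count aggregates
accumulated over the evaluation window, all on the percent scale:
notification rate Rₙ = dₙ/dᵢ, notification coverage CRₙ = dₙ/E(d),
review rate Rᵣ = dᵣ/dₙ, review coverage CRᵣ = dᵣ/E(d), and the reviewed
community-death proportion CRDₚ = d_rc/dᵣ. E(d) (expected deaths from
mortality estimation models and population projections) is an *input*;
the package never estimates it.

Conventions, each forced by internal consistency of the published
worked figures or by totality:

* **No capping.** Rₙ and Rᵣ may exceed 100 % — review committees review
  deaths that were never notified weekly — and the uncapped value feeds
  the composite (a capped review rate cannot reproduce the published
  regional composite extremes).
* **Undefined, not zero.** A zero denominator flags the indicator as
  undefined; the composite raises, listing the offending indicators,
  instead of silently treating them as 0.
* **Unrounded composition.** Indicators enter the composite unrounded;
  rounding happens only at display. (Both orders agree to within the
  one-decimal print resolution on the packaged panel.)
* **National aggregation** sums numerators and denominators across
  regions (it is not a weighted mean of regional indices). The packaged
  Ethiopian panel's regional expected-death values sum to 60 639 while
  the separately published national total is 60 686; the national
  computation uses the published total by default with a switch to
  recompute from the regional rows. The difference moves the national
  index by < 0.01 points.
* **Class thresholds.** low < 40 %, moderate = [40, 60] (closed at both
  ends, making the map total and deterministic; no observed value falls
  on an endpoint), good > 60 %.

## Group comparisons

Two-group contrasts use the classical pooled-variance t-test (a Welch
switch exists) so that the two-group ANOVA identity F = t² holds
exactly; one-way ANOVA is the classical sums-of-squares F-test. The
Shapiro–Wilk gate is advisory — it warns rather than blocking, because
the evaluation workflow applies parametric tests throughout and the gate
exists to surface, not enforce, the assumption. Bonferroni post-hoc
contrasts run only after a significant omnibus ANOVA (an override flag
exists); the adjustment family is all k(k−1)/2 pairwise contrasts within
one stratifier, with adjusted p = min(1, p·m), and both raw and adjusted
p-values are reported since display conventions differ between reports.
Groups with a single observation are skipped in pairwise testing (the
pooled t is undefined) and excluded from the family count.

`compare_from_summaries` is an approximate normal z-test built from
published (mean, SE) pairs alone — z = Δmean/√(SE₁²+SE₂²) — for checking
table rows when raw data are unavailable. It ignores the degrees of
freedom and the pooling of variances, so its p-values match the exact
test only to order of magnitude; results carry an `approximate` flag.

## Trend analysis

Mann–Kendall with the standard tie-group variance correction and the
±1 continuity correction in the normal approximation (a switch disables
it); Kendall's tau is reported as tau-a (S over the pair count).
Sen's slope is the median of all pairwise slopes; its confidence bounds
are the order statistics at ranks (N ∓ z_{α/2}√var S)/2 among the N
sorted pairwise slopes, linearly interpolated between adjacent order
statistics and clipped to [1, N]. Linear interpolation is chosen for
determinism; with the short series this module targets (n = 8 yearly
points, N = 28 slopes) the interpolation choice moves the bounds by at
most the gap between adjacent slopes. The module is unit-agnostic:
slopes are per year on whatever scale the series is supplied.

## Survey design

Design effect deff = 1 + (m−1)ρ with mean cluster size m and
intra-cluster correlation ρ (ρ = 0.33 is the conservative convention for
facility surveys). Stratum sample sizes start from n₀ = z²σ²/ε², apply
the finite-population correction n₀N/(n₀+N−1), then the design effect,
then ceiling, capped at the stratum population N. Applying deff *after*
the FPC is the default (a flag flips the order); the post-FPC order is
the conservative one whenever the FPC is active. σ², ε and z have no
defaults: they are survey-specific inputs. PPS allocation integerizes
the ideal shares n·N_r/N by the largest-remainder rule — the total is
conserved exactly, every region is within one unit of its ideal share,
and remainder ties break alphabetically for determinism.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not the full
richness of a real survey:

* Item responses are **exchangeable Bernoulli draws** at a per-dimension
  yes-probability (overridable per region and per item). Real items are
  heterogeneous and correlated within facilities; the generator's
  facility-level score variance is therefore the binomial
  p(1−p)/n_items, typically *smaller* than real survey variance. Passing
  recovery tests demonstrates the pipeline's arithmetic and calibration,
  not robustness to realistic item correlation.
* A facility is MDSR-implementing with probability `inclusion_prob`
  (default 400/519 ≈ 0.77, the implementing share observed in the 2020
  national evaluation); implementing facilities draw last-year
  notified/reviewed counts as 1 + Poisson(1.0)/1 + Poisson(0.5).
* Panel counts form a thinning chain: identified ~ Binomial(E(d),
  p_identify), notified ~ Binomial(identified, p_notify), **reviewed ~
  Binomial(identified, p_review)** — drawn from identified rather than
  notified so the empirically observed regime of review rates above
  100 % is reachable. This is a modelling convenience, not a claim about
  the real review process. reviewed_community ~ Binomial(reviewed,
  p_community).
* The trend series is intercept + slope·(year − year₀) + N(0, noise_sd),
  clipped to [0, 100]. Default: intercept 100 %, slope −8.33 %/year over
  2013–2020 (reproducing the observed community-review share declining
  from 100 % to ~41.7 %), noise SD 5 percentage points — a realistic
  year-to-year wobble for a national proportion series.

The `ethiopia2020` profile pins the generator to the 2020 national
evaluation's conditions: 519 surveyed facilities allocated to the 11
regions by PPS over the implementing-cohort mix, the published national
stratifier shares (59.5 % rural, 89.3 % primary level, 78.5 % ≥ 2 years
implementing, the agro-ecological mix), dimension yes-probabilities
equal to the published national mean scores (0.517/0.200/0.384/0.696),
and per-region panel probabilities derived from the packaged count panel
(p_identify = dᵢ/E(d), p_notify = dₙ/dᵢ, p_review = dᵣ/dᵢ,
p_community = d_rc/dᵣ). All randomness flows from the single config
seed via `numpy.random.default_rng`.

## Numerical and degenerate-input conventions

* Weight vectors must sum to 1 within 1e-9; anything else is a
  configuration error.
* ANOVA on fully constant data returns F = 0, p = 1 (not an error);
  zero within-group variance with between-group differences returns
  F = ∞, p = 0.
* Constant input to Shapiro–Wilk is an error (the statistic is
  undefined).
* A count panel row with reviewed_community + reviewed_facility ≠
  reviewed is a consistency error naming the region; negative counts are
  rejected; unknown categorical levels are rejected with the row index.
* Test problem sizes (10 000 null simulations for type-I calibration,
  200 replicate panels, 500 trend replicates, 200 enumeration seeds) are
  chosen so Monte-Carlo error is comfortably below the asserted
  tolerances while the full suite runs in seconds.

## Known limitations

* Item semantics are abstract: items are positional
  (`structure_1..7`, …), so the package scores any instrument with the
  same 7/11/10/26 shape but cannot validate item content.
* The summary-statistic z-test is approximate by construction; exact
  per-table p-values require the raw per-facility scores.
* No survey weights in analysis (scores are analysed unweighted, as in
  the evaluation workflow this mirrors), no seasonal Mann–Kendall or
  autocorrelation correction, no nonparametric fallbacks, and no
  estimation of expected deaths.
* The packaged count panel stores the values as published, including two
  regions printing identical review splits (78/41/37) — possibly a
  transcription artifact in the source — and a handful of printed rate
  cells that disagree with their own printed counts by up to ~0.25
  percentage points; the count-derived values are treated as
  authoritative.
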