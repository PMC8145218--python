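# Methods

This note documents the statistical procedures implemented in
`surveyconcord`, the conventions that were fixed where several defensible
choices existed, what the synthetic generator does and does not emulate, and
the package's known limitations.

## Records and coding rules

A record is one prevalence estimate (percent, 0–100) from one source at one
place and time. Sources are of two kinds: `reference` (large public
household-survey programmes) and `field` (small purpose-run surveys).
Geography is a 5-level administrative hierarchy — 1 village/town/locality/
traditional authority, 2 district, 3 province/state/department/county,
4 region, 5 country — and each record carries an ordered `geo_path` of place
names from the country down to its own unit. Paths may skip tiers (a province
directly under a country) but cannot be deeper than the hierarchy allows for
the declared level. Unit-type words are mapped to levels through an editable
synonym table with per-country overrides, because the same word sits at
different levels in different countries ("county" is a level-3 unit in
Liberia but a level-2 unit elsewhere).

Years: a survey collected within one calendar year keeps that year; a survey
spanning two consecutive years is coded at the first year + 0.5
(2013/14 → 2013.5). Year gaps between matched records are therefore
multiples of 0.5. A generous plausibility window [1990, 2035] catches typos
without blocking reuse.

Estimates based on fewer than 10 observations are excluded before any
pairing; the boundary is inclusive-keep (n = 10 stays).

Composite geographies ("Nghe An+Cao Bang+Kon Tum") are declared as single
path elements in the input table, never inferred: the table author states
which reference unit (often itself a composite) contains them.

One extension beyond the minimal schema: an optional `cohort` tag. Reference
extracts are sometimes tailored to one field survey's eligible population
(same age ranges, same sampled subpopulation), so two reference rows can
legitimately share source, geography, year and indicator while carrying
different n and estimates. The cohort tag keeps such rows distinct and
restricts matching to the intended extract; it is empty (and inert) for
ordinary tables.

## Matching

For each field record, the reference cycle is chosen first: the most recent
cycle at or before the field year. If only later cycles exist the earliest
one is used and the pair is flagged `fallback=True` (posterior match) —
allowed by default because such matches occur in practice when a public
survey ran a year after the baseline; callers can filter on the flag or
disallow it. Geography is then resolved within that cycle: the identical
unit at the same level if present, otherwise the nearest ancestor by path
prefix, climbing one level at a time, never downward. Unmatched field records
are reported with a reason, not dropped silently.

Same-source scenario pairs mimic these matching conditions inside one
source: S1 (same unit, different cycles; earlier cycle plays the reference
role), S2 (same cycle, a higher-level unit against each strictly contained
lower-level unit), S3 (earlier cycle at the higher level vs later cycle at
the lower level). Same-year-same-level pairs are never emitted. S2 is
anchored at the earliest cycle by default — the reference side represents the
pre-existing public estimate — with an `s2_cycle="all"` option for every
cycle. This anchoring is a genuine design choice: the source material for
this design is not self-consistent about which cycle same-year comparisons
should use, and the worked example the package reproduces anchors them at
the earlier cycle.

All signed quantities are reference minus field (difference in pp, year gap,
level gap); unsigned bands (level 0/1/2+, years ≤1 / 1.5–3 / ≥3.5) are used
for stratified tables. Both are stored.

## Concordance summaries

Conventions, fixed once and used everywhere:

* "within k" means |difference| ≤ k percentage points, inclusive; k is in
  points, not relative percent, because every input table is on the percent
  scale;
* sample SDs (n−1), reported as missing for single-pair groups;
* quantiles by linear interpolation (numpy default); medians and IQRs in the
  stratified tables inherit this rule, which matters at small n;
* box plots follow Tukey: whiskers at the furthest observations within
  1.5×IQR of the quartiles, points beyond counted as outliers;
* sample-size tertiles are rank-based thirds of the chosen member's n over
  the pair set at hand, stable under ties, lowest third = Tertile 1;
* reference-value bins are half-open [lo, lo+w) with the top bin closed at
  100.

## Variance partition

The partition is sequential (Type I): factors enter the least-squares design
in a fixed, recorded order — indicator, level band, year gap (a single
linear term), season concordance; season is omitted in same-source mode,
where a single survey programme collects in essentially one season within a
country. Each factor's share is the drop in residual SS when its columns are
appended, divided by the total corrected SS. Sequential SS was chosen over
Type II/III because it is the only decomposition that is exactly additive —
shares plus residual ("other") sum to 100 — which is how partition tables in
this literature are presented. The cost is order dependence, which the result
object records; orthogonal designs are order-invariant (tested).

Implementation is by incremental least squares (`numpy.linalg.lstsq`) on
nested design matrices with treatment-coded categoricals; minimum-norm
solutions make rank-deficient augmentations (a factor collinear with earlier
ones, or single-level) contribute exactly 0. A brute-force one-way oracle
(SS_between/SS_total from group means) and statsmodels' Type I ANOVA table
serve as independent cross-checks in the tests. No F-tests or p-values are
produced: the output is a descriptive decomposition, not inference.

Exact share values from any particular study are not reproduction targets:
they depend on the full pair set, the factor order and the SS type, of which
only the machinery is specified here.

## Sampling-error simulation

Two estimates of the same true prevalence p, each from n independent
observations, are simulated as independent binomial(n, p) counts;
the signed difference is 100(B₁−B₂)/n pp. Defaults are the study
conditions: p ∈ {1, 10, 20, …, 90, 99}%, n = 500 (a typical per-indicator
sample in both source kinds), 1,000 iterations. The closed-form SD of the
difference, 100·√(2p(1−p)/n), ties the simulation to theory in the tests
(within 3 Monte-Carlo standard errors at every grid p).

The headline quantity is the maximum over the grid of the Tukey upper
whisker of |difference|. The whisker — not the absolute maximum — is the
right reading of a box-plot-based "range": at p = 0.5 the maximum of 1,000
draws exceeds 10 pp with non-trivial probability even under pure sampling
error, while the whisker stays near 7–8 pp. A 95% normal CI half-width
helper (1.96×SE) accompanies the simulation for the common back-of-envelope
check (SE 5 pp → ±9.8 pp).

Seeding: one root seed; each grid prevalence gets an independent child
stream (`SeedSequence.spawn`), so per-p results are invariant to the rest of
the grid.

## Synthetic landscapes

The generator emulates the mechanisms hypothesized to drive cross-source
discordance, composed additively on the logit scale so effects never leave
(0,1):

logit p(i, g, t, s) = μ_i + Σ_levels a_unit + β_i(t−t₀) + γ_i·1[s=wet]

with μ_i uniform on logit([0.05, 0.95]) (covering the whole reference-value
range), nested geographic effects a ~ N(0, σ²_level) per region/province/
district/village, indicator-specific linear drift β and wet-season shift γ.
Method bias is a per-(source, indicator) logit shift δ applied before
sampling — different questionnaires, training and frames measure different
quantities. Sampling error is binomial with a design effect implemented as
effective-sample-size deflation (n_eff = n/DEFF) rather than explicit
cluster simulation: simpler, and sufficient to widen difference
distributions realistically. Defaults: σ = 0.2–0.3, drift SD 0.05/yr,
seasonal SD 0.1, bias SD 0.3, n = 500, DEFF = 1.5, reference observed at
province+national level one cycle before a district-level field survey, and
20% of season labels masked to "unknown" (dates are often unrecoverable from
field reports). An off-by-default site-selection option restricts field
sites to the lower tail of the geographic effects, mimicking NGO targeting
of worse-off areas; its strength is not calibrated to any real programme.

What the generator does *not* emulate: real countries' prevalence profiles,
questionnaire content, correlated indicator families, non-linear trends,
cluster-level correlation structure, or frame undercoverage. Passing
recovery tests therefore show that the pipeline attributes variance to the
mechanisms that generated it under this model — not that real cross-source
gaps decompose the same way.

Ground truth (all latent parameters) is returned and serialisable to JSON,
so tests compare attributed shares against injected mechanisms: a noise-only
landscape leaves the residual dominant and pair-difference SDs at the
binomial closed form; a bias-only landscape puts the indicator factor first;
widening the cycle gap under a common drift raises the year-gap share.

## Problem sizes used in the test suite

Fixture checks run on the packaged 15-pair and 31-pair worked examples.
Stochastic checks use landscapes of 8–40 indicators over 20–40 districts
(320–800 pairs), 5 replicate seeds where averaging is asserted, and 10,000
simulation iterations for closed-form agreement — sizes at which the
asserted effects are comfortably outside Monte-Carlo noise under fixed
seeds.

## Limitations

* Matching is exact on place names within declared paths; there is no
  gazetteer or fuzzy matching, and no indicator harmonization beyond exact
  id equality.
* Partition shares are descriptive and order-dependent; no uncertainty is
  attached to them.
* The pipeline consumes pre-aggregated tables only; computing estimates from
  microdata with survey weights is out of scope by design.
* Posterior-year fallback and ancestor-climb depth are policy knobs; results
  can be sensitive to them when reference coverage is sparse.
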