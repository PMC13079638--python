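# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Instrument and data model

The default codebook describes a four-section instrument: 66 symptom items
(Likert 0 = none … 3 = severe) partitioned into 10 physiological systems,
47 binary hazard-exposure items in 6 categories (physical, ergonomic, dust,
radiological, chemical, biological), 26 protective measures (0 = not used,
1–3 = poor/moderate/high effectiveness) in 3 hierarchy-of-controls levels,
and 6 categorical demographics. Published per-system item counts total 62
while the instrument is described as 66 items; the codebook keeps the
66-item total and adds the four extra items to the neurological,
musculoskeletal, ENT & oral, and psychological systems, which carry the
best-documented symptom lists. Other instruments can supply their own
codebook (JSON/YAML); section value ranges and domain memberships are
enforced at load time.

Validation is total and complete-case by default: every out-of-range or
missing cell is reported with its respondent and item; respondents with any
missing answer are dropped (and logged) under the `drop` policy, mirroring
a complete-case survey design, with an opt-in `impute_zero` policy. Item
order is always codebook order, never file order, so downstream indices are
stable.

## Symptom metrics

Severity scores are symptomatic-only means: `S̄_j` averages codes over
respondents with code ≥ 1. The alternative (population mean including
zeros) is bounded above by `3 × prevalence` and would be inconsistent with
severity values near 1.0–1.4 at prevalences of 20–45%; the symptomatic-only
mean lives in [1, 3] regardless of prevalence and is undefined (reported as
null, with a warning) for unreported symptoms. "Presence" is code ≥ 1
everywhere (prevalence, system prevalence, burden, networks).

## Co-occurrence network

Candidate nodes are items with prevalence ≥ `node_min_prevalence`
(default 0.20 — the threshold that admits roughly the top-20 symptom set in
cohorts like the study's; the node rule is configurable because no
published rule fixes it). Candidate edges are pairs co-reported at least
once; the retained edge count is `ceil(edge_quantile × candidates)` with
`edge_quantile = 0.30`. Ties at the cut are broken deterministically:
larger weight, then larger combined node counts, then lexicographic item
ids. Because retention is a prefix of one fixed total order, raising the
quantile never removes a retained edge (nestedness, property-tested).
Isolated nodes are dropped after filtering. Metrics are computed on the
retained, unweighted graph: density `2E/(N(N−1))`, average degree `2E/N`,
triangle-based average clustering, and normalized betweenness. Edge weights
are kept as attributes for display; centrality is deliberately unweighted
since only edge display width is weight-coded in the source figures. Spring
layout is an optional export step with a fixed seed and never affects
metrics.

## Composite risk score

Components per binary hazard: EP (column mean), ES (Cohen's d of total
burden, pooled SD with (n1−1, n2−1) weighting), and BAPS (count of systems
with two-sided Mann–Whitney p < 0.05 comparing exposed vs unexposed system
scores). The Mann–Whitney implementation enumerates the exact null over all
label assignments (midranks, two-sided by deviation from the null mean)
when both groups have ≤ 8 observations, and otherwise uses the
tie-corrected normal approximation with continuity correction. No
multiple-testing correction is applied inside BAPS — the assessment
framework counts raw p < 0.05 — and a Holm option is deliberately not the
default.

The composite weights ES 50%, BAPS 30%, EP 20%. Since only the weights are
published, normalization is a declared package convention: |ES| is divided
by the cohort maximum |ES| (0 when the maximum is 0) and BAPS by the number
of systems, placing every component in [0, 1]. |ES| rather than signed ES
enters the composite so a protective (negative) association cannot rank as
a top hazard by sign alone; the direction is flagged in the output table.
Published composite values from the original cohort are not reproducible
without its raw data (per-factor BAPS was never printed), so the table is
documented as method-faithful rather than value-matching.

## Composite protective effectiveness

`CPE = 0.4·IR + 0.6·(MPE/3)`. The weights are not printed in the source
tables; they were identified by grid search over pairs (w, 1−w) at step
0.01 with MPE normalized by its scale maximum 3, minimizing the maximum
absolute deviation from the ten published composite values. That search is
re-run in the test suite (`test_weights_identified_by_grid_search`) so the
default is continuously re-verified rather than trusted: it reproduces all
ten published values to two decimals and the optimum is unique on the grid.
MPE averages over users only (codes begin at 1 for users), which is the
only reading consistent with published values such as MPE 1.86 at a 46.77%
implementation rate.

## Stratification

System scores are Z-scored with the population divisor n. This convention
is forced by an identity in the source analysis: the reported WCSS at k = 1
equals n × p (620 = 62 × 10), which holds exactly only under population-SD
scoring. Constant columns are an error; callers drop them explicitly (the
pipeline does so and logs it).

K-means is Lloyd's algorithm: centers initialized at k distinct
observations drawn from a single seeded stream (default seed 42), sweeps
until the assignment stabilizes (cap 300), 10 random restarts scored by
WCSS. The published "10 iterations" is read as 10 restarts — convergence
in 10 Lloyd sweeps is not guaranteed, and best-of-restarts is the
conventional meaning; both counts are configurable. A cluster emptied
during a sweep is reseeded at the farthest point whose donor cluster keeps
at least one member. Fixed (seed, restarts) is bitwise reproducible, and
the converged objective agrees with scikit-learn's on the same data
(cross-checked in tests, not used as the implementation, since the seeded
initialization and reseed policy here are part of the contract).

The elbow is automated as the k maximizing the second difference
`WCSS(k−1) − 2·WCSS(k) + WCSS(k+1)`; the full curve is always reported and
a weak-curvature warning (below 5% of WCSS(1) by default) flags the
selection for manual confirmation, because the original choice of k = 3 was
visual and the raw second difference of the published curve actually peaks
at k = 2. Clusters are renumbered by descending mean burden so "cluster 0
is worst" is an invariant, not an accident of initialization.

## Reliability and power

Cronbach's alpha uses sample variances (divisor n−1):
`α = m/(m−1)·(1 − Σs²_i / s²_total)`, null (with a warning) when the total
score has zero variance. The 95% CI is Feldt's F interval with
(n−1, (n−1)(m−1)) degrees of freedom — the source reports CIs without a
method; Feldt is the standard closed form, and a bootstrap could be
substituted without changing the interface.

Power for the two-sample t-test uses the noncentral t with noncentrality
`d·√(n1n2/(n1+n2))` and df `n1+n2−2`; at d = 0 the two-sided power equals
alpha exactly. The required sample size search returns the smallest total n
(even, at 1:1 allocation) reaching the target power; 80% power at d = 0.5
gives 128, matching the prospective calculation in the source. The
source's own post-hoc powers (0.85 at 31 vs 30; 0.59 at 40 vs 21) are not
reproducible under this standard model (which gives ≈ 0.49 and ≈ 0.44) and
also contradict its n = 128 requirement; the package therefore reports the
noncentral-t values and treats the printed ones as unexplained.

## Synthetic cohort generator

Each respondent carries a latent class c ∈ {high, moderate, low}. Class
counts are allocated by largest remainder on the configured proportions
(0.21, 0.40, 0.39 → exactly 13/25/24 at n = 62) and shuffled; this makes
the class composition a controlled study condition rather than an extra
multinomial noise source. Given the class, each symptom item is present
with the class-and-system propensity and, if present, draws its severity
from the class's distribution over {1, 2, 3} (means 1.50/1.25/1.10). The
per-system propensity shape follows the published system-prevalence
pattern, and one multiplier per class is found by bisection (tolerance
1e-3 on expected burden) so the expected class mean burdens are
(32.08, 12.44, 2.71). The calibration is verified by Monte Carlo at
n = 10,000 (within 5%).

Hazard exposures are Bernoulli draws whose log-odds are tilted by the
latent class: the tilt is the configured standardized effect times the
standardized class burden, and the intercept is solved per item so the
marginal prevalence equals the configured rate. Tilting exposure by class
— rather than shifting symptom propensities additively for each exposed
respondent — keeps every cell a valid code, leaves both the class-mean
burden calibration and the marginal exposure prevalences exact, and still
induces exposed-vs-unexposed burden contrasts ordered by the configured
effects; with ten simultaneous published effects of 0.49–0.886 at their
published prevalences, independent additive shifts would instead sum to
about two burden SDs and make the low-burden class impossible to calibrate.
In a single cross-section the two constructions are observationally
interchangeable. Unnamed items' exposure rates are set so each hazard
category's mean prevalence matches its published category mean; protective
measures are used independently with published (or category-mean) rates and
per-item effectiveness distributions whose means match the published
values.

Demographics are drawn independently from the published cohort marginals
and never influence symptoms, mirroring the reported absence of
demographic effects.

What the generator does **not** emulate: within-system item correlation
beyond the shared class and system propensity (so per-system Cronbach
alphas run lower than for real scales, where items share symptom-specific
causes); correlation among hazard exposures beyond their common class
tilt; any demographic–symptom association; and any item-level distribution
beyond the aggregate calibration targets. Passing tests therefore certify
the pipeline's arithmetic, calibration, and recovery behavior — not that
the synthetic cohort reproduces every data-dependent published number
(system prevalences, per-factor composite risk values, per-system alphas,
and realized cluster burdens all depend on the unreleased raw data).

## Problem sizes and seeds

Simulation-based checks use: n = 10,000 (one seed) for generator
calibration; 100 seeds at n = 62 for class-recovery (adjusted Rand and
share-recovery rates under a well-separated configuration); 10 seeds at
n = 2,000 for composite-risk rank recovery; 1,000 replicates for the BAPS
type-I calibration; and 300–1,000 random cases for each oracle-agreement
property. All randomness flows through explicit integer seeds; the
generator derives per-section substreams from one master seed at fixed
offsets, so sections are independently stable under parameter changes.
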