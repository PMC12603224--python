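# Methods

This note documents the statistical models, conventions and design
decisions behind `metaphen`, in the order data flows through the package.

## The annotation format and its central convention

A metaphenomic annotation captures one published cohort: pathological
(post-mortem) diagnosis from a controlled vocabulary (PD, MSA, PSP, DLB,
CBD, the combined code LBD for studies that could not separate PD from
DLB, and OTHER with an optional free-text sublabel such as `OTHER:AD`),
case counts, optional demographic and timing summaries, an optional
cross-tab of in-life clinical diagnoses, and phenotype observations as
`(term_id, n_present, n_assessed)` against an is-a phenotype ontology.

The central convention is that **missing is encoded as absent, never as
zero**. Published reports omit most phenotypes; a lack of reporting does
not equate to an absent sign. Consequently a cohort that did not assess a
term contributes to neither numerator nor denominator of that term's
pooled frequency, unreported demographics are `null`, and unmentioned
findings contribute nothing to a diagnostic query. Timing fields carry an
`onset_reference` flag (`symptom_onset` vs `diagnosis`) because a
minority of studies only report time from diagnosis; pooling mixes both
without correction, but the flag is preserved for sensitivity analyses.

Schema violations (missing or ill-typed fields) fail at read time with
the file, record and field named; scientific cross-field invariants
(`n_present ≤ n_assessed ≤ n_cases`, clinical counts ≤ cases, raw values
consistent with their summary, publication year within the covered era)
are returned by `annotations.validate` as a list of error/warning issues
so a whole corpus can be QC'd in one pass.

## Ontology handling

Only is-a edges are used; other relationship types are ignored at parse
time. Obsolete terms are retained and flagged, and are accepted in
curated label→term mappings only via their replaced-by target, which
keeps mappings stable across ontology releases. Label lookup is exact
after case-folding and whitespace normalisation — no fuzzy matching, as
befits a hand-curated table.

Cohort-level counts cannot be union-propagated up the hierarchy because
per-case overlap between sibling terms is unknown (the same patient may
appear under two tremor subtypes). `aggregate_to_term` therefore exposes
two modes with a clear interpretation: `max` (default) is a conservative
lower bound on the parent-term count — at least that many cases carried
*some* descendant sign — and `capped_sum` is an upper bound assuming no
overlap, capped so presence never exceeds assessment. Profile building
with `propagate=True` applies `max`-mode aggregation per cohort before
pooling, so sibling-term double counting cannot cross cohort boundaries.
Whether an analysis should use propagated or as-annotated counts is left
to the caller via the flag; both behaviours are first-class.

## Pooling and demographic models

Cohort summaries are pooled with sample-size weighting. The pooled mean
is Σnᵢmᵢ/Σnᵢ; the pooled variance combines within-cohort sums of squares
(nᵢ−1 weighted, since cohort SDs are sample SDs) with between-cohort mean
dispersion and divides by N−1, which makes the result identical — to
numerical precision, and property-tested at 1e-9 — to the mean/SD of the
concatenated raw per-case values. This identity is the specification of
the pooling rule: it makes pooling invariant to how cases happen to be
split across publications.

Age of onset and survival are modelled as Gaussians fitted by moments on
fixed supports — 30–100 years for onset, 0–30 years for survival — with
no renormalisation after truncation; these are deliberately coarse
population-level descriptions. Survival beyond t years is the Gaussian
upper tail 1 − Φ((t−μ)/σ), so the 50% survival point is the pooled mean.
Age-conditional pre-test probabilities normalise weighted densities,
P(d | age) ∝ w_d·pdf_d(age); the default weights are each disease's share
of pooled case counts (uniform weights are available by flag — the choice
matters only when the literature's sampling of diseases is judged
unrepresentative of the clinic population).

Group differences in onset/death/duration use a Kruskal–Wallis omnibus
test followed, only when significant, by pairwise two-sided rank-sum
tests at a Bonferroni-style α = 0.005. Pairs that are small (≤25 per
group) and tie-free use the exact rank-sum null distribution; others the
tie-corrected normal approximation.

## Diagnostic accuracy

The in-life clinical diagnosis is the prediction and the pathological
diagnosis the ground truth. The K×K cross-tab is collapsed one disease at
a time into 2×2 (TP = diagonal cell, FN = rest of column, FP = rest of
row, TN = remainder), giving sensitivity, specificity and balanced
accuracy = (sens+spec)/2. Clinical "corticobasal syndrome" (CBS) labels
are credited to CBD by default, since CBD's in-life presentation *is*
CBS; the equivalence is configurable. Only the final diagnosis at death
is stored; interim diagnoses are out of scope. Rates over a zero margin
serialise as null/NaN, never 0, and accuracy-over-time windows where the
balanced accuracy is undefined (no cases of the disease, or no
comparator cases) are omitted rather than imputed.

## Likelihood ratios

For a contrast A vs B, a term's sensitivity is its pooled frequency in A
and its specificity is 1 − its pooled frequency in B, from summed counts
across cohorts (pooling weights by sample size naturally) rather than
averaged per-study frequencies. Then `LR+ = sens/(1−spec)` and
`LR− = (1−sens)/spec`.

Two guards address publication-bias artefacts. First, a minimum
assessment count per contrast side (default 10) suppresses
small-denominator noise; the threshold is a package choice on the order
of the smallest informative case series. Second, a term never reported on
one side has an unbounded LR+ — a *candidate* pathognomonic sign that may
equally be a reporting gap — and is excluded by default (`finite=False`,
serialised as null). A Haldane-style continuity correction (+0.5/+1 on
both frequencies) is available for exploratory screens and converges to
the uncorrected LR as counts grow. The discriminator screen ranks
eligible terms by LR+ descending (ties: larger total assessment, then
term id — fully deterministic); the inverse "next best observation" query
ranks by |log₁₀ LR+|, the distance from uninformative, so strong negative
discriminators rank alongside strong positive ones.

External tests enter as published (sensitivity, specificity) pairs. A
test validated for only one side of a contrast (e.g. a neurofilament
light chain cut-off validated for atypical Parkinsonism vs PD) is reused
on the complementary side by inverting both values (1 − value); the
inversion is an involution and is applied automatically to diseases
outside the test's `applies_to` set.

## The diagnostic calculator

Evidence is combined under conditional independence. For each disease in
the differential, pre-test odds (from the age prior, an explicit
override, or uniform) are multiplied by one LR per piece of evidence:
LR+ for present findings, LR− for explicitly absent findings, nothing for
unmentioned findings, and the appropriate (possibly inverted) test LR.

Two output views are computed, because they answer different questions:

1. **Per-disease odds view** ("is it d, or one of the others?"):
   post-test odds = prior odds × Π LR(d vs REST), where the REST
   frequency is the case-count-weighted mixture of the other differential
   members. In `pairwise` mode a per-opponent contrast table is produced
   instead, with the product over opponents as the combination rule —
   reported as this package's documented convention, since one-vs-one LR
   products have no single canonical multi-class combination. These
   probabilities deliberately do not sum to 1 across the differential.
2. **Normalised multi-class posterior**: prior(d) × Π P(evidence | d),
   renormalised over the differential. Under conditional independence
   this is exact Bayes (verified against brute-force enumeration on two-
   and three-disease synthetic worlds to 1e-9), and for a two-disease
   differential it coincides with the odds view. It is computed from the
   frequencies directly rather than from one-vs-rest LR products, because
   the latter's disease-specific REST denominators do not cancel under
   normalisation for ≥3 diseases.

A disease whose profile has never assessed a queried term is dropped from
the differential with the reason recorded, rather than scored on missing
evidence. Findings with unbounded LRs are excluded and flagged by
default; opting in to pathognomonic evidence caps LRs at 10³ (10⁻³ for
the reciprocal side). Sequential updating recomputes the posterior on the
enlarged query, so it is exactly associative and order-free; duplicate
evidence is rejected.

Screening projections are expectation arithmetic: TP = n·prev·sens,
FP = n·(1−prev)·(1−spec), with PPV/NPV derived; counts are real-valued
expectations, not rounded.

## The synthetic literature generator

The generator emulates the *structure* of the clinicopathological
literature: per-study pathological diagnosis drawn with weights matching
the published per-disease case counts; study sizes log-uniform between 10
and 200 (mimicking the mix of small series and large cohorts; the default
corpus is 125 studies, the published corpus scale); per-case onset and
duration from disease-specific Gaussians whose defaults are the published
pooled means/SDs, with age at death = onset + duration at case level and
non-positive durations resampled (disable `resample_negative_durations`
to sample the plain Normal when recovering untruncated moments);
phenotype counts Binomial(n, frequency) with stylised per-disease
frequency maps over the bundled mini-ontology; clinical labels
multinomial from a stylised confusion matrix; and reporting censoring —
each study reports each phenotype with probability 0.5, sex with
probability 0.467 and misdiagnosis data with probability 0.62 (the
published reporting rates), independent of the values themselves.

What it does **not** emulate, and what passing tests therefore do not
establish about real data: informative censoring (real reporting is
biased towards striking signs), duplicated cases across overlapping
cohorts, temporal ordering of symptom emergence, dual proteinopathies,
diagnostic-criteria drift over publication years, and correlated
phenotypes (findings are conditionally independent by construction, which
is exactly what makes the generator a fair oracle for the naïve-Bayes
calculator, and exactly why real-data performance may differ). The
phenotype frequency and confusion defaults are plausible clinical
stylisations chosen once for testability; they are not published
measurements.

Each study draws from a counter-derived substream
(`default_rng([seed, i])`), so corpora are bit-reproducible and studies
are independent of iteration order. `recovery_report` compares estimates
against generating parameters with a ±3·SE band for means and exact
Clopper–Pearson 99% intervals for proportions.

## Numerical choices and test scales

- Degenerate inputs: Gaussian fits require SD > 0; odds conversions
  reject p ∈ {0, 1}; zero confusion margins yield null rates; empty
  discriminator lists are valid results.
- The parameter-recovery harness uses 50 single-disease cohorts (sizes
  10–200), giving ≈5,000 pooled cases and a standard error well under
  0.15 years — ample for the ±0.5-year acceptance band while keeping
  runs to seconds. Coverage checks run 100 seeded replicates of a
  two-disease, 14-study corpus against 99% intervals.
- All stochastic tests are seeded; the test suite and the acceptance
  script complete in well under a minute on one CPU.

## Known limitations

The pooled profiles inherit every bias of the published literature:
publication bias towards striking phenotypes, case duplication across
cohorts, and criteria drift. LRs carry no confidence intervals in this
version (the delta-method interval used in the test suite is a natural
extension). The Gaussian survival model ignores censoring and is not a
substitute for proper survival analysis. The calculator's conditional
independence assumption is untestable for many clinical markers; the
practical mitigation is selecting reasonably independent observations,
using the ontology hierarchy to subsume obviously collinear terms into a
single ancestor (the aggregation machinery exists for precisely this),
and normalising over several conditions so weakly collinear terms largely
cancel.
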