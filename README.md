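# metaphen

Metaphenomic annotation and probabilistic differential diagnosis of
Parkinsonian disorders.

## The problem

The clinical diagnosis of Parkinson's disease (PD) and its mimics —
multiple system atrophy (MSA), progressive supranuclear palsy (PSP),
dementia with Lewy bodies (DLB) and corticobasal degeneration (CBD) — is
wrong in up to one in five cases, and the gold standard (post-mortem
confirmation of the underlying proteinopathy) arrives too late to help.
Three decades of clinicopathological studies contain the evidence needed to
do better, but it is locked up in heterogeneous prose: every study reports
a different subset of demographics, phenotypes and misdiagnosis data.

`metaphen` is a toolkit for that literature, aimed at movement-disorder
researchers and methodologists building diagnostic decision support. It
provides:

- **annotations** — a versioned JSON format for cohort-level phenotype
  data: pathological diagnosis, counts, onset/death/duration summaries,
  clinical-vs-pathological cross-tabs, and phenotype observations as
  (ontology term, n present, n assessed) triples. A core rule is that
  *missing is never zero*: a study that did not assess a sign contributes
  nothing to that sign's denominator.
- **ontology** — an is-a graph over phenotype terms (HPO-style CURIEs)
  with ancestor/descendant queries and count aggregation up the hierarchy
  (subsuming, say, sibling tremor subtypes into "tremor" without double
  counting patients).
- **aggregation** — sample-size-weighted pooling of cohort summaries into
  per-disease profiles, Gaussian onset/survival models, age-conditional
  pre-test probabilities and rank-based group tests.
- **accuracy** — clinical-vs-pathological confusion matrices, one-vs-rest
  sensitivity/specificity/balanced accuracy, misdiagnosis and missed-
  diagnosis rates, and accuracy-over-time series.
- **likelihood** — per-term likelihood ratios for disease contrasts,
  `LR+ = sens/(1−spec)`, `LR− = (1−sens)/spec`, with a minimum-observation
  filter and explicit handling of candidate pathognomonic signs
  (unbounded LRs are excluded by default, not silently kept).
- **bayes** — a naïve-Bayes diagnostic calculator: pre-test odds from age
  of onset × product of finding and test LRs → post-test odds and
  probabilities, plus screening projections and the inverse query "which
  observation would best resolve this differential?".
- **synth** — a synthetic literature generator with known ground truth
  (Gaussian demographics, Bernoulli phenotypes, a misdiagnosis confusion
  matrix, per-study reporting censoring) so that every analysis stage is
  testable end to end without the real database.

## Worked example

A 50-year-old presents with resting tremor, orthostatic hypotension and
REM sleep behaviour disorder (RBD). Against per-disease profiles built
from a synthetic literature corpus (the bundled generator, seed 7):

```python
from metaphen.synth import default_config, simulate_corpus
from metaphen.aggregation import build_profiles
from metaphen.ontology import load_mini_ontology
from metaphen.bayes import (DiagnosticQuery, Finding, ExternalTest,
                            posterior, sequential_update)

graph = load_mini_ontology()
annotations, truth = simulate_corpus(default_config(seed=7))
profiles = build_profiles(annotations, graph=graph)

query = DiagnosticQuery(
    age=50,
    findings=(Finding("HP:0002322"),   # resting tremor
              Finding("HP:0001278"),   # orthostatic hypotension
              Finding("HP:0033696")),  # RBD
)
result = posterior(query, profiles)
print(result.dropped)
print({d: round(p, 2) for d, p in result.probability.items()})

nflc = ExternalTest("NFLC", 0.86, 0.85, result="positive",
                    applies_to=frozenset({"MSA", "PSP"}))
updated = sequential_update(result, test=nflc)
print({d: round(p, 2) for d, p in updated.probability.items()})
```

prints

```
{'CBD': 'terms never assessed in CBD: HP:0033696'}
{'PD': 0.72, 'MSA': 0.63, 'PSP': 0.0, 'DLB': 0.12}
{'PD': 0.3, 'MSA': 0.91, 'PSP': 0.01, 'DLB': 0.02}
```

CBD is dropped from the differential because RBD has never been assessed
in the simulated CBD literature (scoring it on missing evidence would
conflate "not reported" with "absent"). Each remaining number is a
per-disease post-test probability — "is it this disease or one of the
others?" — so the values deliberately do not sum to 1; a normalised
multi-class posterior is available as `result.posterior`. Before the blood
test the picture favours PD with MSA close behind; a positive
neurofilament light chain result (a marker validated for atypical
Parkinsonism vs PD, sensitivity 0.86 / specificity 0.85) flips the
differential decisively towards MSA.

The same machinery runs from the shell:

```bash
metaphen simulate --out sim --seed 7
metaphen diagnose src/metaphen/data/example_query.json sim/corpus.json --out dx
metaphen screen --n 10000 --prev 0.1 --sens 0.98 --spec 0.953
```

The last command projects a population screening scenario — 10,000 people
at 10% prevalence tested with a 98%-sensitive, 95.3%-specific assay —
and reports 980 expected true positives against 423 false positives
(positive predictive value ≈ 0.70): a reminder that a strong test applied
at modest prevalence still mislabels nearly a third of its positives.

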