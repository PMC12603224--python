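"""Naïve-Bayes diagnostic calculator over phenotype likelihood ratios.

Evidence — clinical findings coded as ontology terms, plus external
diagnostic tests with published sensitivity/specificity — is combined under
a conditional-independence assumption:

    post-test odds(d) = pre-test odds(d) × Π LR_i(d)

where present findings contribute LR+, explicitly-absent findings LR−, and
unmentioned findings contribute nothing (absence of reporting is not
absence of the sign). Pre-test probabilities come from the age-of-onset
Gaussian models, a user override, or a uniform default.

Two views of the result are produced:

* a per-disease odds view ("is it d or not?"), using one-vs-rest or
  pairwise-product LR combinations — these probabilities deliberately do
  not sum to 1 across the differential;
* a normalised multi-class posterior over the differential, computed as
  prior(d) × Π P(evidence | d) renormalised. Under conditional
  independence this is exact Bayes, and for a two-disease differential it
  coincides with the odds view.

A test validated only for one side of a contrast (e.g. a neurofilament
light chain cut-off validated for atypical Parkinsonism vs PD) is reused
for diseases on the complementary side by inverting both its sensitivity
and specificity (1 − value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .aggregation import DiseaseProfile, age_prior
from .likelihood import (
    InsufficientObservations,
    LrConfig,
    contrast_lr,
    invert_test,
    one_vs_rest_lr,
)

__all__ = [
    "Finding",
    "ExternalTest",
    "DiagnosticQuery",
    "DiagnosticResult",
    "ScreeningProjection",
    "prob_to_odds",
    "odds_to_prob",
    "posterior",
    "sequential_update",
    "screening_projection",
    "next_best_observation",
]

Mode = Literal["one_vs_rest", "pairwise"]
PathognomonicPolicy = Literal["exclude", "cap"]

#: LR cap applied (in place of ±inf) when pathognomonic evidence is opted in.
LR_CAP = 1e3


def prob_to_odds(p: float) -> float:
    """Convert a probability in (0, 1) to odds p/(1−p)."""
    if not 0 < p < 1:
        raise ValueError(f"probability must be strictly inside (0, 1), got {p}")
    return p / (1 - p)


def odds_to_prob(o: float) -> float:
    """Convert odds ≥ 0 to a probability o/(1+o)."""
    if o < 0:
        raise ValueError(f"odds must be non-negative, got {o}")
    return o / (1 + o)


@dataclass(frozen=True)
class Finding:
    term_id: str
    status: Literal["present", "absent"] = "present"


@dataclass(frozen=True)
class ExternalTest:
    """An external diagnostic test with published operating characteristics.

    ``applies_to`` lists the diseases on the validated side of the test's
    contrast; for other diseases the inverted (1 − value) characteristics
    are used.
    """

    name: str
    sensitivity: float
    specificity: float
    result: Literal["positive", "negative"] = "positive"
    applies_to: frozenset[str] = frozenset()

    def operating_point(self, disease: str) -> tuple[float, float]:
        if disease in self.applies_to:
            return self.sensitivity, self.specificity
        return invert_test(self.sensitivity, self.specificity)


@dataclass(frozen=True)
class DiagnosticQuery:
    findings: tuple[Finding, ...] = ()
    external_tests: tuple[ExternalTest, ...] = ()
    age: Optional[float] = None
    differential: tuple[str, ...] = ("PD", "MSA", "PSP", "DLB", "CBD")
    prior_override: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        terms = [f.term_id for f in self.findings]
        if len(terms) != len(set(terms)):
            raise ValueError("each finding term may appear only once in a query")


@dataclass
class DiagnosticResult:
    query: DiagnosticQuery
    mode: Mode
    differential: tuple[str, ...]
    dropped: dict[str, str]
    pre_test_probability: dict[str, float]
    lr_details: dict[str, list[tuple[str, Optional[float]]]]
    lr_product: dict[str, float]
    post_test_odds: dict[str, float]
    probability: dict[str, float]
    posterior: dict[str, float]
    pairwise: dict[tuple[str, str], dict] = field(default_factory=dict)
    excluded: list[tuple[str, str, str]] = field(default_factory=list)
    _context: dict = field(default_factory=dict, repr=False)

    def to_table(self, decimals: Optional[int] = None) -> pd.DataFrame:
        """Worked-example-style table: one row per contrast with per-finding
        LRs, the contrast product, pre-test probability, post-test odds and
        probability."""
        rows = []
        labels = [_finding_label(f) for f in self.query.findings] + [
            t.name for t in self.query.external_tests
        ]
        for d in self.differential:
            per_finding = dict(self.lr_details[d])
            if self.mode == "pairwise":
                for opp in self.differential:
                    if opp == d:
                        continue
                    pw = self.pairwise[(d, opp)]
                    rows.append(
                        {
                            "contrast": f"{d} vs {opp}",
                            **pw["per_finding"],
                            "contrast_LR": pw["product"],
                            "pre_test_probability": self.pre_test_probability[d],
                            "post_test_odds": self.post_test_odds[d],
                            "probability": self.probability[d],
                        }
                    )
            else:
                rows.append(
                    {
                        "contrast": f"{d} vs REST",
                        **{k: per_finding.get(k) for k in labels},
                        "contrast_LR": self.lr_product[d],
                        "pre_test_probability": self.pre_test_probability[d],
                        "post_test_odds": self.post_test_odds[d],
                        "probability": self.probability[d],
                    }
                )
        frame = pd.DataFrame(rows)
        if decimals is not None:
            frame = frame.round(decimals)
        return frame


def _finding_label(f: Finding) -> str:
    return f.term_id if f.status == "present" else f"absent:{f.term_id}"


def _effective_differential(
    query: DiagnosticQuery, profiles: Mapping[str, DiseaseProfile]
) -> tuple[list[str], dict[str, str]]:
    """Drop diseases for which queried evidence is structurally unavailable."""
    kept, dropped = [], {}
    for d in query.differential:
        if d not in profiles:
            dropped[d] = "no profile available"
            continue
        missing = [
            f.term_id
            for f in query.findings
            if f.term_id not in profiles[d].phenotype_table
        ]
        if missing:
            dropped[d] = f"terms never assessed in {d}: {', '.join(missing)}"
            continue
        if query.age is not None and query.prior_override is None and (
            profiles[d].onset_model is None
        ):
            dropped[d] = "no onset model for age-conditional prior"
            continue
        kept.append(d)
    if not kept:
        raise ValueError("every disease in the differential was dropped")
    return kept, dropped


def _priors(
    query: DiagnosticQuery,
    profiles: Mapping[str, DiseaseProfile],
    differential: Sequence[str],
    prior_weights: Optional[Mapping[str, float]],
) -> dict[str, float]:
    if query.prior_override is not None:
        missing = [d for d in differential if d not in query.prior_override]
        if missing:
            raise ValueError(f"prior_override missing diseases: {missing}")
        total = sum(query.prior_override[d] for d in differential)
        return {d: query.prior_override[d] / total for d in differential}
    if query.age is not None:
        models = {d: profiles[d].onset_model for d in differential}
        weights = (
            dict(prior_weights)
            if prior_weights is not None
            else {d: profiles[d].n_cases for d in differential}
        )
        return age_prior(query.age, models, weights)
    return {d: 1.0 / len(differential) for d in differential}


def _finding_lr(lr_obj, status: str) -> Optional[float]:
    value = lr_obj.lr_positive if status == "present" else lr_obj.lr_negative
    return value


def _test_lr(test: ExternalTest, disease: str) -> Optional[float]:
    sens, spec = test.operating_point(disease)
    if test.result == "positive":
        return sens / (1 - spec) if spec < 1 else None
    return (1 - sens) / spec if spec > 0 else None


def _test_likelihood(test: ExternalTest, disease: str) -> float:
    sens, _ = test.operating_point(disease)
    return sens if test.result == "positive" else 1 - sens


def posterior(
    query: DiagnosticQuery,
    profiles: Mapping[str, DiseaseProfile],
    mode: Mode = "one_vs_rest",
    config: LrConfig = LrConfig(),
    pathognomonic_policy: PathognomonicPolicy = "exclude",
    prior_weights: Optional[Mapping[str, float]] = None,
) -> DiagnosticResult:
    """Run the diagnostic calculator for one patient query.

    Diseases whose profiles never assessed a queried term are dropped from
    the differential (reported in ``result.dropped``) rather than scored on
    missing evidence. Findings whose LR is unbounded for a disease are
    excluded (flagged) under ``pathognomonic_policy="exclude"`` or clamped
    to ``LR_CAP``/``1/LR_CAP`` under ``"cap"``.
    """
    differential, dropped = _effective_differential(query, profiles)
    priors = _priors(query, profiles, differential, prior_weights)

    lr_details: dict[str, list[tuple[str, Optional[float]]]] = {}
    lr_product: dict[str, float] = {}
    post_odds: dict[str, float] = {}
    probability: dict[str, float] = {}
    pairwise: dict[tuple[str, str], dict] = {}
    excluded: list[tuple[str, str, str]] = []
    scores: dict[str, float] = {}
    sub_profiles = {d: profiles[d] for d in differential}

    def resolve(value: Optional[float], disease: str, label: str) -> Optional[float]:
        if value is not None and math.isfinite(value):
            return value
        if pathognomonic_policy == "cap":
            return LR_CAP if value is None or value > 1 else 1 / LR_CAP
        excluded.append((disease, label, "unbounded likelihood ratio"))
        return None

    for d in differential:
        details: list[tuple[str, Optional[float]]] = []
        product = 1.0
        # phenotype findings against the rest of the differential
        for f in query.findings:
            label = _finding_label(f)
            if len(differential) == 1:
                raise ValueError("cannot contrast a single-disease differential")
            lr_obj = one_vs_rest_lr(
                sub_profiles, d, f.term_id, rest_weights=prior_weights, config=config
            )
            value = resolve(_finding_lr(lr_obj, f.status), d, label)
            details.append((label, value))
            if value is not None:
                product *= value
        for test in query.external_tests:
            value = resolve(_test_lr(test, d), d, test.name)
            details.append((test.name, value))
            if value is not None:
                product *= value
        lr_details[d] = details
        lr_product[d] = product

        if mode == "pairwise":
            total = 1.0
            for opp in differential:
                if opp == d:
                    continue
                per_finding: dict[str, Optional[float]] = {}
                pw_product = 1.0
                for f in query.findings:
                    label = _finding_label(f)
                    lr_obj = contrast_lr(profiles[d], profiles[opp], f.term_id, config)
                    value = resolve(_finding_lr(lr_obj, f.status), d, f"{label} vs {opp}")
                    per_finding[label] = value
                    if value is not None:
                        pw_product *= value
                for test in query.external_tests:
                    a_on, b_on = d in test.applies_to, opp in test.applies_to
                    if a_on == b_on:
                        value: Optional[float] = 1.0  # uninformative for this contrast
                    else:
                        # direct characteristics when d is on the validated
                        # side, inverted (1 − value) when the opponent is
                        sens, spec = (
                            (test.sensitivity, test.specificity)
                            if a_on
                            else invert_test(test.sensitivity, test.specificity)
                        )
                        raw = (
                            (sens / (1 - spec) if spec < 1 else None)
                            if test.result == "positive"
                            else ((1 - sens) / spec if spec > 0 else None)
                        )
                        value = resolve(raw, d, f"{test.name} vs {opp}")
                    per_finding[test.name] = value
                    if value is not None:
                        pw_product *= value
                pairwise[(d, opp)] = {"per_finding": per_finding, "product": pw_product}
                total *= pw_product
            post_odds[d] = prob_to_odds(priors[d]) * total
        else:
            post_odds[d] = prob_to_odds(priors[d]) * product
        probability[d] = odds_to_prob(post_odds[d])

        # normalised multi-class posterior: prior × Π P(evidence | d)
        score = priors[d]
        for f in query.findings:
            np_d, na_d = profiles[d].phenotype_table[f.term_id]
            freq = (
                (np_d + 0.5) / (na_d + 1.0)
                if config.zero_policy == "haldane"
                else np_d / na_d
            )
            score *= freq if f.status == "present" else 1 - freq
        for test in query.external_tests:
            score *= _test_likelihood(test, d)
        scores[d] = score

    total_score = sum(scores.values())
    posterior_dist = (
        {d: scores[d] / total_score for d in differential}
        if total_score > 0
        else {d: math.nan for d in differential}
    )

    return DiagnosticResult(
        query=query,
        mode=mode,
        differential=tuple(differential),
        dropped=dropped,
        pre_test_probability=priors,
        lr_details=lr_details,
        lr_product=lr_product,
        post_test_odds=post_odds,
        probability=probability,
        posterior=posterior_dist,
        pairwise=pairwise,
        excluded=excluded,
        _context={
            "profiles": profiles,
            "mode": mode,
            "config": config,
            "pathognomonic_policy": pathognomonic_policy,
            "prior_weights": prior_weights,
        },
    )


def sequential_update(
    result: DiagnosticResult,
    finding: Optional[Finding] = None,
    test: Optional[ExternalTest] = None,
) -> DiagnosticResult:
    """Fold one new piece of evidence into an existing result.

    Equivalent to recomputing :func:`posterior` on the enlarged query
    (the update is associative and order-free). Duplicate evidence is
    rejected.
    """
    if (finding is None) == (test is None):
        raise ValueError("provide exactly one of finding= or test=")
    query = result.query
    if finding is not None:
        if any(f.term_id == finding.term_id for f in query.findings):
            raise ValueError(f"finding {finding.term_id} already in the query")
        query = replace(query, findings=query.findings + (finding,))
    else:
        if any(t.name == test.name for t in query.external_tests):
            raise ValueError(f"test {test.name!r} already in the query")
        query = replace(query, external_tests=query.external_tests + (test,))
    ctx = result._context
    return posterior(
        query,
        ctx["profiles"],
        mode=ctx["mode"],
        config=ctx["config"],
        pathognomonic_policy=ctx["pathognomonic_policy"],
        prior_weights=ctx["prior_weights"],
    )


@dataclass(frozen=True)
class ScreeningProjection:
    """Expected outcome counts of screening n people at a given prevalence."""

    n: float
    prevalence: float
    sensitivity: float
    specificity: float
    TP: float
    FP: float
    FN: float
    TN: float

    @property
    def ppv(self) -> float:
        return self.TP / (self.TP + self.FP)

    @property
    def npv(self) -> float:
        return self.TN / (self.TN + self.FN)


def screening_projection(
    n: float, prevalence: float, sensitivity: float, specificity: float
) -> ScreeningProjection:
    """Expected confusion counts when screening ``n`` individuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")
    diseased = n * prevalence
    healthy = n - diseased
    return ScreeningProjection(
        n=n,
        prevalence=prevalence,
        sensitivity=sensitivity,
        specificity=specificity,
        TP=diseased * sensitivity,
        FN=diseased * (1 - sensitivity),
        FP=healthy * (1 - specificity),
        TN=healthy * specificity,
    )


def next_best_observation(
    profiles: Mapping[str, DiseaseProfile],
    disease_a: str,
    disease_b: str,
    candidate_terms: Sequence[str],
    config: LrConfig = LrConfig(),
) -> list[tuple[str, float]]:
    """Rank candidate observations by informativeness for a diagnostic dilemma.

    Informativeness is |log10 LR+| — distance from the uninformative LR of
    1 — so a strong *negative* discriminator (LR+ ≪ 1) ranks as highly as a
    strong positive one. Ties break by larger total assessment count, then
    term id.
    """
    scored = []
    for term_id in candidate_terms:
        try:
            lr = contrast_lr(profiles[disease_a], profiles[disease_b], term_id, config)
        except (InsufficientObservations, KeyError):
            continue
        if not lr.finite or lr.lr_positive is None or lr.lr_positive <= 0:
            continue
        score = abs(math.log10(lr.lr_positive))
        scored.append((term_id, score, lr.n_a_assessed + lr.n_b_assessed))
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(term_id, score) for term_id, score, _ in scored]
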