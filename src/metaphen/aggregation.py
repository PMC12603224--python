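"""Pooling cohort summaries into per-disease profiles.

Demographic summaries (age of onset, age at death, disease duration) are
pooled across cohorts with sample-size weighting: the pooled mean is the
case-weighted mean, and the pooled variance combines within-cohort variance
with between-cohort mean dispersion so that the result equals the mean/SD
one would obtain from the concatenated raw per-case values. Phenotype counts
are pooled by summation of numerators and denominators over the cohorts that
assessed each term — a cohort that did not assess a term contributes nothing.

Onset and survival distributions are modelled as Gaussians fitted by moments
(mean and SD of the pooled data) on fixed supports — 30–100 years for age of
onset, 0–30 years for survival — without renormalisation after truncation.
These are deliberately simple population-level descriptions used for
age-conditional pre-test probabilities, not per-case survival models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .annotations import AgeSummary, CohortAnnotation, base_code
from .ontology import OntologyGraph, aggregate_to_term, ancestors, descendants

__all__ = [
    "PooledSummary",
    "GaussianModel",
    "DiseaseProfile",
    "TestConfig",
    "GroupTestResult",
    "pooled_mean_sd",
    "fit_gaussian",
    "survival_probability",
    "age_prior",
    "build_profile",
    "build_profiles",
    "group_tests",
]


@dataclass(frozen=True)
class PooledSummary:
    """Sample-size-weighted pooled mean/SD over cohorts."""

    mean: float
    sd: float
    n_total: int
    weights: tuple[float, ...] = ()


@dataclass(frozen=True)
class GaussianModel:
    """Moment-fitted normal density on a fixed support (years)."""

    mu: float
    sigma: float
    support: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.support[0] >= self.support[1]:
            raise ValueError("support must satisfy lo < hi")

    def pdf(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        out = np.where(
            (x >= lo) & (x <= hi), stats.norm.pdf(x, self.mu, self.sigma), 0.0
        )
        return float(out) if out.ndim == 0 else out

    @property
    def ml_age(self) -> float:
        """Age of maximum likelihood: the mode, clipped to the support."""
        return float(np.clip(self.mu, *self.support))


def pooled_mean_sd(summaries: Sequence[AgeSummary]) -> PooledSummary:
    """Pool per-cohort (mean, sd, n) summaries.

    Equivalent to computing mean and sample SD of the concatenated raw
    values, provided each cohort SD is itself a sample (n−1) SD.
    """
    if not summaries:
        raise ValueError("cannot pool an empty list of summaries")
    for s in summaries:
        if s.sd < 0:
            raise ValueError("negative sd")
        if s.n < 1:
            raise ValueError("summary with n < 1")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    sd = np.array([s.sd for s in summaries], dtype=float)
    n_total = float(n.sum())
    mean = float((n * m).sum() / n_total)
    if n_total > 1:
        ss_within = ((n - 1) * sd**2).sum()
        ss_between = (n * (m - mean) ** 2).sum()
        pooled_sd = math.sqrt((ss_within + ss_between) / (n_total - 1))
    else:
        pooled_sd = float(sd[0])
    return PooledSummary(
        mean=mean,
        sd=pooled_sd,
        n_total=int(n_total),
        weights=tuple(n / n_total),
    )


def fit_gaussian(
    summary: PooledSummary, support: tuple[float, float]
) -> GaussianModel:
    """Moment-fit a normal density to a pooled summary on a fixed support."""
    if summary.sd <= 0:
        raise ValueError("cannot fit a Gaussian with sd = 0 (degenerate summary)")
    return GaussianModel(mu=summary.mean, sigma=summary.sd, support=tuple(support))


def survival_probability(model: GaussianModel, t: float) -> float:
    """P(survival beyond ``t`` years) under the Gaussian duration model."""
    lo, hi = model.support
    if not lo <= t <= hi:
        raise ValueError(f"t={t} outside model support {model.support}")
    return float(stats.norm.sf(t, model.mu, model.sigma))


def age_prior(
    age: float,
    models: Mapping[str, GaussianModel],
    weights: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Pre-test probability of each disease conditional on age of onset.

    ``P(d | age) ∝ w_d · pdf_d(age)``; weights default to uniform and are
    normalised internally, so any proportional weighting gives the same
    result.
    """
    if not models:
        raise ValueError("no models supplied")
    w = {d: 1.0 for d in models} if weights is None else dict(weights)
    if any(w.get(d, 0.0) < 0 for d in models):
        raise ValueError("negative weight")
    dens = {}
    for d, model in models.items():
        lo, hi = model.support
        if not lo <= age <= hi:
            raise ValueError(f"age {age} outside support of {d} model")
        dens[d] = w.get(d, 0.0) * model.pdf(age)
    total = sum(dens.values())
    if total == 0:
        raise ValueError("all weighted densities are zero")
    return {d: v / total for d, v in dens.items()}


@dataclass
class DiseaseProfile:
    """Pooled per-disease demographic models and phenotype frequency table."""

    disease: str
    onset: Optional[PooledSummary] = None
    death: Optional[PooledSummary] = None
    duration: Optional[PooledSummary] = None
    onset_model: Optional[GaussianModel] = None
    death_model: Optional[GaussianModel] = None
    duration_model: Optional[GaussianModel] = None
    phenotype_table: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_sources: int = 0
    n_cases: int = 0

    def frequency(self, term_id: str) -> Optional[float]:
        """Pooled P(term present | disease), or None if never assessed."""
        if term_id not in self.phenotype_table:
            return None
        n_present, n_assessed = self.phenotype_table[term_id]
        return n_present / n_assessed if n_assessed else None

    def n_assessed(self, term_id: str) -> int:
        return self.phenotype_table.get(term_id, (0, 0))[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term_id": t, "n_present": np_, "n_assessed": na}
            for t, (np_, na) in sorted(self.phenotype_table.items())
        ]
        return pd.DataFrame(rows, columns=["term_id", "n_present", "n_assessed"])

    def to_json(self) -> str:
        def _summary(s: Optional[PooledSummary]) -> Optional[dict]:
            if s is None:
                return None
            return {"mean": s.mean, "sd": s.sd, "n_total": s.n_total}

        return json.dumps(
            {
                "disease": self.disease,
                "onset": _summary(self.onset),
                "death": _summary(self.death),
                "duration": _summary(self.duration),
                "n_sources": self.n_sources,
                "n_cases": self.n_cases,
                "phenotype_table": {
                    t: list(v) for t, v in sorted(self.phenotype_table.items())
                },
            },
            indent=1,
        )


def _pool_field(
    annotations: Sequence[CohortAnnotation], name: str
) -> Optional[PooledSummary]:
    summaries = [getattr(a, name) for a in annotations if getattr(a, name) is not None]
    return pooled_mean_sd(summaries) if summaries else None


def _maybe_model(
    summary: Optional[PooledSummary], support: tuple[float, float]
) -> Optional[GaussianModel]:
    if summary is None or summary.sd <= 0:
        return None
    return fit_gaussian(summary, support)


def build_profile(
    annotations: Sequence[CohortAnnotation],
    disease: str,
    graph: Optional[OntologyGraph] = None,
    propagate: bool = False,
    onset_support: tuple[float, float] = reference.ONSET_SUPPORT,
    survival_support: tuple[float, float] = reference.SURVIVAL_SUPPORT,
) -> DiseaseProfile:
    """Pool all cohorts with the given pathological diagnosis into a profile.

    With ``propagate=True`` (requires ``graph``) each cohort's observations
    are additionally aggregated onto every ancestor term before pooling, so
    that e.g. sibling tremor subtypes contribute to the parent "tremor"
    count without double-counting cases (conservative ``max`` mode).
    """
    cohorts = [a for a in annotations if base_code(a.path_diagnosis) == base_code(disease)]
    if not cohorts:
        raise ValueError(f"no cohorts with pathological diagnosis {disease!r}")
    if propagate and graph is None:
        raise ValueError("propagate=True requires an ontology graph")

    table: dict[str, list[int]] = {}
    for cohort in cohorts:
        observations = [(o.term_id, o.n_present, o.n_assessed) for o in cohort.phenotypes]
        per_cohort: dict[str, tuple[int, int]] = {
            t: (np_, na) for t, np_, na in observations
        }
        if propagate:
            targets: set[str] = set()
            for t, _, _ in observations:
                if t in graph:
                    targets.update(ancestors(graph, t))
            for target in targets:
                subtree = descendants(graph, target) | {target}
                contrib = [o for o in observations if o[0] in subtree]
                if contrib:
                    per_cohort[target] = aggregate_to_term(
                        contrib, target, graph, mode="max"
                    )
        for t, (np_, na) in per_cohort.items():
            cell = table.setdefault(t, [0, 0])
            cell[0] += np_
            cell[1] += na

    onset = _pool_field(cohorts, "onset")
    death = _pool_field(cohorts, "death")
    duration = _pool_field(cohorts, "duration")
    return DiseaseProfile(
        disease=base_code(disease),
        onset=onset,
        death=death,
        duration=duration,
        onset_model=_maybe_model(onset, onset_support),
        death_model=_maybe_model(death, onset_support),
        duration_model=_maybe_model(duration, survival_support),
        phenotype_table={t: (v[0], v[1]) for t, v in table.items()},
        n_sources=len({a.source_id for a in cohorts}),
        n_cases=sum(a.n_cases for a in cohorts),
    )


def build_profiles(
    annotations: Sequence[CohortAnnotation],
    diseases: Sequence[str] = reference.MAIN_DISEASES,
    graph: Optional[OntologyGraph] = None,
    propagate: bool = False,
) -> dict[str, DiseaseProfile]:
    """Build profiles for every listed disease present in the corpus."""
    present = {base_code(a.path_diagnosis) for a in annotations}
    return {
        d: build_profile(annotations, d, graph=graph, propagate=propagate)
        for d in diseases
        if base_code(d) in present
    }


@dataclass
class TestConfig:
    """Significance levels for the group-difference testing cascade."""

    alpha_pairwise: float = 0.005
    alpha_omnibus: float = 0.05
    exact_max_n: int = 25

    def __post_init__(self) -> None:
        for a in (self.alpha_pairwise, self.alpha_omnibus):
            if not 0 < a < 1:
                raise ValueError("alpha must be in (0, 1)")


@dataclass
class GroupTestResult:
    statistic: float
    pvalue: float
    pairwise_p: pd.DataFrame
    significant: pd.DataFrame


def group_tests(
    groups: Mapping[str, Sequence[float]], config: TestConfig = TestConfig()
) -> GroupTestResult:
    """Kruskal–Wallis omnibus test, then pairwise rank-sum tests.

    Pairwise comparisons run only when the omnibus test is significant;
    small tie-free pairs use the exact rank-sum null distribution, larger or
    tied pairs the tie-corrected normal approximation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    stat, p = stats.kruskal(*arrays.values())
    names = list(arrays)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    if p < config.alpha_omnibus:
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                x, y = arrays[a], arrays[b]
                combined = np.concatenate([x, y])
                no_ties = len(np.unique(combined)) == combined.size
                method = (
                    "exact"
                    if no_ties and max(x.size, y.size) <= config.exact_max_n
                    else "asymptotic"
                )
                pw = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
                pmat.loc[a, b] = pmat.loc[b, a] = pw.pvalue
    significant = pmat < config.alpha_pairwise
    return GroupTestResult(
        statistic=float(stat), pvalue=float(p), pairwise_p=pmat, significant=significant
    )
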