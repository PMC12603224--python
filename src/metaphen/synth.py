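"""Synthetic clinicopathological literature corpora with known ground truth.

Each simulated "publication" draws a pathological diagnosis, a cohort size
(log-uniform, mimicking the mix of case reports and large series), per-case
ages of onset and disease durations from disease-specific Gaussians (age at
death is onset + duration at case level, negative durations resampled),
phenotype counts as Binomial(n, frequency), and in-life clinical labels
from a multinomial over the disease's confusion row. Per-study reporting
censoring — each study reports only a subset of phenotypes, sex in only a
fraction of studies, misdiagnosis data in a fraction — emulates the patchy
reporting of the real literature. Censoring is independent of the values
themselves, so estimates stay unbiased; what it costs is denominators.

Default parameters mirror the pooled literature summaries in
:mod:`metaphen.reference`; the phenotype frequency and confusion defaults
are plausible clinical stylisations chosen for testability, not published
measurements.

Reproducibility: each study uses an independent counter-derived substream
of a single seeded generator, so corpora are byte-identical for identical
(config, seed) and studies do not interact through draw order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .accuracy import ConfusionMatrix
from .aggregation import DiseaseProfile
from .annotations import (
    AgeSummary,
    ClinicalDiagnosisCount,
    CohortAnnotation,
    PhenotypeObservation,
)

__all__ = [
    "DiseaseSimParams",
    "SimConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_corpus",
    "recovery_report",
]


@dataclass(frozen=True)
class DiseaseSimParams:
    """Generating parameters for one disease."""

    onset: tuple[float, float]  # (mean, sd) years
    duration: tuple[float, float]  # (mean, sd) years
    phenotype_freqs: Mapping[str, float] = field(default_factory=dict)
    weight: float = 1.0  # share of studies


@dataclass
class SimConfig:
    """Full specification of a synthetic literature corpus."""

    diseases: dict[str, DiseaseSimParams]
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    n_studies: int = 125
    study_size_range: tuple[int, int] = (10, 200)
    phenotype_report_prob: float = 0.5
    sex_report_prob: float = 0.467
    misdiag_report_prob: float = 0.62
    diagnosis_ref_prob: float = reference.DIAGNOSIS_REFERENCED_FRACTION
    female_prop: float = reference.FEMALE_PROPORTION
    year_range: tuple[int, int] = (1992, 2022)
    #: Resample non-positive duration draws (durations are elapsed times).
    #: Disable to sample the plain Normal, e.g. for moment-recovery checks
    #: against untruncated generating parameters.
    resample_negative_durations: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.diseases:
            raise ValueError("config defines no diseases")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        lo, hi = self.study_size_range
        if lo < 1 or hi < lo:
            raise ValueError("study_size_range must satisfy 1 <= lo <= hi")
        for p in (
            self.phenotype_report_prob,
            self.sex_report_prob,
            self.misdiag_report_prob,
            self.diagnosis_ref_prob,
            self.female_prop,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if sum(d.weight for d in self.diseases.values()) <= 0:
            raise ValueError("disease weights must have positive sum")
        for d, params in self.diseases.items():
            if params.onset[1] <= 0 or params.duration[1] <= 0:
                raise ValueError(f"{d}: SDs must be positive")
            for t, f in params.phenotype_freqs.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"{d}/{t}: frequency {f} outside [0, 1]")
            if d in self.confusion:
                row = self.confusion[d]
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"confusion row for {d} does not sum to 1")
                if any(v < 0 for v in row.values()):
                    raise ValueError(f"confusion row for {d} has negative entries")


@dataclass
class SyntheticTruth:
    """The generating configuration plus realised per-study latent values."""

    config: SimConfig
    study_diseases: list[str]
    study_sizes: list[int]

    @property
    def n_cases(self) -> int:
        return sum(self.study_sizes)


#: Stylised per-disease phenotype frequencies over the bundled mini-ontology.
_DEFAULT_FREQS: dict[str, dict[str, float]] = {
    "PD": {
        "HP:0002322": 0.75, "HP:0031908": 0.40, "HP:0002067": 0.95,
        "HP:0002063": 0.85, "HP:0001278": 0.30, "HP:0033696": 0.40,
        "HP:0000726": 0.30, "HP:0000738": 0.25, "HP:0002066": 0.05,
        "HP:0010307": 0.01, "HP:0000605": 0.02, "HP:0002527": 0.35,
        "HP:0000802": 0.40, "HP:0000458": 0.75, "HP:0100543": 0.40,
    },
    "MSA": {
        "HP:0002322": 0.30, "HP:0031908": 0.05, "HP:0002067": 0.90,
        "HP:0002063": 0.80, "HP:0001278": 0.75, "HP:0033696": 0.70,
        "HP:0000726": 0.05, "HP:0000738": 0.05, "HP:0002066": 0.55,
        "HP:0010307": 0.30, "HP:0000605": 0.05, "HP:0002527": 0.45,
        "HP:0000802": 0.80, "HP:0000458": 0.30, "HP:0100543": 0.15,
        "HP:0000020": 0.70,
    },
    "PSP": {
        "HP:0002322": 0.10, "HP:0002067": 0.90, "HP:0002063": 0.85,
        "HP:0001278": 0.10, "HP:0033696": 0.15, "HP:0000726": 0.40,
        "HP:0000738": 0.05, "HP:0002066": 0.15, "HP:0010307": 0.02,
        "HP:0000605": 0.75, "HP:0002527": 0.80, "HP:0000802": 0.15,
        "HP:0000458": 0.20, "HP:0100543": 0.55, "HP:0001260": 0.60,
        "HP:0002015": 0.50,
    },
    "DLB": {
        "HP:0002322": 0.40, "HP:0002067": 0.80, "HP:0002063": 0.70,
        "HP:0001278": 0.45, "HP:0033696": 0.65, "HP:0000726": 0.90,
        "HP:0000738": 0.70, "HP:0033725": 0.60, "HP:0002527": 0.40,
        "HP:0000458": 0.60, "HP:0100543": 0.90,
    },
    # RBD (HP:0033696) deliberately never assessed in CBD, matching the
    # real-literature gap that forces CBD out of RBD-containing differentials.
    "CBD": {
        "HP:0002322": 0.14, "HP:0002067": 0.85, "HP:0002063": 0.90,
        "HP:0001278": 0.08, "HP:0000726": 0.45, "HP:0032147": 0.40,
        "HP:0030015": 0.45, "HP:0002527": 0.55, "HP:0000605": 0.30,
        "HP:0100543": 0.60,
    },
}

#: Stylised clinical-label confusion rows, P(label in life | pathology).
_DEFAULT_CONFUSION: dict[str, dict[str, float]] = {
    "PD": {"PD": 0.83, "MSA": 0.054, "PSP": 0.02, "DLB": 0.02, "CBS": 0.006, "OTHER": 0.07},
    "MSA": {"MSA": 0.83, "PD": 0.083, "PSP": 0.0685, "DLB": 0.01, "CBS": 0.0035, "OTHER": 0.005},
    "PSP": {"PSP": 0.78, "PD": 0.0852, "MSA": 0.0563, "CBS": 0.0363, "DLB": 0.002, "OTHER": 0.0402},
    "DLB": {"DLB": 0.70, "MSA": 0.09, "PD": 0.05, "PSP": 0.01, "OTHER": 0.15},
    "CBD": {"CBS": 0.55, "PSP": 0.1738, "OTHER": 0.1312, "PD": 0.05, "MSA": 0.02, "DLB": 0.075},
}


def default_config(seed: int = 0, n_studies: int = 125) -> SimConfig:
    """Corpus configuration on the scale of the published literature.

    125 studies across the five main diseases weighted by their published
    case counts, with onset/duration Gaussians set to the published pooled
    means and SDs.
    """
    diseases = {
        d: DiseaseSimParams(
            onset=reference.ONSET_MEAN_SD[d],
            duration=reference.DURATION_MEAN_SD[d],
            phenotype_freqs=_DEFAULT_FREQS[d],
            weight=reference.CORPUS_CASE_COUNTS[d],
        )
        for d in reference.MAIN_DISEASES
    }
    return SimConfig(
        diseases=diseases,
        confusion={d: dict(v) for d, v in _DEFAULT_CONFUSION.items()},
        n_studies=n_studies,
        seed=seed,
    )


def single_disease_config(
    disease: str,
    onset: tuple[float, float],
    duration: tuple[float, float],
    n_studies: int = 50,
    study_size_range: tuple[int, int] = (10, 200),
    seed: int = 0,
) -> SimConfig:
    """A one-disease corpus for targeted parameter-recovery checks.

    Durations are drawn from the plain (untruncated) Normal so pooled
    moments can be compared directly against the generating parameters.
    """
    return SimConfig(
        diseases={
            disease: DiseaseSimParams(onset=onset, duration=duration, weight=1.0)
        },
        n_studies=n_studies,
        study_size_range=study_size_range,
        phenotype_report_prob=1.0,
        misdiag_report_prob=0.0,
        resample_negative_durations=False,
        seed=seed,
    )


def _positive_normal(
    rng: np.random.Generator, mu: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws with non-positive values resampled (durations)."""
    out = rng.normal(mu, sd, size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
    raise RuntimeError("resampling failed; duration distribution mostly negative")


def simulate_corpus(config: SimConfig) -> tuple[list[CohortAnnotation], SyntheticTruth]:
    """Generate a corpus of cohort annotations plus its ground truth."""
    config.validate()
    names = sorted(config.diseases)
    weights = np.array([config.diseases[d].weight for d in names], dtype=float)
    weights /= weights.sum()
    lo, hi = config.study_size_range

    annotations: list[CohortAnnotation] = []
    study_diseases: list[str] = []
    study_sizes: list[int] = []
    for i in range(config.n_studies):
        rng = np.random.default_rng([config.seed, i])
        disease = names[int(rng.choice(len(names), p=weights))]
        params = config.diseases[disease]
        size = int(np.clip(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))), max(lo, 2), hi))
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))

        onset = rng.normal(*params.onset, size)
        duration = (
            _positive_normal(rng, *params.duration, size)
            if config.resample_negative_durations
            else rng.normal(*params.duration, size)
        )
        death = onset + duration
        onset_ref = "diagnosis" if rng.random() < config.diagnosis_ref_prob else "symptom_onset"

        n_female = n_male = None
        if rng.random() < config.sex_report_prob:
            n_female = int(rng.binomial(size, config.female_prop))
            n_male = size - n_female

        phenotypes = []
        for term_id in sorted(params.phenotype_freqs):
            if rng.random() < config.phenotype_report_prob:
                freq = params.phenotype_freqs[term_id]
                phenotypes.append(
                    PhenotypeObservation(
                        term_id=term_id,
                        n_present=int(rng.binomial(size, freq)),
                        n_assessed=size,
                    )
                )

        clinical = []
        if disease in config.confusion and rng.random() < config.misdiag_report_prob:
            labels = sorted(config.confusion[disease])
            probs = np.array([config.confusion[disease][l] for l in labels])
            counts = rng.multinomial(size, probs / probs.sum())
            clinical = [
                ClinicalDiagnosisCount(label=l, count=int(c))
                for l, c in zip(labels, counts)
                if c > 0
            ]

        annotations.append(
            CohortAnnotation(
                source_id=f"synthetic:{i:04d}",
                publication_year=year,
                cohort_label="cohort",
                path_diagnosis=disease,
                n_cases=size,
                n_female=n_female,
                n_male=n_male,
                onset=AgeSummary.from_values(onset, keep_values=False),
                death=AgeSummary.from_values(death, keep_values=False),
                duration=AgeSummary.from_values(duration, keep_values=False),
                onset_reference=onset_ref,
                clinical_diagnoses=clinical,
                phenotypes=phenotypes,
            )
        )
        study_diseases.append(disease)
        study_sizes.append(size)
    truth = SyntheticTruth(
        config=config, study_diseases=study_diseases, study_sizes=study_sizes
    )
    return annotations, truth


def clopper_pearson(k: int, n: int, level: float = 0.99) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def recovery_report(
    profiles: Mapping[str, DiseaseProfile],
    truth: SyntheticTruth,
    confusion: Optional[ConfusionMatrix] = None,
    level: float = 0.99,
) -> pd.DataFrame:
    """Compare estimates against the generating parameters.

    One row per generating parameter with (truth, estimate, error,
    within_ci). Means use a ±3·SE band (SE from the generating SD and the
    pooled n); proportions use the exact binomial interval at ``level``.
    """
    extra = set(profiles) - set(truth.config.diseases)
    if extra:
        raise ValueError(f"profiles for diseases not in the truth config: {sorted(extra)}")
    rows = []
    for d, params in sorted(truth.config.diseases.items()):
        if d not in profiles:
            continue
        p = profiles[d]
        for name, summary, (mu, sd) in (
            ("onset_mean", p.onset, params.onset),
            ("duration_mean", p.duration, params.duration),
        ):
            if summary is None:
                continue
            se = sd / np.sqrt(summary.n_total)
            rows.append(
                {
                    "disease": d, "parameter": name, "truth": mu,
                    "estimate": summary.mean, "error": summary.mean - mu,
                    "within_ci": abs(summary.mean - mu) <= 3 * se,
                }
            )
        for term_id, freq in sorted(params.phenotype_freqs.items()):
            if term_id not in p.phenotype_table:
                continue
            k, n = p.phenotype_table[term_id]
            lo_ci, hi_ci = clopper_pearson(k, n, level)
            rows.append(
                {
                    "disease": d, "parameter": f"freq:{term_id}", "truth": freq,
                    "estimate": k / n, "error": k / n - freq,
                    "within_ci": lo_ci <= freq <= hi_ci,
                }
            )
        if confusion is not None and d in truth.config.confusion:
            col = confusion.counts[d]
            n = int(col.sum())
            if n > 0:
                # fold truth labels the same way the matrix folds them
                truth_row: dict[str, float] = {}
                for label, prob in truth.config.confusion[d].items():
                    folded = "CBD" if label == "CBS" else label
                    folded = folded if folded in confusion.labels else "OTHER"
                    truth_row[folded] = truth_row.get(folded, 0.0) + prob
                for label, prob in sorted(truth_row.items()):
                    k = int(col[label])
                    lo_ci, hi_ci = clopper_pearson(k, n, level)
                    rows.append(
                        {
                            "disease": d, "parameter": f"confusion:{label}",
                            "truth": prob, "estimate": k / n,
                            "error": k / n - prob,
                            "within_ci": lo_ci <= prob <= hi_ci,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["disease", "parameter", "truth", "estimate", "error", "within_ci"]
    )
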