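"""Likelihood ratios for phenotype terms and external diagnostic tests.

For a contrast "disease A vs disease B", a phenotype term's sensitivity is
its pooled frequency in A and its specificity is one minus its pooled
frequency in B. Likelihood ratios follow the standard definitions

    LR+ = sensitivity / (1 - specificity)
    LR- = (1 - sensitivity) / specificity

A term never reported in B has specificity 1 and an unbounded LR+
(a candidate pathognomonic sign). Because absent reporting in published
cohorts cannot be read as an absent sign, such terms are excluded by
default (``zero_policy="exclude"``, ``finite=False``); a Haldane-style
continuity correction (+0.5 to numerators, +1 to denominators of both
frequencies) is available for exploratory screens. A minimum assessment
count per side (default 10) suppresses small-denominator artefacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .aggregation import DiseaseProfile

__all__ = [
    "LikelihoodRatio",
    "LrConfig",
    "InsufficientObservations",
    "contrast_lr",
    "one_vs_rest_lr",
    "top_discriminators",
    "lr_from_test",
    "invert_test",
    "lr_table",
]

REST = "REST"


class InsufficientObservations(ValueError):
    """A contrast side does not meet the minimum assessment count."""


@dataclass(frozen=True)
class LrConfig:
    min_assessed: int = 10
    zero_policy: Literal["exclude", "haldane"] = "exclude"
    propagate: bool = False

    def __post_init__(self) -> None:
        if self.min_assessed < 1:
            raise ValueError("min_assessed must be >= 1")


@dataclass(frozen=True)
class LikelihoodRatio:
    """Sensitivity/specificity and LRs for one term and one disease contrast."""

    term_id: str
    disease_a: str
    disease_b: str
    sensitivity: float
    specificity: float
    lr_positive: Optional[float]
    lr_negative: Optional[float]
    n_a_assessed: int
    n_b_assessed: int
    finite: bool


def _ratios(
    sensitivity: float, specificity: float
) -> tuple[Optional[float], Optional[float], bool]:
    lr_pos = sensitivity / (1 - specificity) if specificity < 1 else None
    lr_neg = (1 - sensitivity) / specificity if specificity > 0 else None
    return lr_pos, lr_neg, lr_pos is not None


def _freqs(
    n_present_a: int,
    n_assessed_a: int,
    n_present_b: int,
    n_assessed_b: int,
    config: LrConfig,
) -> tuple[float, float]:
    if config.zero_policy == "haldane":
        freq_a = (n_present_a + 0.5) / (n_assessed_a + 1.0)
        freq_b = (n_present_b + 0.5) / (n_assessed_b + 1.0)
    else:
        freq_a = n_present_a / n_assessed_a
        freq_b = n_present_b / n_assessed_b
    return freq_a, freq_b


def contrast_lr(
    profile_a: DiseaseProfile,
    profile_b: DiseaseProfile,
    term_id: str,
    config: LrConfig = LrConfig(),
) -> LikelihoodRatio:
    """Likelihood ratios for ``term_id`` in the A-vs-B contrast."""
    for side, profile in (("a", profile_a), ("b", profile_b)):
        if profile.n_assessed(term_id) < config.min_assessed:
            raise InsufficientObservations(
                f"term {term_id}: side {side} ({profile.disease}) assessed "
                f"{profile.n_assessed(term_id)} < min_assessed {config.min_assessed}"
            )
    np_a, na_a = profile_a.phenotype_table[term_id]
    np_b, na_b = profile_b.phenotype_table[term_id]
    sens, freq_b = _freqs(np_a, na_a, np_b, na_b, config)
    spec = 1 - freq_b
    lr_pos, lr_neg, finite = _ratios(sens, spec)
    return LikelihoodRatio(
        term_id=term_id,
        disease_a=profile_a.disease,
        disease_b=profile_b.disease,
        sensitivity=sens,
        specificity=spec,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        n_a_assessed=na_a,
        n_b_assessed=na_b,
        finite=finite,
    )


def one_vs_rest_lr(
    profiles: Mapping[str, DiseaseProfile],
    disease: str,
    term_id: str,
    rest_weights: Optional[Mapping[str, float]] = None,
    config: LrConfig = LrConfig(),
) -> LikelihoodRatio:
    """Likelihood ratios for ``disease`` against a weighted mixture of the rest.

    The rest frequency is the weighted average of the other diseases'
    pooled frequencies, with weights renormalised over the diseases that
    actually assessed the term. Default weights are each profile's pooled
    case count.
    """
    profile_a = profiles[disease]
    if profile_a.n_assessed(term_id) < config.min_assessed:
        raise InsufficientObservations(
            f"term {term_id}: disease {disease} assessed "
            f"{profile_a.n_assessed(term_id)} < min_assessed {config.min_assessed}"
        )
    rest = {
        d: p
        for d, p in profiles.items()
        if d != disease and term_id in p.phenotype_table and p.n_assessed(term_id) > 0
    }
    if not rest:
        raise InsufficientObservations(
            f"term {term_id}: no rest disease has assessed it"
        )
    total_rest_assessed = sum(p.n_assessed(term_id) for p in rest.values())
    if total_rest_assessed < config.min_assessed:
        raise InsufficientObservations(
            f"term {term_id}: rest pool assessed {total_rest_assessed} "
            f"< min_assessed {config.min_assessed}"
        )
    weights = {
        d: (rest_weights[d] if rest_weights is not None else p.n_cases)
        for d, p in rest.items()
    }
    wsum = sum(weights.values())
    if wsum <= 0:
        raise ValueError("rest weights sum to zero over assessing diseases")

    np_a, na_a = profile_a.phenotype_table[term_id]
    sens = (
        (np_a + 0.5) / (na_a + 1.0) if config.zero_policy == "haldane" else np_a / na_a
    )
    freq_rest = 0.0
    for d, p in rest.items():
        np_b, na_b = p.phenotype_table[term_id]
        f = (np_b + 0.5) / (na_b + 1.0) if config.zero_policy == "haldane" else np_b / na_b
        freq_rest += weights[d] / wsum * f
    spec = 1 - freq_rest
    lr_pos, lr_neg, finite = _ratios(sens, spec)
    return LikelihoodRatio(
        term_id=term_id,
        disease_a=profile_a.disease,
        disease_b=REST,
        sensitivity=sens,
        specificity=spec,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        n_a_assessed=na_a,
        n_b_assessed=total_rest_assessed,
        finite=finite,
    )


def _rank_key(lr: LikelihoodRatio) -> tuple:
    # descending LR+, then larger total assessment, then term id
    return (-lr.lr_positive, -(lr.n_a_assessed + lr.n_b_assessed), lr.term_id)


def top_discriminators(
    profiles: Mapping[str, DiseaseProfile],
    disease_a: str,
    disease_b: str,
    k: int = 5,
    config: LrConfig = LrConfig(),
) -> list[LikelihoodRatio]:
    """Top-k terms by LR+ for discriminating ``disease_a`` from ``disease_b``.

    Only terms assessed on both sides with at least ``min_assessed``
    observations and a finite LR+ are eligible; an empty list is a valid
    result.
    """
    profile_a, profile_b = profiles[disease_a], profiles[disease_b]
    candidates = set(profile_a.phenotype_table) & set(profile_b.phenotype_table)
    results = []
    for term_id in candidates:
        try:
            lr = contrast_lr(profile_a, profile_b, term_id, config)
        except InsufficientObservations:
            continue
        if lr.finite and lr.lr_positive is not None:
            results.append(lr)
    results.sort(key=_rank_key)
    return results[:k]


def lr_from_test(sensitivity: float, specificity: float) -> tuple[float, float]:
    """(LR+, LR−) of an external diagnostic test from its sensitivity/specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if specificity >= 1:
        raise ValueError("specificity = 1 gives an unbounded LR+; cap it upstream")
    if specificity <= 0:
        raise ValueError("specificity = 0 gives an undefined LR-")
    return sensitivity / (1 - specificity), (1 - sensitivity) / specificity


def invert_test(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Reuse a test validated for one contrast on the complementary contrast.

    A test validated as "atypical vs typical" discriminates the complement
    with sensitivity' = 1 − sensitivity and specificity' = 1 − specificity.
    Involution: inverting twice restores the original pair.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return 1 - sensitivity, 1 - specificity


def lr_table(
    ratios: Sequence[LikelihoodRatio], term_names: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Flat export table; non-finite LR+ serialises as null (NaN), never 0."""
    rows = []
    for lr in ratios:
        rows.append(
            {
                "term_id": lr.term_id,
                "term_name": (term_names or {}).get(lr.term_id),
                "disease_a": lr.disease_a,
                "disease_b": lr.disease_b,
                "sens": lr.sensitivity,
                "spec": lr.specificity,
                "lr_pos": lr.lr_positive if lr.lr_positive is not None else math.nan,
                "lr_neg": lr.lr_negative if lr.lr_negative is not None else math.nan,
                "n_a": lr.n_a_assessed,
                "n_b": lr.n_b_assessed,
                "finite": lr.finite,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "disease_a", "disease_b", "sens", "spec",
            "lr_pos", "lr_neg", "n_a", "n_b", "finite",
        ],
    )
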