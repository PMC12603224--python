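"""Clinical-vs-pathological diagnostic accuracy.

The in-life clinical diagnosis is framed as the prediction and the
post-mortem pathological diagnosis as ground truth. The full K×K
cross-tabulation is collapsed, one disease at a time, into a 2×2 confusion
matrix from which sensitivity, specificity and balanced accuracy follow.

Clinically, corticobasal degeneration (CBD) presents as corticobasal
syndrome (CBS); with ``cbs_equals_cbd=True`` (the default) CBS counts are
credited to the clinical CBD column. Diagnoses outside the tracked label
set fold into OTHER. Rates over a zero margin are reported as NaN
(undefined), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations import CohortAnnotation, base_code

#: Fixed presentation order for exports.
DEFAULT_LABELS: tuple[str, ...] = ("PD", "MSA", "PSP", "DLB", "CBD", "OTHER")

Direction = Literal["clinical_to_path", "path_to_clinical"]


@dataclass
class ConfusionMatrix:
    """K×K cross-tab: rows are clinical (in-life) labels, columns pathological."""

    labels: tuple[str, ...]
    counts: pd.DataFrame  # index=clinical, columns=pathological

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class BinaryPerformance:
    """One-vs-rest 2×2 collapse for a single disease."""

    disease: str
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2


def build_confusion(
    annotations: Sequence[CohortAnnotation],
    labels: Sequence[str] = DEFAULT_LABELS,
    cbs_equals_cbd: bool = True,
) -> ConfusionMatrix:
    """Cross-tabulate clinical diagnosis counts against pathological diagnosis.

    Cohorts without misdiagnosis data contribute nothing. Labels outside
    ``labels`` fold into OTHER (which must therefore be in ``labels`` if any
    out-of-set diagnoses occur).
    """
    labels = tuple(labels)
    counts = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)

    def fold(code: str) -> str:
        c = base_code(code)
        if c == "CBS":
            c = "CBD" if cbs_equals_cbd else "OTHER"
        return c if c in labels else "OTHER"

    for a in annotations:
        if not a.has_misdiagnosis_data:
            continue
        total = sum(c.count for c in a.clinical_diagnoses)
        if total > a.n_cases:
            raise ValueError(
                f"{a.source_id}/{a.cohort_label}: clinical counts {total} exceed "
                f"n_cases {a.n_cases}"
            )
        p = fold(a.path_diagnosis)
        if p not in labels:
            raise ValueError(f"pathological label {p!r} not representable in {labels}")
        for cd in a.clinical_diagnoses:
            counts.loc[fold(cd.label), p] += cd.count
    return ConfusionMatrix(labels=labels, counts=counts)


def binary_performance(matrix: ConfusionMatrix, disease: str) -> BinaryPerformance:
    """Collapse the K×K matrix to one-vs-rest 2×2 for one disease."""
    d = base_code(disease)
    if d not in matrix.labels:
        raise KeyError(f"disease {disease!r} not in matrix labels {matrix.labels}")
    c = matrix.counts
    tp = int(c.loc[d, d])
    col = int(c[d].sum())
    row = int(c.loc[d].sum())
    if col == 0:
        raise ValueError(f"no pathological {d} cases in the matrix")
    fn = col - tp
    fp = row - tp
    tn = matrix.grand_total - tp - fn - fp
    return BinaryPerformance(disease=d, TP=tp, FP=fp, FN=fn, TN=tn)


def performance_table(
    matrix: ConfusionMatrix, diseases: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-disease sensitivity/specificity/balanced accuracy table.

    By default covers the named diseases (OTHER excluded) that have at
    least one pathological case in the matrix; explicitly listed diseases
    are not skipped and raise if their column is empty.
    """
    diseases = list(
        diseases
        or [
            d
            for d in matrix.labels
            if d != "OTHER" and matrix.counts[d].sum() > 0
        ]
    )
    rows = []
    for d in diseases:
        perf = binary_performance(matrix, d)
        rows.append(
            {
                "disease": d,
                "TP": perf.TP,
                "FP": perf.FP,
                "FN": perf.FN,
                "TN": perf.TN,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "balanced_accuracy": perf.balanced_accuracy,
            }
        )
    return pd.DataFrame(rows).set_index("disease")


def misdiagnosis_rates(matrix: ConfusionMatrix, direction: Direction) -> pd.DataFrame:
    """Normalised mis-/missed-diagnosis proportions.

    ``clinical_to_path``: for each in-life label, the distribution of true
    pathological diagnoses (row-normalised; "what did a clinical PD label
    turn out to be?"). ``path_to_clinical``: for each pathological
    diagnosis, the distribution of in-life labels (column-normalised;
    "what were true PD cases called in life?"). Zero-margin vectors are NaN.
    """
    c = matrix.counts.astype(float)
    if direction == "clinical_to_path":
        margins = c.sum(axis=1)
        out = c.div(margins.replace(0, np.nan), axis=0)
    elif direction == "path_to_clinical":
        margins = c.sum(axis=0)
        out = c.div(margins.replace(0, np.nan), axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out


def accuracy_timeline(
    annotations: Sequence[CohortAnnotation],
    disease: str,
    window_years: int,
    labels: Sequence[str] = DEFAULT_LABELS,
    cbs_equals_cbd: bool = True,
) -> pd.DataFrame:
    """Balanced accuracy per publication-year window.

    Windows partition the publication-year range of the cross-tabulated
    cohorts; windows where balanced accuracy is undefined — no pathological
    cases of ``disease``, or no comparator cases at all — are omitted.
    ``n`` is the total number of cross-tabulated cases in the window.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    usable = [a for a in annotations if a.has_misdiagnosis_data]
    if not usable:
        return pd.DataFrame(columns=["window_start", "window_end", "balanced_accuracy", "n"])
    years = [a.publication_year for a in usable]
    start, stop = min(years), max(years)
    rows = []
    for lo in range(start, stop + 1, window_years):
        hi = lo + window_years - 1
        in_window = [a for a in usable if lo <= a.publication_year <= hi]
        if not in_window:
            continue
        matrix = build_confusion(in_window, labels=labels, cbs_equals_cbd=cbs_equals_cbd)
        d = base_code(disease)
        col_total = int(matrix.counts[d].sum())
        if col_total == 0 or col_total == matrix.grand_total:
            continue
        perf = binary_performance(matrix, d)
        rows.append(
            {
                "window_start": lo,
                "window_end": hi,
                "balanced_accuracy": perf.balanced_accuracy,
                "n": matrix.grand_total,
            }
        )
    return pd.DataFrame(rows)
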