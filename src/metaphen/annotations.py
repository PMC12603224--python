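"""The metaphenomic annotation format: cohort-level phenotype records.

A metaphenomic annotation captures one published clinicopathological cohort
in machine-readable form: the post-mortem (gold standard) diagnosis, case
counts, demographic and timing summaries, the in-life clinical diagnoses of
the same cases, and phenotype observations as (term, n_present, n_assessed)
triples against a phenotype ontology.

A central convention throughout: **missing is never zero**. A cohort that
did not assess a phenotype contributes nothing to that term's denominator,
and absent demographic fields are encoded as absent, because in published
reports a lack of reporting does not equate to an absent sign.

On-disk format: JSON, one document per publication::

    {"format_version": "1.0",
     "source": {"source_id": "10.1000/example", "publication_year": 2005},
     "cohorts": [ { ...cohort fields... } ]}

Schema-level problems (missing/ill-typed fields) raise
:class:`AnnotationFormatError` at read time; cross-field scientific
invariants are checked by :func:`validate`, which returns issues rather
than raising so a whole corpus can be QC'd in one pass.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .ontology import OntologyGraph

FORMAT_VERSION = "1.0"

#: Controlled pathological diagnosis codes. ``LBD`` marks studies that could
#: not separate PD from DLB at post-mortem; ``OTHER`` may carry a free-text
#: sublabel (``OTHER:AD``). In-life clinical labels additionally allow
#: ``CBS`` (corticobasal syndrome, the clinical presentation of CBD).
PATH_CODES = {"PD", "MSA", "PSP", "DLB", "CBD", "LBD", "OTHER"}
CLINICAL_CODES = PATH_CODES | {"CBS"}

_EARLIEST_YEAR = 1992  # validation of the modern PD diagnostic criteria


class AnnotationFormatError(ValueError):
    """An annotation file violates the JSON schema."""


def base_code(code: str) -> str:
    """Collapse ``OTHER:<sublabel>`` to ``OTHER``; other codes unchanged."""
    return "OTHER" if code.upper().startswith("OTHER") else code.upper()


def _check_code(code: str, allowed: set[str]) -> str:
    if base_code(code) not in allowed:
        raise ValueError(f"unknown disease code {code!r}")
    return code


class AgeSummary(BaseModel):
    """Summary of an age-like variable (years): mean, SD and group size.

    ``values`` optionally carries the raw per-case values; when present they
    must agree with the summary fields (checked by :func:`validate`, with
    sample SD, so that annotating raw case lists and summary statistics are
    interchangeable downstream).
    """

    model_config = ConfigDict(extra="forbid")

    mean: float
    sd: float = Field(ge=0)
    n: int = Field(ge=1)
    values: Optional[list[float]] = None

    @classmethod
    def from_values(cls, values: Sequence[float], keep_values: bool = True) -> "AgeSummary":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(
            mean=float(arr.mean()),
            sd=sd,
            n=int(arr.size),
            values=list(map(float, arr)) if keep_values else None,
        )


class PhenotypeObservation(BaseModel):
    model_config = ConfigDict(extra="forbid")

    term_id: str
    n_present: int = Field(ge=0)
    n_assessed: int = Field(ge=0)

    @field_validator("term_id")
    @classmethod
    def _curie(cls, v: str) -> str:
        if not re.fullmatch(r"[A-Za-z]+:\S+", v):
            raise ValueError(f"term_id {v!r} is not a CURIE")
        return v


class ClinicalDiagnosisCount(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    count: int = Field(ge=0)

    @field_validator("label")
    @classmethod
    def _code(cls, v: str) -> str:
        return _check_code(v, CLINICAL_CODES)


class CohortAnnotation(BaseModel):
    """One publication's cohort in the metaphenomic annotation format."""

    model_config = ConfigDict(extra="forbid")

    source_id: str
    publication_year: int
    cohort_label: str = "cohort"
    path_diagnosis: str
    n_cases: int = Field(ge=1)
    n_female: Optional[int] = Field(default=None, ge=0)
    n_male: Optional[int] = Field(default=None, ge=0)
    onset: Optional[AgeSummary] = None
    death: Optional[AgeSummary] = None
    duration: Optional[AgeSummary] = None
    onset_reference: Literal["symptom_onset", "diagnosis"] = "symptom_onset"
    clinical_diagnoses: list[ClinicalDiagnosisCount] = Field(default_factory=list)
    phenotypes: list[PhenotypeObservation] = Field(default_factory=list)
    dual_diagnosis: bool = False
    pathology_notes: Optional[str] = None

    @field_validator("path_diagnosis")
    @classmethod
    def _path_code(cls, v: str) -> str:
        return _check_code(v, PATH_CODES)

    @property
    def has_misdiagnosis_data(self) -> bool:
        return len(self.clinical_diagnoses) > 0


@dataclass(frozen=True)
class Issue:
    """One validation finding: severity, offending field, message."""

    severity: Literal["error", "warning"]
    field: str
    message: str


@dataclass
class CorpusFilter:
    """Corpus subsetting rules applied before an analysis.

    ``split_lbd`` drops cohorts labelled with the combined ``LBD`` code so
    that only studies separating PD and DLB enter PD/DLB contrasts.
    """

    diseases: Optional[set[str]] = None
    year_range: Optional[tuple[int, int]] = None
    require_misdiagnosis: bool = False
    exclude_dual: bool = False
    split_lbd: bool = False

    def __post_init__(self) -> None:
        if self.year_range is not None and self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be ordered (min, max)")


def validate(
    annotation: CohortAnnotation, graph: Optional[OntologyGraph] = None
) -> list[Issue]:
    """Check cross-field invariants; returns issues instead of raising."""
    issues: list[Issue] = []
    err = lambda field, msg: issues.append(Issue("error", field, msg))
    warn = lambda field, msg: issues.append(Issue("warning", field, msg))

    if annotation.publication_year < _EARLIEST_YEAR:
        err("publication_year", f"publication_year before {_EARLIEST_YEAR}")
    if (
        annotation.n_female is not None
        and annotation.n_male is not None
        and annotation.n_female + annotation.n_male > annotation.n_cases
    ):
        err("n_female", "n_female + n_male exceeds n_cases")

    seen_terms: set[str] = set()
    for i, obs in enumerate(annotation.phenotypes):
        loc = f"phenotypes[{i}]"
        if obs.n_present > obs.n_assessed:
            err(loc, f"{obs.term_id}: n_present {obs.n_present} > n_assessed {obs.n_assessed}")
        if obs.n_assessed > annotation.n_cases:
            err(loc, f"{obs.term_id}: n_assessed {obs.n_assessed} > n_cases {annotation.n_cases}")
        if obs.term_id in seen_terms:
            err(loc, f"duplicate phenotype term {obs.term_id}")
        seen_terms.add(obs.term_id)
        if graph is not None:
            if obs.term_id not in graph:
                err(loc, f"term {obs.term_id} not in ontology")
            elif graph[obs.term_id].obsolete:
                if graph[obs.term_id].replaced_by:
                    warn(loc, f"term {obs.term_id} is obsolete; use its replacement")
                else:
                    err(loc, f"term {obs.term_id} is obsolete with no replacement")

    total_clinical = sum(c.count for c in annotation.clinical_diagnoses)
    if total_clinical > annotation.n_cases:
        err("clinical_diagnoses", f"clinical counts sum to {total_clinical} > n_cases")

    for name in ("onset", "death", "duration"):
        summary: Optional[AgeSummary] = getattr(annotation, name)
        if summary is None:
            continue
        if summary.n > annotation.n_cases:
            err(name, f"{name}.n {summary.n} > n_cases {annotation.n_cases}")
        if summary.values is not None:
            arr = np.asarray(summary.values, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            if (
                len(summary.values) != summary.n
                or not math.isclose(float(arr.mean()), summary.mean, abs_tol=1e-9)
                or not math.isclose(sd, summary.sd, abs_tol=1e-9)
            ):
                err(name, f"{name} raw values disagree with the reported summary")
        if summary.sd == 0 and summary.n > 1 and summary.values is None:
            warn(name, f"{name}.sd is 0 with n > 1")
    return issues


# ---------------------------------------------------------------------------
# IO


def _annotation_to_cohort_dict(a: CohortAnnotation) -> dict:
    d = a.model_dump(exclude_none=True)
    d.pop("source_id")
    d.pop("publication_year")
    return d


def write_corpus(annotations: Iterable[CohortAnnotation], path: str | Path) -> list[Path]:
    """Write annotations as format-versioned JSON documents.

    A ``.json`` path receives one bundle file; any other path is treated as
    a directory with one document per source publication.
    """
    path = Path(path)
    by_source: dict[tuple[str, int], list[CohortAnnotation]] = {}
    for a in annotations:
        by_source.setdefault((a.source_id, a.publication_year), []).append(a)
    documents = [
        {
            "format_version": FORMAT_VERSION,
            "source": {"source_id": sid, "publication_year": year},
            "cohorts": [
                _annotation_to_cohort_dict(a)
                for a in sorted(group, key=lambda a: a.cohort_label)
            ],
        }
        for (sid, year), group in sorted(by_source.items())
    ]
    if path.suffix == ".json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(
            json.dumps({"format_version": FORMAT_VERSION, "documents": documents}, indent=1)
        )
        return [path]
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for doc in documents:
        stem = re.sub(r"[^A-Za-z0-9_.-]+", "_", doc["source"]["source_id"])
        out = path / f"{stem}.json"
        out.write_text(json.dumps(doc, indent=1))
        written.append(out)
    return written


def _parse_document(doc: dict, origin: str) -> list[CohortAnnotation]:
    try:
        source = doc["source"]
        cohorts = doc["cohorts"]
    except (KeyError, TypeError) as exc:
        raise AnnotationFormatError(f"{origin}: missing top-level field {exc}") from None
    out = []
    for i, cohort in enumerate(cohorts):
        try:
            out.append(
                CohortAnnotation(
                    source_id=source["source_id"],
                    publication_year=source["publication_year"],
                    **cohort,
                )
            )
        except (ValidationError, KeyError) as exc:
            if isinstance(exc, ValidationError):
                first = exc.errors()[0]
                field = ".".join(str(p) for p in first["loc"])
                msg = first["msg"]
            else:
                field, msg = str(exc), "missing"
            raise AnnotationFormatError(
                f"{origin}: cohort {i}: field {field!r}: {msg}"
            ) from None
    return out


def read_corpus(path: str | Path) -> list[CohortAnnotation]:
    """Read annotation JSON from a file or a directory of files.

    Records are returned in a stable order (source_id, cohort_label)
    regardless of file layout.
    """
    path = Path(path)
    files = sorted(path.glob("*.json")) if path.is_dir() else [path]
    if not files:
        raise AnnotationFormatError(f"no annotation JSON files under {path}")
    annotations: list[CohortAnnotation] = []
    for f in files:
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationFormatError(f"{f}: invalid JSON: {exc}") from None
        docs = doc.get("documents", [doc]) if isinstance(doc, dict) else doc
        for d in docs:
            annotations.extend(_parse_document(d, str(f)))
    annotations.sort(key=lambda a: (a.source_id, a.cohort_label))
    return annotations


def filter_corpus(
    annotations: Sequence[CohortAnnotation], corpus_filter: CorpusFilter
) -> list[CohortAnnotation]:
    """Apply a :class:`CorpusFilter`; order-preserving and idempotent."""
    f = corpus_filter
    out = []
    for a in annotations:
        if f.diseases is not None and base_code(a.path_diagnosis) not in {
            base_code(d) for d in f.diseases
        }:
            continue
        if f.year_range is not None and not (
            f.year_range[0] <= a.publication_year <= f.year_range[1]
        ):
            continue
        if f.require_misdiagnosis and not a.has_misdiagnosis_data:
            continue
        if f.exclude_dual and a.dual_diagnosis:
            continue
        if f.split_lbd and base_code(a.path_diagnosis) == "LBD":
            continue
        out.append(a)
    return out


def corpus_table(annotations: Sequence[CohortAnnotation]) -> pd.DataFrame:
    """Flat one-row-per-cohort table for inspection / CSV export."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "source_id": a.source_id,
                "publication_year": a.publication_year,
                "cohort_label": a.cohort_label,
                "path_diagnosis": a.path_diagnosis,
                "n_cases": a.n_cases,
                "n_female": a.n_female,
                "n_male": a.n_male,
                "onset_mean": a.onset.mean if a.onset else None,
                "onset_sd": a.onset.sd if a.onset else None,
                "death_mean": a.death.mean if a.death else None,
                "duration_mean": a.duration.mean if a.duration else None,
                "onset_reference": a.onset_reference,
                "n_clinical_diagnosed": sum(c.count for c in a.clinical_diagnoses) or None,
                "n_phenotype_terms": len(a.phenotypes),
                "dual_diagnosis": a.dual_diagnosis,
            }
        )
    return pd.DataFrame(rows)
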