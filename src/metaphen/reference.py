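"""Published summary statistics used as defaults across the package.

These are the pooled clinicopathological literature values for the five main
Parkinsonian disorders: Parkinson's disease (PD), multiple system atrophy
(MSA), progressive supranuclear palsy (PSP), dementia with Lewy bodies (DLB)
and corticobasal degeneration (CBD). They parameterise the synthetic-corpus
generator defaults and the worked examples; they are literature summaries,
not ground truth for any particular cohort.

Ages are decimal years. Counts are post-mortem-confirmed cases.
"""

from __future__ import annotations

MAIN_DISEASES: tuple[str, ...] = ("PD", "MSA", "PSP", "DLB", "CBD")

#: Pooled age of symptom onset, mean and SD in years, per disease.
ONSET_MEAN_SD: dict[str, tuple[float, float]] = {
    "PD": (62.75, 11.11),
    "MSA": (59.19, 9.12),
    "PSP": (65.60, 8.10),
    "DLB": (69.34, 10.46),
    "CBD": (62.64, 7.78),
}

#: Pooled age at death, mean and SD in years.
DEATH_MEAN_SD: dict[str, tuple[float, float]] = {
    "PD": (77.37, 7.86),
    "MSA": (66.49, 8.52),
    "PSP": (73.87, 7.93),
    "DLB": (78.59, 8.52),
    "CBD": (70.77, 7.64),
}

#: Pooled disease duration (onset to death), mean and SD in years.
DURATION_MEAN_SD: dict[str, tuple[float, float]] = {
    "PD": (14.64, 6.96),
    "MSA": (7.19, 2.60),
    "PSP": (7.39, 3.80),
    "DLB": (7.85, 5.75),
    "CBD": (6.91, 3.26),
}

#: Post-mortem diagnosed cases per disease in the full published corpus
#: (125 publications, 610 annotations).
CORPUS_CASE_COUNTS: dict[str, int] = {
    "PD": 2406,
    "MSA": 1594,
    "PSP": 1835,
    "DLB": 834,
    "CBD": 354,
    "OTHER": 2264,
}

#: Cases with clinical-vs-pathological cross-tabulation (misdiagnosis subset).
MISDIAGNOSIS_CASE_COUNTS: dict[str, int] = {
    "PD": 1698,
    "MSA": 965,
    "PSP": 1349,
    "DLB": 347,
    "CBD": 265,
    "OTHER": 1124,
}

#: Cases reporting biological sex, and the female proportion among them.
N_SEX_REPORTED: int = 4341
FEMALE_PROPORTION: float = 0.38

#: Fraction of timing data referenced to diagnosis rather than symptom onset.
DIAGNOSIS_REFERENCED_FRACTION: float = 0.15

#: Published external diagnostic tests as (sensitivity, specificity).
#: NFLC (blood/CSF neurofilament light chain) was validated for atypical
#: Parkinsonism (MSA/PSP) against PD; RT-QuIC / seed amplification detects
#: misfolded alpha-synuclein (Lewy body disease vs not).
NFLC_SENS_SPEC: tuple[float, float] = (0.86, 0.85)
RTQUIC_SENS_SPEC: tuple[float, float] = (0.98, 0.953)

#: Default Gaussian model supports in years: symptom onset age and survival.
ONSET_SUPPORT: tuple[float, float] = (30.0, 100.0)
SURVIVAL_SUPPORT: tuple[float, float] = (0.0, 30.0)
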