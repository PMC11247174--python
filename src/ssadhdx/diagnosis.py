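"""Integrated molecular + biochemical + metabolomic diagnosis and cohort summaries.

The diagnostic call combines two confirmatory evidence channels:

- molecular: biallelic pathogenic / likely pathogenic *ALDH5A1* variants
  (homozygous or compound heterozygous);
- biochemical/metabolomic: elevated urine GHB (> 7 mmol/mol creatinine) or a
  positive plasma/urine SSADHD metabolomic signature.

Both channels met -> comprehensively confirmed; one -> molecularly confirmed
or biochemically supported; neither, but suggestive clinical features or
brain imaging -> suspected; otherwise not supported.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ssadhdx.metabolomics import Call, ZScoreProfile, ghb_flag, ssadhd_signature
from ssadhdx.variants import (
    Classification,
    PATHOGENIC_CLASSES,
    normalize_hgvs,
    novel_fraction,
    truncate_percent,
    unique_variant_count,
)

PEDIATRIC_MAX_AGE = 18.0

#: Clinical features that justify suspicion of a GABA-catabolism disorder.
DEFAULT_SUSPICION_FLAGS = frozenset(
    {
        "developmental_delay",
        "hypotonia",
        "seizures",
        "ataxia",
        "autistic_features",
        "speech_delay",
        "failure_to_thrive",
        "stroke",
        "abnormal_urine_organic_acids",
    }
)


class Zygosity(str, enum.Enum):
    HOMOZYGOUS = "homozygous"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"
    SINGLE_HETEROZYGOUS = "single_heterozygous"
    NONE = "none"


class DiagnosisStatus(str, enum.Enum):
    COMPREHENSIVELY_CONFIRMED = "comprehensively_confirmed"
    MOLECULARLY_CONFIRMED = "molecularly_confirmed"
    BIOCHEMICALLY_SUPPORTED = "biochemically_supported"
    SUSPECTED = "suspected"
    NOT_SUPPORTED = "not_supported"


#: Evidence ordering used by the monotonicity property: adding positive
#: evidence may only move a subject up this ranking.
STATUS_RANK = {
    DiagnosisStatus.NOT_SUPPORTED: 0,
    DiagnosisStatus.SUSPECTED: 1,
    DiagnosisStatus.BIOCHEMICALLY_SUPPORTED: 2,
    DiagnosisStatus.MOLECULARLY_CONFIRMED: 2,
    DiagnosisStatus.COMPREHENSIVELY_CONFIRMED: 3,
}


@dataclass
class SubjectRecord:
    """One individual: demographics, clinical flags, biochemistry, genotype."""

    subject_id: str
    age_years: float | None = None
    sex: str = "unknown"  # {M, F, unknown}
    clinical_flags: frozenset[str] = field(default_factory=frozenset)
    urine_ghb: float | None = None  # mmol/mol creatinine
    ghb_reported_elevated: bool = False  # free-text "elevated GHB" report
    imaging_suggestive: bool | None = None
    allele1: str | None = None
    allele2: str | None = None
    allele_classifications: tuple[Classification, Classification] | None = None
    zprofile: ZScoreProfile | None = None

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"sex must be M, F or unknown, got {self.sex!r}")

    @property
    def alleles(self) -> list[str]:
        return [normalize_hgvs(a) for a in (self.allele1, self.allele2) if a]


@dataclass(frozen=True)
class Diagnosis:
    subject_id: str
    status: DiagnosisStatus
    rationale: tuple[str, ...]


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_male: int
    n_female: int
    pct_male: float
    pct_female: float
    mean_age: float
    median_age: float
    sd_age: float | None
    n_pediatric: int
    n_adult: int
    n_homozygous: int
    n_unique_variants: int
    n_novel_variants: int | None = None
    pct_novel: float | None = None


def zygosity(allele1: str | None, allele2: str | None) -> Zygosity:
    """Zygosity from two (normalized) cDNA allele strings."""
    a1 = normalize_hgvs(allele1) if allele1 else ""
    a2 = normalize_hgvs(allele2) if allele2 else ""
    if a1 and a2:
        return Zygosity.HOMOZYGOUS if a1 == a2 else Zygosity.COMPOUND_HETEROZYGOUS
    if a1 or a2:
        return Zygosity.SINGLE_HETEROZYGOUS
    return Zygosity.NONE


def _molecular_criterion(s: SubjectRecord) -> bool:
    zyg = zygosity(s.allele1, s.allele2)
    if zyg not in (Zygosity.HOMOZYGOUS, Zygosity.COMPOUND_HETEROZYGOUS):
        return False
    if s.allele_classifications is None:
        return False
    return all(c in PATHOGENIC_CLASSES for c in s.allele_classifications)


def _biochemical_criterion(s: SubjectRecord) -> tuple[bool, list[str]]:
    reasons = []
    if s.urine_ghb is not None and ghb_flag(s.urine_ghb) == "elevated":
        reasons.append(f"urine GHB elevated ({s.urine_ghb:g} mmol/mol creatinine)")
    if s.ghb_reported_elevated:
        reasons.append("urine GHB reported elevated")
    if s.zprofile is not None:
        try:
            sig = ssadhd_signature(s.zprofile)
        except ValueError:
            sig = None
        if sig is not None and sig.call is Call.POSITIVE:
            reasons.append(f"{s.zprofile.specimen} metabolomic signature positive")
    return bool(reasons), reasons


def integrated_diagnosis(
    s: SubjectRecord,
    suspicion_flags: frozenset[str] = DEFAULT_SUSPICION_FLAGS,
) -> Diagnosis:
    """Combine evidence channels into a diagnostic status with rationale."""
    has_any = (
        s.alleles
        or s.urine_ghb is not None
        or s.ghb_reported_elevated
        or s.zprofile is not None
        or s.clinical_flags
        or s.imaging_suggestive is not None
    )
    if not has_any:
        raise ValueError(f"subject {s.subject_id}: no evidence channel present")

    rationale: list[str] = []
    molecular = _molecular_criterion(s)
    if molecular:
        rationale.append(
            f"biallelic P/LP variants ({zygosity(s.allele1, s.allele2).value}): "
            + " / ".join(s.alleles)
        )
    biochemical, reasons = _biochemical_criterion(s)
    rationale.extend(reasons)

    if molecular and biochemical:
        status = DiagnosisStatus.COMPREHENSIVELY_CONFIRMED
    elif molecular:
        status = DiagnosisStatus.MOLECULARLY_CONFIRMED
    elif biochemical:
        status = DiagnosisStatus.BIOCHEMICALLY_SUPPORTED
    else:
        suggestive = sorted(s.clinical_flags & suspicion_flags)
        if suggestive or s.imaging_suggestive:
            status = DiagnosisStatus.SUSPECTED
            if suggestive:
                rationale.append("clinical features: " + ", ".join(suggestive))
            if s.imaging_suggestive:
                rationale.append("characteristic brain imaging")
        else:
            status = DiagnosisStatus.NOT_SUPPORTED
            rationale.append("no supporting evidence")
    return Diagnosis(s.subject_id, status, tuple(rationale))


def cohort_summary(
    subjects: Sequence[SubjectRecord],
    known_variants: Iterable[str] | None = None,
    pediatric_max: float = PEDIATRIC_MAX_AGE,
) -> CohortSummary:
    """Demographic, zygosity and allele-level summary of a cohort.

    Ages must be present.  ``known_variants`` enables the novel-variant
    fraction (distinct alleles absent from the known set, percentage
    truncated to one decimal).  Homozygous subjects are counted per subject
    (siblings sharing a genotype count separately).
    """
    if not subjects:
        raise ValueError("empty cohort")
    ages = [s.age_years for s in subjects]
    if any(a is None for a in ages):
        raise ValueError("every subject needs age_years for a cohort summary")
    n = len(subjects)
    n_male = sum(s.sex == "M" for s in subjects)
    n_female = sum(s.sex == "F" for s in subjects)
    alleles = [a for s in subjects for a in s.alleles]
    n_unique = unique_variant_count(alleles)
    n_novel = pct_novel = None
    if known_variants is not None:
        known = {normalize_hgvs(a) for a in known_variants}
        distinct = {normalize_hgvs(a) for a in alleles}
        n_novel = len(distinct - known)
        pct_novel = novel_fraction(alleles, known)
    return CohortSummary(
        n=n,
        n_male=n_male,
        n_female=n_female,
        pct_male=truncate_percent(n_male, n),
        pct_female=truncate_percent(n_female, n),
        mean_age=round(statistics.fmean(ages), 1),
        median_age=statistics.median(ages),
        sd_age=round(statistics.stdev(ages), 2) if n >= 2 else None,
        n_pediatric=sum(a <= pediatric_max for a in ages),
        n_adult=sum(a > pediatric_max for a in ages),
        n_homozygous=sum(
            zygosity(s.allele1, s.allele2) is Zygosity.HOMOZYGOUS for s in subjects
        ),
        n_unique_variants=n_unique,
        n_novel_variants=n_novel,
        pct_novel=pct_novel,
    )


# ---------------------------------------------------------------------------
# Cohort table I/O

def subjects_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Build SubjectRecords from a cohort table.

    Expected columns: subject_id, age_years, sex, clinical_flags
    (semicolon-separated), urine_ghb (empty = not measured),
    ghb_reported_elevated (0/1), imaging_suggestive (0/1), allele1, allele2,
    class1, class2.  Missing columns default to absent evidence.
    """
    def get(row, col, default=""):
        v = row.get(col, default)
        return "" if pd.isna(v) else str(v).strip()

    subjects = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in get(row, "clinical_flags").split(";") if f)
        ghb_raw = get(row, "urine_ghb")
        cls_raw = (get(row, "class1"), get(row, "class2"))
        classifications = None
        if all(cls_raw):
            classifications = (Classification(cls_raw[0]), Classification(cls_raw[1]))
        subjects.append(
            SubjectRecord(
                subject_id=get(row, "subject_id"),
                age_years=float(get(row, "age_years")) if get(row, "age_years") else None,
                sex=get(row, "sex") or "unknown",
                clinical_flags=flags,
                urine_ghb=float(ghb_raw) if ghb_raw else None,
                ghb_reported_elevated=get(row, "ghb_reported_elevated") in ("1", "True", "true"),
                imaging_suggestive=get(row, "imaging_suggestive") in ("1", "True", "true") or None,
                allele1=get(row, "allele1") or None,
                allele2=get(row, "allele2") or None,
                allele_classifications=classifications,
            )
        )
    return subjects


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a tab-separated cohort table into SubjectRecords."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError("cohort table needs a subject_id column")
    return subjects_from_frame(df)
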