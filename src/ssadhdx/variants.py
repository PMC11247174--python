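"""Rule-based pathogenicity classification of *ALDH5A1* variants.

The classifier encodes the loss-of-function criteria used for recessive
prevalence estimation from population allele-frequency databases: a variant
is pathogenic / likely pathogenic when it truncates the protein (stop-gain,
frameshift, start-loss, or a canonical ±1/±2 splice-site change) or has been
reported in a confirmed affected individual; stop-loss variants stay variants
of uncertain significance; benign-asserted or implausibly common variants are
excluded.  A second, "extended" inclusion tier adds unreported variants that
stringent computational predictions flag as deleterious: missense with CADD
PHRED ≥ 28.0, or any potentially spliceogenic variant with a SpliceAI max
delta ≥ 0.2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Population labels of the gnomAD-v4-style export this package emulates.
POPULATIONS = (
    "pan_ethnic",
    "african",
    "east_asian",
    "south_asian",
    "admixed_american",
    "ashkenazi",
    "remaining",
    "european_non_finnish",
    "european_finnish",
    "middle_eastern",
    "amish",
)

TRANSCRIPTS = ("NM_001080", "NM_017040")

#: Default frequency guard: an allele this common in any population is more
#: frequent than expected for an ultra-rare recessive disease.
DEFAULT_MAX_CREDIBLE_AF = 0.01

DEFAULT_CADD_CUTOFF = 28.0
DEFAULT_SPLICEAI_CUTOFF = 0.2


class Consequence(str, enum.Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    START_LOSS = "start_loss"
    STOP_LOSS = "stop_loss"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Consequence classes treated as protein-truncating without further evidence.
TRUNCATING = frozenset(
    {Consequence.STOP_GAIN, Consequence.FRAMESHIFT, Consequence.START_LOSS}
)


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    EXCLUDED_BENIGN = "excluded_benign"
    EXCLUDED_FREQUENCY = "excluded_frequency"


PATHOGENIC_CLASSES = frozenset(
    {Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC}
)


class InclusionTier(str, enum.Enum):
    BASE = "base"
    EXTENDED_ONLY = "extended_only"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class PopulationAlleleStats:
    """Allele count / allele number for one variant in one population."""

    population: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population label: {self.population!r}")
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError(
                f"allele_count {self.allele_count} outside [0, AN={self.allele_number}]"
            )

    @property
    def af(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class VariantRecord:
    """One *ALDH5A1* variant with annotations and per-population statistics.

    ``splice_offset`` is the signed distance in bp from the nearest canonical
    splice-site boundary (None when not annotated).  ``cadd_phred`` and
    ``spliceai_max`` may be absent (None); absent scores simply fail the
    extended-tier branches.
    """

    variant_id: str
    hgvs_c: str
    consequence: Consequence
    hgvs_p: str = ""
    transcript: str = "NM_001080"
    splice_offset: int | None = None
    cadd_phred: float | None = None
    spliceai_max: float | None = None
    reported_in_affected: bool = False
    asserted_benign: bool = False
    population_stats: tuple[PopulationAlleleStats, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.transcript not in TRANSCRIPTS:
            raise ValueError(f"unknown transcript: {self.transcript!r}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        if self.spliceai_max is not None and not 0.0 <= self.spliceai_max <= 1.0:
            raise ValueError("spliceai_max must be in [0, 1]")
        pops = [s.population for s in self.population_stats]
        if len(pops) != len(set(pops)):
            raise ValueError("population_stats has duplicate population labels")

    def stats_for(self, population: str) -> PopulationAlleleStats | None:
        for s in self.population_stats:
            if s.population == population:
                return s
        return None


def classify_variant(
    v: VariantRecord, max_credible_af: float = DEFAULT_MAX_CREDIBLE_AF
) -> Classification:
    """Apply the pathogenicity rules to one variant.

    Precedence: a benign/likely-benign assertion excludes the variant; next,
    an allele frequency above ``max_credible_af`` in any population excludes
    it; then a previous report in a confirmed affected individual makes it
    pathogenic (except stop-loss, which is never P/LP); an unreported
    truncating change (stop-gain, frameshift, start-loss, or canonical splice
    at ±1/±2) is likely pathogenic; everything else is a VUS.
    """
    if max_credible_af <= 0:
        raise ValueError("max_credible_af must be positive")
    if v.asserted_benign:
        return Classification.EXCLUDED_BENIGN
    if any(s.af > max_credible_af for s in v.population_stats):
        return Classification.EXCLUDED_FREQUENCY
    if v.reported_in_affected and v.consequence is not Consequence.STOP_LOSS:
        return Classification.PATHOGENIC
    if v.consequence is Consequence.CANONICAL_SPLICE:
        if v.splice_offset is None:
            raise ValueError(
                f"{v.variant_id}: canonical_splice variant without splice_offset; "
                "cannot apply the +/-1/2 window"
            )
        if abs(v.splice_offset) in (1, 2):
            return Classification.LIKELY_PATHOGENIC
        return Classification.VUS
    if v.consequence in TRUNCATING:
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


def assign_inclusion_tier(
    v: VariantRecord,
    c: Classification,
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF,
    spliceai_cutoff: float = DEFAULT_SPLICEAI_CUTOFF,
) -> InclusionTier:
    """Assign the prevalence-analysis inclusion tier given a classification.

    P/LP variants always belong to the base tier.  A VUS joins the extended
    tier when it is missense with CADD PHRED at or above ``cadd_cutoff``, or
    when its SpliceAI max delta is at or above ``spliceai_cutoff`` (both
    boundaries inclusive).  Excluded classifications never contribute.
    """
    if c in PATHOGENIC_CLASSES:
        return InclusionTier.BASE
    if c is Classification.VUS:
        cadd_hit = (
            v.consequence is Consequence.MISSENSE
            and v.cadd_phred is not None
            and v.cadd_phred >= cadd_cutoff
        )
        splice_hit = v.spliceai_max is not None and v.spliceai_max >= spliceai_cutoff
        if cadd_hit or splice_hit:
            return InclusionTier.EXTENDED_ONLY
    return InclusionTier.EXCLUDED


# ---------------------------------------------------------------------------
# Table I/O

_REQUIRED_COLUMNS = (
    "variant_id",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "splice_offset",
    "cadd_phred",
    "spliceai_max",
    "reported_in_affected",
    "asserted_benign",
)

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(raw: str, column: str, row: int) -> bool:
    try:
        return _BOOL_MAP[raw.strip().lower()]
    except KeyError:
        raise ValueError(f"row {row}: malformed boolean in {column}: {raw!r}") from None


def _parse_optional_float(raw: str, column: str, row: int) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"row {row}: malformed number in {column}: {raw!r}") from None


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant table into validated records.

    Expected columns: the annotation columns listed in the module docs plus
    ``AC_<pop>`` / ``AN_<pop>`` pairs.  Empty strings mean "absent".  Rows
    violating an invariant (AC > AN, malformed numbers, duplicated
    variant_id) are rejected with row-numbered messages; row numbers count
    data rows from 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Validate an in-memory variant table (string cells, as read from TSV)."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    pop_cols = []
    for pop in POPULATIONS:
        ac, an = f"AC_{pop}", f"AN_{pop}"
        if ac in df.columns or an in df.columns:
            if ac not in df.columns or an not in df.columns:
                raise ValueError(f"population {pop}: need both {ac} and {an}")
            pop_cols.append(pop)

    records: list[VariantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        vid = row["variant_id"].strip()
        if not vid:
            raise ValueError(f"row {i}: empty variant_id")
        if vid in seen:
            raise ValueError(f"row {i}: duplicate variant_id {vid!r}")
        seen.add(vid)
        stats = []
        for pop in pop_cols:
            ac_raw = row[f"AC_{pop}"].strip()
            an_raw = row[f"AN_{pop}"].strip()
            if ac_raw == "" and an_raw == "":
                continue
            try:
                ac, an = int(ac_raw), int(an_raw)
            except ValueError:
                raise ValueError(
                    f"row {i}: malformed AC/AN for population {pop}"
                ) from None
            try:
                stats.append(PopulationAlleleStats(pop, ac, an))
            except ValueError as e:
                raise ValueError(f"row {i}: {e}") from None
        offset_raw = row["splice_offset"].strip()
        try:
            offset = int(offset_raw) if offset_raw else None
        except ValueError:
            raise ValueError(f"row {i}: malformed splice_offset: {offset_raw!r}") from None
        try:
            cons = Consequence(row["consequence"].strip())
        except ValueError:
            raise ValueError(
                f"row {i}: unknown consequence {row['consequence']!r}"
            ) from None
        try:
            rec = VariantRecord(
                variant_id=vid,
                hgvs_c=normalize_hgvs(row["hgvs_c"]),
                hgvs_p=row["hgvs_p"].strip(),
                transcript=row["transcript"].strip(),
                consequence=cons,
                splice_offset=offset,
                cadd_phred=_parse_optional_float(row["cadd_phred"], "cadd_phred", i),
                spliceai_max=_parse_optional_float(row["spliceai_max"], "spliceai_max", i),
                reported_in_affected=_parse_bool(row["reported_in_affected"], "reported_in_affected", i),
                asserted_benign=_parse_bool(row["asserted_benign"], "asserted_benign", i),
                population_stats=tuple(stats),
            )
        except ValueError as e:
            raise ValueError(f"row {i}: {e}") from None
        records.append(rec)
    return records


def classify_table(
    records: Sequence[VariantRecord],
    max_credible_af: float = DEFAULT_MAX_CREDIBLE_AF,
    cadd_cutoff: float = DEFAULT_CADD_CUTOFF,
    spliceai_cutoff: float = DEFAULT_SPLICEAI_CUTOFF,
) -> list[tuple[VariantRecord, Classification, InclusionTier]]:
    """Classify and tier every record (order-preserving)."""
    out = []
    for v in records:
        c = classify_variant(v, max_credible_af)
        t = assign_inclusion_tier(v, c, cadd_cutoff, spliceai_cutoff)
        out.append((v, c, t))
    return out


def classification_summary(
    classified: Sequence[tuple[VariantRecord, Classification, InclusionTier]],
) -> dict:
    """Counts per classification and per inclusion tier."""
    by_class: dict[str, int] = {}
    by_tier: dict[str, int] = {}
    for _, c, t in classified:
        by_class[c.value] = by_class.get(c.value, 0) + 1
        by_tier[t.value] = by_tier.get(t.value, 0) + 1
    return {"n": len(classified), "by_classification": by_class, "by_tier": by_tier}


# ---------------------------------------------------------------------------
# Allele-level identity

def normalize_hgvs(allele: str) -> str:
    """Whitespace-strip and map unicode dashes to ASCII hyphens.

    cDNA HGVS string equality (on one transcript) is variant identity here;
    protein-annotation discrepancies do not split a variant.
    """
    return allele.strip().replace("–", "-").replace("−", "-")


def unique_variant_count(alleles: Iterable[str]) -> int:
    """Number of distinct cDNA-level alleles (empty entries ignored)."""
    distinct = {normalize_hgvs(a) for a in alleles if a and normalize_hgvs(a)}
    return len(distinct)


def truncate_percent(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal, e.g. 3/19 -> 15.7."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    return math.floor(1000.0 * numerator / denominator) / 10.0


def novel_fraction(alleles: Iterable[str], known_set: Iterable[str]) -> float:
    """Percent of distinct alleles absent from ``known_set`` (one decimal, truncated)."""
    distinct = {normalize_hgvs(a) for a in alleles if a and normalize_hgvs(a)}
    if not distinct:
        raise ValueError("no alleles supplied")
    known = {normalize_hgvs(a) for a in known_set}
    n_novel = len(distinct - known)
    return truncate_percent(n_novel, len(distinct))
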