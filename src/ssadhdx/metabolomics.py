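"""Untargeted-metabolomics z-score pipeline and GABA-pathway signatures.

Semiquantitative LC-MS intensities are made comparable across analytical
batches by dividing each value by the per-batch median of invariant anchor
specimens, then natural-log transformed and scored against a normal reference
population: z = (log(value) - mean_log) / sd_log per metabolite.  A result is
abnormal when |z| >= 2.

Signature calls encode the disease patterns of the GABA degradation pathway:

- SSADH deficiency, plasma: joint elevation of 2-pyrrolidinone (the stable
  lactam of GABA) and 4-guanidinobutanoate (GABA transamidination product).
  Adults attenuate — 4-guanidinobutanoate often sits high-normal
  (z in roughly [1.7, 2.4)) with normal 2-pyrrolidinone — so a "supportive"
  band catches that pattern below the +2 threshold.
- SSADH deficiency, urine: joint elevation of 4-guanidinobutanoate and
  succinimide; urinary 2-pyrrolidinone is uninformative and carries no weight.
- GABA-transaminase deficiency, plasma: joint elevation of 2-pyrrolidinone
  and succinamic acid.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SPECIMENS = ("plasma", "urine", "csf")

# Canonical metabolite names used by the signature logic.
PYRROLIDINONE = "2-pyrrolidinone"
GUANIDINOBUTANOATE = "4-guanidinobutanoate"
ARGININATE = "argininate"
SUCCINAMATE = "succinamic acid"
SUCCINIMIDE = "succinimide"

ABNORMAL_Z = 2.0           # |z| >= 2 is abnormal (inclusive)
SUPPORTIVE_Z = 1.7         # adult high-normal band for 4-guanidinobutanoate
GHB_NORMAL_MAX = 7.0       # urine GHB normal range 0-7 mmol/mol creatinine
PEDIATRIC_MAX_AGE = 18.0   # pediatric <= 18 y, adult >= 19 y


class Flag(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    NORMAL = "normal"
    NOT_REPORTED = "not_reported"


class Call(str, enum.Enum):
    POSITIVE = "positive"
    SUPPORTIVE = "supportive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


@dataclass
class IntensityMatrix:
    """Raw or normalized intensities: samples x metabolites.

    ``values`` is a DataFrame indexed by sample id with metabolite columns;
    NaN marks a missing measurement.  ``batch_of`` and ``anchor_flags`` map
    sample id -> batch label / anchor status.
    """

    values: pd.DataFrame
    specimen: str
    batch_of: Mapping[str, str]
    anchor_flags: Mapping[str, bool]

    def __post_init__(self) -> None:
        if self.specimen not in SPECIMENS:
            raise ValueError(f"unknown specimen {self.specimen!r}")
        missing = [s for s in self.values.index if s not in self.batch_of]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")
        if (self.values.to_numpy(dtype=float, na_value=0.0) < 0).any():
            raise ValueError("intensities must be non-negative")
        batches = set(self.batch_of[s] for s in self.values.index)
        for b in batches:
            members = [s for s in self.values.index if self.batch_of[s] == b]
            if not any(self.anchor_flags.get(s, False) for s in members):
                raise ValueError(f"batch {b!r} has no anchor sample")

    @property
    def anchors(self) -> list[str]:
        return [s for s in self.values.index if self.anchor_flags.get(s, False)]


@dataclass(frozen=True)
class ReferenceStats:
    """Per-metabolite location/scale of the log-normalized reference cohort."""

    mean_log: pd.Series
    sd_log: pd.Series
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("reference cohort must have n >= 2")
        if (self.sd_log <= 0).any():
            raise ValueError("sd_log must be positive for every metabolite")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.mean_log.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_log": self.mean_log, "sd_log": self.sd_log, "n": self.n}
        )


@dataclass
class ZScoreProfile:
    """One sample's z-scores and abnormality flags."""

    sample_id: str
    specimen: str
    z: pd.Series
    age_years: float | None = None

    def flag(self, metabolite: str) -> Flag:
        if metabolite not in self.z.index or pd.isna(self.z[metabolite]):
            return Flag.NOT_REPORTED
        v = self.z[metabolite]
        if v >= ABNORMAL_Z:
            return Flag.HIGH
        if v <= -ABNORMAL_Z:
            return Flag.LOW
        return Flag.NORMAL

    @property
    def abnormal_flags(self) -> dict[str, Flag]:
        return {m: self.flag(m) for m in self.z.index}


@dataclass(frozen=True)
class SignatureCall:
    sample_id: str
    disease: str  # "SSADHD" | "GABA_TD"
    call: Call
    evidence: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupStats:
    """Age association and pediatric-vs-adult contrast for one marker."""

    marker: str
    slope_per_year: float
    regression_p: float
    t_statistic: float      # NaN when a group has < 2 members
    ttest_p: float          # NaN when not estimable
    mean_pediatric: float
    mean_adult: float
    n_pediatric: int
    n_adult: int


# ---------------------------------------------------------------------------
# Pipeline steps

def creatinine_normalize(
    values: pd.DataFrame, creatinine: pd.Series | Mapping[str, float]
) -> pd.DataFrame:
    """Divide each urine sample's intensities by its creatinine level."""
    cr = pd.Series(creatinine, dtype=float).reindex(values.index)
    if cr.isna().any():
        missing = list(values.index[cr.isna()])
        raise ValueError(f"missing creatinine for sample(s): {missing[:5]}")
    if (cr <= 0).any():
        bad = list(values.index[cr <= 0])
        raise ValueError(f"non-positive creatinine for sample(s): {bad[:5]}")
    return values.div(cr, axis=0)


def anchor_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each value by the per-batch anchor median of its metabolite.

    Anchor medians become 1 by construction, so any multiplicative factor
    shared by a whole batch (instrument drift, run-to-run gain) cancels.
    A metabolite with no anchor coverage in a batch cannot be normalized
    there: its values become missing, with a warning.
    """
    values = m.values.astype(float)
    out = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    batches: dict[str, list[str]] = {}
    for s in values.index:
        batches.setdefault(m.batch_of[s], []).append(s)
    for batch, members in batches.items():
        anchors = [s for s in members if m.anchor_flags.get(s, False)]
        med = values.loc[anchors].median(axis=0, skipna=True)
        uncovered = med.index[med.isna() | (med == 0)]
        if len(uncovered):
            logger.warning(
                "batch %s: no usable anchor coverage for %d metabolite(s); "
                "values set missing",
                batch,
                len(uncovered),
            )
        ok = med.index.difference(uncovered)
        out.loc[members, ok] = values.loc[members, ok].div(med[ok], axis=1)
    return IntensityMatrix(
        values=out,
        specimen=m.specimen,
        batch_of=dict(m.batch_of),
        anchor_flags=dict(m.anchor_flags),
    )


def build_reference(normalized: pd.DataFrame, n: int | None = None) -> ReferenceStats:
    """Per-metabolite mean and sample SD (ddof=1) of log-normalized values.

    Non-positive values cannot be logged and count as missing.  Metabolites
    with fewer than two observations or zero spread are excluded with a
    warning (a constant column carries no information for scoring).
    """
    if len(normalized) < 2:
        raise ValueError("reference cohort must have >= 2 samples")
    logged = np.log(normalized.where(normalized > 0))
    counts = logged.notna().sum(axis=0)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    keep = (counts >= 2) & (sd > 0)
    dropped = list(normalized.columns[~keep])
    if dropped:
        logger.warning(
            "excluding %d metabolite(s) from reference (constant or <2 values): %s",
            len(dropped),
            dropped[:5],
        )
    return ReferenceStats(mean_log=mean[keep], sd_log=sd[keep], n=n or len(normalized))


def zscore_matrix(normalized: pd.DataFrame, ref: ReferenceStats) -> pd.DataFrame:
    """z = (log(value) - mean_log) / sd_log for every sample and metabolite."""
    cols = [c for c in normalized.columns if c in ref.mean_log.index]
    vals = normalized[cols]
    nonpos = (vals <= 0).sum().sum()
    if nonpos:
        logger.warning("%d non-positive value(s) at the log step; left unscored", nonpos)
    logged = np.log(vals.where(vals > 0))
    return (logged - ref.mean_log[cols]) / ref.sd_log[cols]


def zscore(
    normalized: IntensityMatrix,
    ref: ReferenceStats,
    ages: Mapping[str, float] | None = None,
) -> list[ZScoreProfile]:
    """Score every non-anchor sample of a normalized matrix against a reference."""
    zmat = zscore_matrix(normalized.values, ref)
    profiles = []
    for s in zmat.index:
        if normalized.anchor_flags.get(s, False):
            continue
        age = None if ages is None else ages.get(s)
        profiles.append(
            ZScoreProfile(
                sample_id=s, specimen=normalized.specimen, z=zmat.loc[s], age_years=age
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Signatures

def _z(p: ZScoreProfile, marker: str) -> float:
    if marker in p.z.index and not pd.isna(p.z[marker]):
        return float(p.z[marker])
    return math.nan


def ssadhd_signature(p: ZScoreProfile, supportive_z: float = SUPPORTIVE_Z) -> SignatureCall:
    """SSADHD biomarker signature call for a plasma or urine profile.

    Plasma: positive when both 2-pyrrolidinone and 4-guanidinobutanoate are
    high (z >= +2); supportive when exactly one of them is high, or when
    4-guanidinobutanoate reaches the high-normal band (z >= ``supportive_z``,
    the adult attenuation pattern), optionally reinforced by elevated
    argininate or succinamic acid; indeterminate when a core marker is not
    reported; negative otherwise.

    Urine: core markers are 4-guanidinobutanoate and succinimide; urinary
    2-pyrrolidinone carries no weight.
    """
    if p.specimen == "plasma":
        core = (PYRROLIDINONE, GUANIDINOBUTANOATE)
    elif p.specimen == "urine":
        core = (GUANIDINOBUTANOATE, SUCCINIMIDE)
    else:
        raise ValueError(f"unsupported specimen for SSADHD signature: {p.specimen!r}")

    flags = {m: p.flag(m) for m in core}
    evidence = {m: f"{m}: z={_z(p, m):+.2f} ({flags[m].value})" for m in core}
    if any(f is Flag.NOT_REPORTED for f in flags.values()):
        return SignatureCall(p.sample_id, "SSADHD", Call.INDETERMINATE, evidence)
    n_high = sum(f is Flag.HIGH for f in flags.values())
    if n_high == len(core):
        return SignatureCall(p.sample_id, "SSADHD", Call.POSITIVE, evidence)
    if p.specimen == "plasma":
        gba_band = _z(p, GUANIDINOBUTANOATE) >= supportive_z
        co_high = any(
            p.flag(m) is Flag.HIGH for m in (ARGININATE, SUCCINAMATE)
        )
        if gba_band and co_high:
            evidence["co-markers"] = "argininate/succinamic acid elevated"
        if n_high == 1 or gba_band:
            return SignatureCall(p.sample_id, "SSADHD", Call.SUPPORTIVE, evidence)
    elif n_high == 1:
        return SignatureCall(p.sample_id, "SSADHD", Call.SUPPORTIVE, evidence)
    return SignatureCall(p.sample_id, "SSADHD", Call.NEGATIVE, evidence)


def gabat_signature(p: ZScoreProfile) -> SignatureCall:
    """GABA-transaminase-deficiency signature: plasma 2-pyrrolidinone + succinamic acid."""
    if p.specimen != "plasma":
        raise ValueError("GABA-TD signature is defined for plasma only")
    core = (PYRROLIDINONE, SUCCINAMATE)
    flags = {m: p.flag(m) for m in core}
    evidence = {m: f"{m}: z={_z(p, m):+.2f} ({flags[m].value})" for m in core}
    if any(f is Flag.NOT_REPORTED for f in flags.values()):
        return SignatureCall(p.sample_id, "GABA_TD", Call.INDETERMINATE, evidence)
    n_high = sum(f is Flag.HIGH for f in flags.values())
    call = {2: Call.POSITIVE, 1: Call.SUPPORTIVE, 0: Call.NEGATIVE}[n_high]
    return SignatureCall(p.sample_id, "GABA_TD", call, evidence)


def ghb_flag(value_mmol_per_mol_cr: float, normal_max: float = GHB_NORMAL_MAX) -> str:
    """Flag a urine GHB value against the 0-7 mmol/mol creatinine normal range."""
    if value_mmol_per_mol_cr < 0:
        raise ValueError("GHB value must be non-negative")
    return "elevated" if value_mmol_per_mol_cr > normal_max else "normal"


# ---------------------------------------------------------------------------
# Group statistics

def age_group_stats(
    profiles: Sequence[ZScoreProfile],
    marker: str,
    pediatric_max: float = PEDIATRIC_MAX_AGE,
) -> GroupStats:
    """Age regression and pediatric-vs-adult contrast for one marker.

    Ordinary least squares of z on age (two-sided slope p-value) plus a
    pooled-variance two-sample two-tailed Student's t-test between the
    pediatric (age <= ``pediatric_max``) and adult groups.  With fewer than
    two members in either group the t-test is not estimable (NaN).
    """
    pairs = [
        (p.age_years, _z(p, marker))
        for p in profiles
        if p.age_years is not None and not math.isnan(_z(p, marker))
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 profiles with age and marker z")
    ages = np.array([a for a, _ in pairs])
    zs = np.array([z for _, z in pairs])
    fit = sps.linregress(ages, zs)
    ped = zs[ages <= pediatric_max]
    adu = zs[ages > pediatric_max]
    if len(ped) >= 2 and len(adu) >= 2:
        t, pval = sps.ttest_ind(ped, adu, equal_var=True)
    else:
        t, pval = math.nan, math.nan
    return GroupStats(
        marker=marker,
        slope_per_year=float(fit.slope),
        regression_p=float(fit.pvalue),
        t_statistic=float(t),
        ttest_p=float(pval),
        mean_pediatric=float(ped.mean()) if len(ped) else math.nan,
        mean_adult=float(adu.mean()) if len(adu) else math.nan,
        n_pediatric=int(len(ped)),
        n_adult=int(len(adu)),
    )
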