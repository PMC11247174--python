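"""Seeded generators for population variant tables and LC-MS-like matrices.

Every generator is deterministic given its seed and emits a
:class:`SyntheticTruth` alongside the dataset, carrying the planted
parameters (cumulative pathogenic allele frequencies, per-sample z-shifts)
so downstream estimates can be checked against ground truth.

The variant generator emulates a gnomAD-style export for *ALDH5A1*: a mix of
truncating (base-tier) variants, CADD/SpliceAI-qualifying (extended-tier)
variants, and decoys (synonymous, sub-threshold missense, stop-loss,
benign-asserted, implausibly common).  Allele counts are planted either
exactly (AC = round-half-even(AF·AN), so the realized Σ AC/AN is the planted
truth) or drawn binomially.

The metabolomics generator emulates the anchored LC-MS design: a reference
population with log-normal intensities, invariant anchor aliquots in every
batch, per-batch multiplicative gain factors (absorbed by anchor
normalization), and case groups whose disease markers are shifted in log
space by z_target · sd_log with z_target drawn uniformly from the target
range.  Case shifts are deterministic offsets (no extra individual noise),
so the observed z-score differs from the target only through
finite-reference estimation error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ssadhdx import metabolomics as mb
from ssadhdx.prevalence import q_from_carrier
from ssadhdx.variants import POPULATIONS

logger = logging.getLogger(__name__)

DEFAULT_ALLELE_NUMBER = 1_000_000

#: Default planted cumulative frequencies for the pan-ethnic population:
#: the base tier matches a carrier frequency of 1/376 and base+extended of
#: 1/236 — the conditions of the population analysis this package emulates.
DEFAULT_Q_BASE = q_from_carrier(1 / 376)
DEFAULT_Q_EXTENDED_ONLY = q_from_carrier(1 / 236) - q_from_carrier(1 / 376)


@dataclass
class SyntheticTruth:
    """Planted parameters emitted next to every simulated dataset."""

    seed: int
    q_planted: dict | None = None     # population -> {base, extended_only} (realized)
    q_requested: dict | None = None   # population -> requested targets
    z_targets: dict | None = None     # sample -> {marker: planted z}
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Variant tables

@dataclass
class VariantSimConfig:
    seed: int = 0
    populations: tuple[str, ...] = ("pan_ethnic",)
    allele_number: int = DEFAULT_ALLELE_NUMBER
    n_base: int = 6
    n_extended: int = 4
    n_decoy: int = 8
    target_q: Mapping[str, Mapping[str, float]] | None = None
    frac_reported: float = 0.5
    mode: str = "exact"  # "exact" | "binomial"

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "binomial"):
            raise ValueError("mode must be 'exact' or 'binomial'")
        unknown = set(self.populations) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown population label(s): {sorted(unknown)}")
        if self.target_q is None:
            self.target_q = {
                pop: {"base": DEFAULT_Q_BASE, "extended_only": DEFAULT_Q_EXTENDED_ONLY}
                for pop in self.populations
            }


_BASE_CYCLE = (
    ("stop_gain", None),
    ("frameshift", None),
    ("canonical_splice", 1),
    ("canonical_splice", -2),
    ("start_loss", None),
)


def _split_af(rng: np.random.Generator, total: float, n: int) -> np.ndarray:
    """Random positive shares of a cumulative frequency (deterministic)."""
    shares = rng.uniform(0.2, 1.0, size=n)
    return total * shares / shares.sum()


def simulate_variant_table(cfg: VariantSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a gnomAD-like variant table with planted cumulative q."""
    rng = np.random.default_rng(cfg.seed)
    an = cfg.allele_number
    rows: list[dict] = []

    def new_row(vid, cons, *, hgvs_c=None, offset=None, cadd=None, spliceai=None,
                reported=False, benign=False):
        return {
            "variant_id": vid,
            "transcript": "NM_001080",
            "hgvs_c": hgvs_c or f"c.{rng.integers(10, 1600)}{'ACGT'[rng.integers(4)]}>"
            f"{'TGCA'[rng.integers(4)]}",
            "hgvs_p": "",
            "consequence": cons,
            "splice_offset": "" if offset is None else str(offset),
            "cadd_phred": "" if cadd is None else f"{cadd:.1f}",
            "spliceai_max": "" if spliceai is None else f"{spliceai:.2f}",
            "reported_in_affected": "true" if reported else "false",
            "asserted_benign": "true" if benign else "false",
            "_af": {},  # requested AF per population; filled below
        }

    # base tier: truncating variants, a configurable fraction already reported
    n_reported = int(np.ceil(cfg.frac_reported * cfg.n_base))
    for i in range(cfg.n_base):
        cons, offset = _BASE_CYCLE[i % len(_BASE_CYCLE)]
        rows.append(
            new_row(f"base_{i + 1:02d}", cons, offset=offset, reported=i < n_reported)
        )
    base_ids = [r["variant_id"] for r in rows]

    # extended tier: unreported missense with CADD >= 28, or spliceogenic VUS
    for i in range(cfg.n_extended):
        if i % 2 == 0:
            r = new_row(f"ext_{i + 1:02d}", "missense", cadd=rng.uniform(28.0, 35.0))
        else:
            r = new_row(
                f"ext_{i + 1:02d}", "other", spliceai=rng.uniform(0.2, 0.9)
            )
        rows.append(r)
    ext_ids = [r["variant_id"] for r in rows if r["variant_id"].startswith("ext_")]

    # decoys: never contribute to any tier
    decoy_specs = [
        ("synonymous", {}),
        ("missense", {"cadd": 25.7}),
        ("stop_loss", {}),
        ("frameshift", {"benign": True}),
        ("missense", {"cadd": 30.0, "common": True}),
        ("other", {"spliceai": 0.15}),
        ("inframe_indel", {}),
        ("missense", {}),
    ]
    for i in range(cfg.n_decoy):
        cons, kw = decoy_specs[i % len(decoy_specs)]
        common = kw.pop("common", False)
        r = new_row(f"decoy_{i + 1:02d}", cons, **kw)
        r["_common"] = common
        rows.append(r)

    # plant allele frequencies per population
    q_requested: dict[str, dict[str, float]] = {}
    for pop in cfg.populations:
        targets = cfg.target_q[pop]
        q_requested[pop] = dict(targets)
        base_afs = _split_af(rng, targets["base"], cfg.n_base)
        ext_afs = (
            _split_af(rng, targets["extended_only"], cfg.n_extended)
            if cfg.n_extended
            else np.array([])
        )
        af_of = dict(zip(base_ids, base_afs)) | dict(zip(ext_ids, ext_afs))
        for r in rows:
            if r["variant_id"] in af_of:
                r["_af"][pop] = af_of[r["variant_id"]]
            elif r.get("_common"):
                r["_af"][pop] = 0.05
            else:
                r["_af"][pop] = float(rng.uniform(1e-6, 1e-4))

    # realize allele counts
    q_planted: dict[str, dict[str, float]] = {
        pop: {"base": 0.0, "extended_only": 0.0} for pop in cfg.populations
    }
    for r in rows:
        for pop in cfg.populations:
            af = r["_af"][pop]
            if cfg.mode == "exact":
                if 0 < af * an < 0.5:
                    logger.warning(
                        "%s/%s: requested AF %.3g yields < 1 allele at AN=%d; "
                        "variant drops to AC 0",
                        r["variant_id"], pop, af, an,
                    )
                ac = int(np.round(af * an))  # round-half-even
            else:
                ac = int(rng.binomial(an, af))
            r[f"AC_{pop}"] = str(ac)
            r[f"AN_{pop}"] = str(an)
            vid = r["variant_id"]
            realized = ac / an if cfg.mode == "exact" else af
            if vid.startswith("base_"):
                q_planted[pop]["base"] += realized
            elif vid.startswith("ext_"):
                q_planted[pop]["extended_only"] += realized
    for r in rows:
        r.pop("_af")
        r.pop("_common", None)

    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed=cfg.seed,
        q_planted=q_planted,
        q_requested=q_requested,
        extra={"mode": cfg.mode, "allele_number": an},
    )
    return df, truth


# ---------------------------------------------------------------------------
# Metabolomics matrices

DEFAULT_DECOY_COUNT = 15

#: Printed pediatric/adult z-score ranges the case groups are planted in.
SSADHD_PEDIATRIC_PLASMA = {
    mb.PYRROLIDINONE: (3.12, 6.50),
    mb.GUANIDINOBUTANOATE: (2.61, 4.03),
}
SSADHD_ADULT_PLASMA = {
    mb.PYRROLIDINONE: (0.02, 1.24),
    mb.GUANIDINOBUTANOATE: (1.70, 2.38),
}
SSADHD_PEDIATRIC_URINE = {
    mb.SUCCINIMIDE: (2.09, 3.16),
    mb.GUANIDINOBUTANOATE: (1.91, 2.78),
}
SSADHD_ADULT_URINE = {
    mb.SUCCINIMIDE: (1.02, 1.72),
    mb.GUANIDINOBUTANOATE: (1.91, 2.78),
}
GABAT_PLASMA = {
    mb.PYRROLIDINONE: (2.5, 5.0),
    mb.SUCCINAMATE: (2.5, 4.5),
}

CORE_PANEL = (
    mb.PYRROLIDINONE,
    mb.GUANIDINOBUTANOATE,
    mb.ARGININATE,
    mb.SUCCINAMATE,
    mb.SUCCINIMIDE,
)


@dataclass(frozen=True)
class CaseGroup:
    name: str
    n: int
    z_ranges: Mapping[str, tuple[float, float]]
    age_range: tuple[float, float]


@dataclass
class MetaboSimConfig:
    seed: int = 0
    specimen: str = "plasma"
    n_reference: int = 395
    n_batches: int = 8
    n_anchors_per_batch: int = 3
    n_decoys: int = DEFAULT_DECOY_COUNT
    mu_range: tuple[float, float] = (2.0, 8.0)
    sd_range: tuple[float, float] = (0.2, 0.6)
    anchor_log_sd: float = 0.02
    batch_log_sd: float = 0.5
    missing_rate: float = 0.0
    case_groups: tuple[CaseGroup, ...] = ()

    @property
    def panel(self) -> list[str]:
        return list(CORE_PANEL) + [f"metabolite_{i:02d}" for i in range(1, self.n_decoys + 1)]


def default_plasma_config(seed: int = 0, **overrides) -> MetaboSimConfig:
    """Plasma design: pediatric + adult SSADHD and GABA-TD case groups."""
    groups = (
        CaseGroup("ssadhd_pediatric_plasma", 8, SSADHD_PEDIATRIC_PLASMA, (0.5, 12.0)),
        CaseGroup("ssadhd_adult_plasma", 5, SSADHD_ADULT_PLASMA, (19.0, 44.0)),
        CaseGroup("gabat_plasma", 5, GABAT_PLASMA, (0.5, 12.0)),
    )
    return MetaboSimConfig(seed=seed, specimen="plasma", case_groups=groups, **overrides)


def default_urine_config(seed: int = 0, **overrides) -> MetaboSimConfig:
    """Urine design: pediatric + adult SSADHD case groups with creatinine."""
    groups = (
        CaseGroup("ssadhd_pediatric_urine", 7, SSADHD_PEDIATRIC_URINE, (0.5, 12.0)),
        CaseGroup("ssadhd_adult_urine", 5, SSADHD_ADULT_URINE, (19.0, 44.0)),
    )
    return MetaboSimConfig(seed=seed, specimen="urine", case_groups=groups, **overrides)


def simulate_metabolomics(
    cfg: MetaboSimConfig,
) -> tuple[mb.IntensityMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate an anchored intensity matrix, sample sheet and planted truth."""
    panel = cfg.panel
    for g in cfg.case_groups:
        missing = set(g.z_ranges) - set(panel)
        if missing:
            raise ValueError(f"case group {g.name}: markers not in panel: {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed)
    mu = rng.uniform(*cfg.mu_range, size=len(panel))
    sd = rng.uniform(*cfg.sd_range, size=len(panel))
    batch_factor = np.exp(rng.normal(0.0, cfg.batch_log_sd, size=cfg.n_batches))
    batch_names = [f"batch_{b + 1:02d}" for b in range(cfg.n_batches)]

    sample_ids: list[str] = []
    batch_of: dict[str, str] = {}
    anchor_flags: dict[str, bool] = {}
    meta_rows: list[dict] = []
    log_values: list[np.ndarray] = []
    z_targets: dict[str, dict[str, float]] = {}

    def add_sample(sid, batch_idx, logvals, *, is_anchor=False, is_reference=False,
                   group="", age=None, sex=""):
        sample_ids.append(sid)
        batch_of[sid] = batch_names[batch_idx]
        anchor_flags[sid] = is_anchor
        log_values.append(logvals + np.log(batch_factor[batch_idx]))
        meta_rows.append(
            {
                "sample_id": sid,
                "specimen": cfg.specimen,
                "batch": batch_names[batch_idx],
                "is_anchor": int(is_anchor),
                "is_reference": int(is_reference),
                "group": group,
                "age_years": "" if age is None else round(float(age), 1),
                "sex": sex,
            }
        )

    for b in range(cfg.n_batches):
        for a in range(cfg.n_anchors_per_batch):
            noise = rng.normal(0.0, cfg.anchor_log_sd, size=len(panel))
            add_sample(f"ANC_{b + 1:02d}_{a + 1}", b, mu + noise, is_anchor=True)

    for i in range(cfg.n_reference):
        eps = rng.standard_normal(len(panel))
        add_sample(
            f"REF_{i + 1:04d}",
            i % cfg.n_batches,
            mu + eps * sd,
            is_reference=True,
            age=rng.uniform(0.5, 18.0),
            sex="MF"[rng.integers(2)],
        )

    slot = cfg.n_reference
    for g in cfg.case_groups:
        for i in range(g.n):
            eps = rng.standard_normal(len(panel))
            logvals = mu + eps * sd
            sid = f"{g.name}_{i + 1:02d}"
            z_targets[sid] = {}
            for marker, (lo, hi) in g.z_ranges.items():
                j = panel.index(marker)
                zt = float(rng.uniform(lo, hi))
                logvals[j] = mu[j] + zt * sd[j]  # deterministic planted shift
                z_targets[sid][marker] = zt
            add_sample(
                sid,
                slot % cfg.n_batches,
                logvals,
                group=g.name,
                age=rng.uniform(*g.age_range),
                sex="MF"[rng.integers(2)],
            )
            slot += 1

    values = pd.DataFrame(np.exp(np.vstack(log_values)), index=sample_ids, columns=panel)
    sheet = pd.DataFrame(meta_rows)

    if cfg.specimen == "urine":
        creat = rng.uniform(2.0, 20.0, size=len(sample_ids))
        values = values.mul(creat, axis=0)
        sheet["creatinine"] = np.round(creat, 3)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        non_anchor = np.array([not anchor_flags[s] for s in sample_ids])
        mask &= non_anchor[:, None]
        values = values.mask(mask)

    matrix = mb.IntensityMatrix(
        values=values, specimen=cfg.specimen, batch_of=batch_of, anchor_flags=anchor_flags
    )
    truth = SyntheticTruth(
        seed=cfg.seed,
        z_targets=z_targets,
        extra={
            "specimen": cfg.specimen,
            "n_reference": cfg.n_reference,
            "mu_log": dict(zip(panel, mu.round(6).tolist())),
            "sd_log": dict(zip(panel, sd.round(6).tolist())),
        },
    )
    return matrix, sheet, truth


def score_simulated(
    matrix: mb.IntensityMatrix, sheet: pd.DataFrame
) -> tuple[mb.ReferenceStats, list[mb.ZScoreProfile]]:
    """Run the full pipeline on a simulated dataset.

    Creatinine-normalize (urine), anchor-normalize, build the reference from
    the flagged reference samples, and score every non-anchor sample.
    Returns the reference statistics and the case profiles (reference
    samples excluded).
    """
    m = matrix
    if "creatinine" in sheet.columns and matrix.specimen == "urine":
        creat = pd.Series(
            sheet.set_index("sample_id")["creatinine"], dtype=float
        ).reindex(matrix.values.index)
        m = mb.IntensityMatrix(
            values=mb.creatinine_normalize(matrix.values, creat),
            specimen=matrix.specimen,
            batch_of=dict(matrix.batch_of),
            anchor_flags=dict(matrix.anchor_flags),
        )
    normalized = mb.anchor_normalize(m)
    info = sheet.set_index("sample_id")
    ref_ids = [s for s in normalized.values.index if info.loc[s, "is_reference"] == 1]
    ref = mb.build_reference(normalized.values.loc[ref_ids], n=len(ref_ids))
    ages = {
        s: float(info.loc[s, "age_years"])
        for s in normalized.values.index
        if str(info.loc[s, "age_years"]) != ""
    }
    profiles = mb.zscore(normalized, ref, ages=ages)
    return ref, [p for p in profiles if p.sample_id not in set(ref_ids)]


# ---------------------------------------------------------------------------
# Cohorts

#: Genotype pool used when none is supplied (distinct cDNA alleles of the
#: bundled case series).
def _default_genotype_pool() -> list[str]:
    from ssadhdx.datasets import load_case_series

    df = load_case_series()
    return sorted(set(df["allele1"]) | set(df["allele2"]))


def simulate_cohort(
    n: int = 24,
    seed: int = 0,
    genotype_pool: Sequence[str] | None = None,
    pediatric_quota: float = 18 / 24,
    male_quota: float = 10 / 24,
    case_fraction: float = 1.0,
    quota_sampling: bool = True,
) -> pd.DataFrame:
    """Generate a cohort table shaped like the package's case series.

    With ``quota_sampling`` the pediatric/adult and sex splits are exact
    quotas (defaults mirror an 18:6 pediatric:adult, 10:14 male:female
    series); otherwise they are Bernoulli draws.  Cases draw urine GHB above
    the 0-7 mmol/mol creatinine normal range, controls within it.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    pool = list(genotype_pool) if genotype_pool is not None else _default_genotype_pool()
    if not pool:
        raise ValueError("genotype pool must be non-empty")

    if quota_sampling:
        n_ped = int(round(pediatric_quota * n))
        n_male = int(round(male_quota * n))
        pediatric = np.array([True] * n_ped + [False] * (n - n_ped))
        male = rng.permutation([True] * n_male + [False] * (n - n_male))
    else:
        pediatric = rng.random(n) < pediatric_quota
        male = rng.random(n) < male_quota
    is_case = rng.random(n) < case_fraction

    rows = []
    for i in range(n):
        age = rng.uniform(0.5, 12.0) if pediatric[i] else rng.uniform(19.0, 44.0)
        a1, a2 = rng.choice(pool, size=2)
        ghb = rng.uniform(50.0, 5000.0) if is_case[i] else rng.uniform(0.0, 7.0)
        rows.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "cohort": "simulated",
                "age_years": round(float(age), 1),
                "sex": "M" if male[i] else "F",
                "clinical_flags": "developmental_delay;hypotonia" if is_case[i] else "",
                "urine_ghb": round(float(ghb), 1),
                "ghb_reported_elevated": 0,
                "imaging_suggestive": 0,
                "allele1": a1 if is_case[i] else "",
                "allele2": a2 if is_case[i] else "",
                "class1": "pathogenic" if is_case[i] else "",
                "class2": "pathogenic" if is_case[i] else "",
            }
        )
    return pd.DataFrame(rows)
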