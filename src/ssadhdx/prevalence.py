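"""Hardy-Weinberg carrier-frequency and disease-prevalence estimation.

For an autosomal recessive disease, let q be the cumulative pathogenic allele
frequency in a population (the sum of qualifying per-variant minor allele
frequencies, assuming no linkage between the rare pathogenic alleles).  Under
Hardy-Weinberg equilibrium the carrier frequency is 2q(1-q) and the disease
prevalence is q².  The exact form 2q(1-q) — not the 2q approximation — is
used throughout: inverting published carrier frequencies with the exact form
reproduces the published prevalence figures, which the approximation does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from ssadhdx.variants import InclusionTier, VariantRecord, POPULATIONS

logger = logging.getLogger(__name__)

TIERS = ("base", "base_plus_extended")

#: Display string for populations with no qualifying alleles.
NOT_ESTIMABLE = "not estimable"


@dataclass(frozen=True)
class CumulativePathogenicFrequency:
    population: str
    tier: str
    q: float
    n_variants: int  # qualifying variants with AC > 0 in this population

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 0.5:
            raise ValueError(f"q={self.q} outside [0, 0.5]")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Carrier frequency 2q(1-q) and disease prevalence q² for one q."""

    q: float
    carrier_frequency: float
    disease_prevalence: float
    carrier_one_in: str
    prevalence_one_in: str
    population: str | None = None
    tier: str | None = None


@dataclass(frozen=True)
class TierComparison:
    population: str | None
    prevalence_base: float
    prevalence_extended: float
    fold_increase: float  # ratio of the "1 in N" denominators, one decimal


def cumulative_frequency(
    variants: Sequence[tuple[VariantRecord, InclusionTier]],
    population: str,
    tier: str = "base",
) -> CumulativePathogenicFrequency:
    """Sum qualifying per-variant allele frequencies for one population.

    ``tier="base"`` admits base-tier variants only; ``"base_plus_extended"``
    also admits the CADD/SpliceAI extended tier.  Records without statistics
    for the population contribute zero (logged as absent).
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population label: {population!r}")
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}, got {tier!r}")
    qualifying = {InclusionTier.BASE}
    if tier == "base_plus_extended":
        qualifying.add(InclusionTier.EXTENDED_ONLY)

    q = 0.0
    n_with_alleles = 0
    n_absent = 0
    for v, t in variants:
        if t not in qualifying:
            continue
        stats = v.stats_for(population)
        if stats is None:
            n_absent += 1
            continue
        q += stats.af
        if stats.allele_count > 0:
            n_with_alleles += 1
    if n_absent:
        logger.warning(
            "%d qualifying variant(s) lack allele statistics for %s; counted as 0",
            n_absent,
            population,
        )
    return CumulativePathogenicFrequency(population, tier, q, n_with_alleles)


def hwe_estimates(
    q: float,
    sig_figs: int = 3,
    population: str | None = None,
    tier: str | None = None,
) -> PrevalenceEstimate:
    """Carrier frequency and disease prevalence from q, with "1/N" strings."""
    if not 0.0 <= q <= 0.5:
        raise ValueError(f"q={q} outside [0, 0.5]")
    carrier = 2.0 * q * (1.0 - q)
    prevalence = q * q
    if q == 0.0:
        carrier_str = prevalence_str = NOT_ESTIMABLE
    else:
        carrier_str = format_one_in_n(carrier, sig_figs)
        prevalence_str = format_one_in_n(prevalence, sig_figs)
    return PrevalenceEstimate(
        q=q,
        carrier_frequency=carrier,
        disease_prevalence=prevalence,
        carrier_one_in=carrier_str,
        prevalence_one_in=prevalence_str,
        population=population,
        tier=tier,
    )


def q_from_carrier(carrier: float) -> float:
    """Invert carrier = 2q(1-q): the smaller root q = (1 - sqrt(1 - 2c)) / 2.

    Lets published carrier frequencies be turned back into allele frequencies
    (and hence prevalences) without the 2q approximation.
    """
    if not 0.0 < carrier <= 0.5:
        raise ValueError(f"carrier frequency {carrier} outside (0, 0.5]")
    return (1.0 - math.sqrt(1.0 - 2.0 * carrier)) / 2.0


def one_in_n_denominator(freq: float, sig_figs: int = 3) -> int:
    """The N of the "1 in N" rendering of a frequency.

    N = 1/freq rounded to ``sig_figs`` significant figures, except that an
    exactly integral 1/freq is kept as that integer (a cohort of 22,000 with
    16 cases reads "1 in 1,375", not "1 in 1,380").
    """
    if freq <= 0 or freq > 1:
        raise ValueError(f"frequency {freq} outside (0, 1]")
    if sig_figs not in (1, 2, 3):
        raise ValueError("sig_figs must be 1, 2 or 3")
    n = 1.0 / freq
    nearest = round(n)
    if nearest > 0 and math.isclose(n, nearest, rel_tol=0.0, abs_tol=1e-6):
        return int(nearest)
    ndigits = sig_figs - 1 - math.floor(math.log10(n))
    return int(round(n, ndigits))


def format_one_in_n(freq: float, sig_figs: int = 3) -> str:
    """Render a frequency as "1/N" with thousands separators."""
    return f"1/{one_in_n_denominator(freq, sig_figs):,}"


def _displayed_denominator(est: PrevalenceEstimate) -> int:
    if est.prevalence_one_in == NOT_ESTIMABLE:
        raise ValueError("prevalence not estimable (q = 0)")
    return int(est.prevalence_one_in.split("/", 1)[1].replace(",", ""))


def fold_from_denominators(n_base: int, n_extended: int) -> float:
    """Fold-increase as the ratio of two "1 in N" denominators, one decimal."""
    if n_base <= 0 or n_extended <= 0:
        raise ValueError("denominators must be positive")
    return round(n_base / n_extended, 1)


def fold_increase(
    base: PrevalenceEstimate, extended: PrevalenceEstimate
) -> TierComparison:
    """Fold-increase in prevalence between inclusion tiers.

    Expressed as the ratio of each estimate's displayed "1 in N" denominator
    (N_base / N_extended), reported to one decimal.
    """
    if base.population != extended.population:
        raise ValueError("tier comparison requires the same population")
    if base.disease_prevalence <= 0 or extended.disease_prevalence <= 0:
        raise ValueError("both prevalences must be positive")
    return TierComparison(
        population=base.population,
        prevalence_base=base.disease_prevalence,
        prevalence_extended=extended.disease_prevalence,
        fold_increase=fold_from_denominators(
            _displayed_denominator(base), _displayed_denominator(extended)
        ),
    )


def estimates_from_carrier(
    carrier: float,
    sig_figs: int = 3,
    population: str | None = None,
    tier: str | None = None,
) -> PrevalenceEstimate:
    """Prevalence estimate reconstructed from a reported carrier frequency."""
    return hwe_estimates(q_from_carrier(carrier), sig_figs, population, tier)


def clinically_referred_frequency(n_cases: int, n_samples: int) -> str:
    """Observed disease frequency in a referred cohort as "1 in N".

    N is exact when n_samples divides evenly by n_cases, else 3 significant
    figures.
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    if n_samples < n_cases:
        raise ValueError("n_samples must be at least n_cases")
    n = one_in_n_denominator(n_cases / n_samples, sig_figs=3)
    return f"1 in {n:,}"


def prevalence_table(
    classified: Sequence[tuple[VariantRecord, InclusionTier]],
    populations: Sequence[str] = POPULATIONS,
    sig_figs: int = 3,
) -> list[dict]:
    """Per-population carrier/prevalence rows for both tiers plus fold-increase.

    Populations whose base tier has q = 0 report "not estimable" cells and no
    fold-increase, mirroring how databases with too few alleles are handled.
    """
    rows = []
    for pop in populations:
        row: dict = {"population": pop}
        ests = {}
        for tier in TIERS:
            cum = cumulative_frequency(classified, pop, tier)
            est = hwe_estimates(cum.q, sig_figs, population=pop, tier=tier)
            ests[tier] = est
            key = "" if tier == "base" else "_extended"
            row[f"q{key}"] = est.q
            row[f"carrier{key}"] = est.carrier_one_in
            row[f"prevalence{key}"] = est.prevalence_one_in
            row[f"n_variants{key}"] = cum.n_variants
        if ests["base"].disease_prevalence > 0 and ests["base_plus_extended"].disease_prevalence > 0:
            row["fold_increase"] = fold_increase(
                ests["base"], ests["base_plus_extended"]
            ).fold_increase
        else:
            row["fold_increase"] = None
        rows.append(row)
    return rows
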