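"""Variant classification rules, inclusion tiers, and table I/O."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssadhdx.variants import (
    Classification,
    Consequence,
    InclusionTier,
    PopulationAlleleStats,
    VariantRecord,
    assign_inclusion_tier,
    classify_table,
    classify_variant,
    novel_fraction,
    read_variant_table,
    truncate_percent,
    unique_variant_count,
)


def make_variant(**kw):
    defaults = dict(variant_id="v1", hgvs_c="c.1A>G", consequence=Consequence.MISSENSE)
    defaults.update(kw)
    return VariantRecord(**defaults)


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            # reported stop-gain in a confirmed affected individual
            (
                dict(hgvs_c="c.612G>A", hgvs_p="p.Trp204Ter",
                     consequence=Consequence.STOP_GAIN, reported_in_affected=True),
                Classification.PATHOGENIC,
            ),
            # unreported frameshift: premature-termination prediction alone
            (
                dict(hgvs_c="c.111_122delinsG", hgvs_p="p.Ala38GlyfsTer94",
                     consequence=Consequence.FRAMESHIFT),
                Classification.LIKELY_PATHOGENIC,
            ),
            (dict(consequence=Consequence.STOP_LOSS), Classification.VUS),
            (dict(consequence=Consequence.STOP_GAIN), Classification.LIKELY_PATHOGENIC),
            (dict(consequence=Consequence.START_LOSS), Classification.LIKELY_PATHOGENIC),
            (dict(consequence=Consequence.CANONICAL_SPLICE, splice_offset=2),
             Classification.LIKELY_PATHOGENIC),
            (dict(consequence=Consequence.CANONICAL_SPLICE, splice_offset=-1),
             Classification.LIKELY_PATHOGENIC),
            (dict(consequence=Consequence.CANONICAL_SPLICE, splice_offset=5),
             Classification.VUS),
            (dict(consequence=Consequence.MISSENSE), Classification.VUS),
            (dict(consequence=Consequence.SYNONYMOUS), Classification.VUS),
            # reported stop-loss stays VUS: never P/LP
            (dict(consequence=Consequence.STOP_LOSS, reported_in_affected=True),
             Classification.VUS),
        ],
    )
    def test_rule_table(self, kw, expected):
        assert classify_variant(make_variant(**kw)) is expected

    def test_frequency_exclusion(self):
        v = make_variant(
            consequence=Consequence.SYNONYMOUS,
            population_stats=(PopulationAlleleStats("pan_ethnic", 300_000, 1_000_000),),
        )
        assert classify_variant(v, max_credible_af=0.01) is Classification.EXCLUDED_FREQUENCY

    def test_benign_assertion_beats_frequency_and_truncation(self):
        v = make_variant(
            consequence=Consequence.FRAMESHIFT,
            asserted_benign=True,
            population_stats=(PopulationAlleleStats("pan_ethnic", 300_000, 1_000_000),),
        )
        assert classify_variant(v) is Classification.EXCLUDED_BENIGN

    def test_exclusion_beats_reported_pathogenicity(self):
        v = make_variant(
            consequence=Consequence.STOP_GAIN,
            reported_in_affected=True,
            population_stats=(PopulationAlleleStats("pan_ethnic", 50_000, 1_000_000),),
        )
        assert classify_variant(v) is Classification.EXCLUDED_FREQUENCY

    def test_splice_without_offset_is_an_error(self):
        v = make_variant(consequence=Consequence.CANONICAL_SPLICE, splice_offset=None)
        with pytest.raises(ValueError, match="splice_offset"):
            classify_variant(v)


class TestInclusionTier:
    @pytest.mark.parametrize(
        "kw, classification, expected",
        [
            # CADD boundary is inclusive at 28.0
            (dict(consequence=Consequence.MISSENSE, cadd_phred=28.0),
             Classification.VUS, InclusionTier.EXTENDED_ONLY),
            (dict(consequence=Consequence.MISSENSE, cadd_phred=25.7),
             Classification.VUS, InclusionTier.EXCLUDED),
            # SpliceAI boundary is inclusive at 0.2, any consequence class
            (dict(consequence=Consequence.OTHER, spliceai_max=0.2),
             Classification.VUS, InclusionTier.EXTENDED_ONLY),
            (dict(consequence=Consequence.OTHER, spliceai_max=0.19),
             Classification.VUS, InclusionTier.EXCLUDED),
            # P/LP always base, even with no scores
            (dict(consequence=Consequence.STOP_GAIN),
             Classification.LIKELY_PATHOGENIC, InclusionTier.BASE),
            (dict(consequence=Consequence.MISSENSE, reported_in_affected=True),
             Classification.PATHOGENIC, InclusionTier.BASE),
            # high CADD on a non-missense VUS does not qualify
            (dict(consequence=Consequence.INFRAME_INDEL, cadd_phred=35.0),
             Classification.VUS, InclusionTier.EXCLUDED),
            # excluded classifications never contribute
            (dict(consequence=Consequence.MISSENSE, cadd_phred=35.0),
             Classification.EXCLUDED_FREQUENCY, InclusionTier.EXCLUDED),
        ],
    )
    def test_tier_table(self, kw, classification, expected):
        assert assign_inclusion_tier(make_variant(**kw), classification) is expected


# Independent brute-force restatement of the rules, structured as a flat
# case-by-case walk so the main implementation can be checked against it.
def oracle_classify(v, max_af=0.01):
    if v.asserted_benign:
        return Classification.EXCLUDED_BENIGN
    for s in v.population_stats:
        if s.allele_count / s.allele_number > max_af:
            return Classification.EXCLUDED_FREQUENCY
    if v.consequence is Consequence.STOP_LOSS:
        return Classification.VUS
    if v.reported_in_affected:
        return Classification.PATHOGENIC
    truncating = False
    if v.consequence in (Consequence.STOP_GAIN, Consequence.FRAMESHIFT, Consequence.START_LOSS):
        truncating = True
    if v.consequence is Consequence.CANONICAL_SPLICE:
        if v.splice_offset is None:
            raise ValueError("splice offset required")
        truncating = v.splice_offset in (-2, -1, 1, 2)
    return Classification.LIKELY_PATHOGENIC if truncating else Classification.VUS


def oracle_tier(v, c):
    if c in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC):
        return InclusionTier.BASE
    if c is not Classification.VUS:
        return InclusionTier.EXCLUDED
    if v.consequence is Consequence.MISSENSE and v.cadd_phred is not None and v.cadd_phred >= 28.0:
        return InclusionTier.EXTENDED_ONLY
    if v.spliceai_max is not None and v.spliceai_max >= 0.2:
        return InclusionTier.EXTENDED_ONLY
    return InclusionTier.EXCLUDED


@st.composite
def variant_records(draw):
    cons = draw(st.sampled_from(list(Consequence)))
    offset = None
    if cons is Consequence.CANONICAL_SPLICE:
        offset = draw(st.integers(min_value=-8, max_value=8))
    ac = draw(st.integers(min_value=0, max_value=60_000))
    return make_variant(
        variant_id=draw(st.uuids()).hex,
        consequence=cons,
        splice_offset=offset,
        cadd_phred=draw(st.one_of(st.none(), st.floats(0, 50))),
        spliceai_max=draw(st.one_of(st.none(), st.floats(0, 1))),
        reported_in_affected=draw(st.booleans()),
        asserted_benign=draw(st.booleans()),
        population_stats=(PopulationAlleleStats("pan_ethnic", ac, 1_000_000),),
    )


@settings(derandomize=True, max_examples=300)
@given(variant_records())
def test_classification_matches_bruteforce_oracle(v):
    c = classify_variant(v)
    assert c is oracle_classify(v)
    assert assign_inclusion_tier(v, c) is oracle_tier(v, c)


def test_classification_is_order_independent():
    rng = random.Random(7)
    records = []
    for i in range(20):
        cons = rng.choice([c for c in Consequence if c is not Consequence.CANONICAL_SPLICE])
        records.append(
            make_variant(
                variant_id=f"v{i}",
                consequence=cons,
                cadd_phred=rng.choice([None, rng.uniform(0, 40)]),
                spliceai_max=rng.choice([None, rng.uniform(0, 1)]),
                reported_in_affected=rng.random() < 0.3,
                population_stats=(
                    PopulationAlleleStats("pan_ethnic", rng.randrange(0, 100), 1_000_000),
                ),
            )
        )
    baseline = {v.variant_id: (c, t) for v, c, t in classify_table(records)}
    shuffled = records[:]
    rng.shuffle(shuffled)
    assert {v.variant_id: (c, t) for v, c, t in classify_table(shuffled)} == baseline


def test_extended_set_is_superset_of_base():
    rng = random.Random(3)
    records = [
        make_variant(
            variant_id=f"v{i}",
            consequence=rng.choice([Consequence.STOP_GAIN, Consequence.MISSENSE]),
            cadd_phred=rng.uniform(20, 40),
        )
        for i in range(30)
    ]
    tiers = {v.variant_id: t for v, _, t in classify_table(records)}
    base = {k for k, t in tiers.items() if t is InclusionTier.BASE}
    extended = base | {k for k, t in tiers.items() if t is InclusionTier.EXTENDED_ONLY}
    assert base <= extended


class TestVariantTable:
    HEADER = (
        "variant_id\ttranscript\thgvs_c\thgvs_p\tconsequence\tsplice_offset"
        "\tcadd_phred\tspliceai_max\treported_in_affected\tasserted_benign"
        "\tAC_pan_ethnic\tAN_pan_ethnic\n"
    )

    def write(self, tmp_path, body):
        p = tmp_path / "variants.tsv"
        p.write_text(self.HEADER + body)
        return p

    def test_well_formed_rows_roundtrip(self, tmp_path):
        body = (
            "v1\tNM_001080\tc.612G>A\tp.Trp204Ter\tstop_gain\t\t\t\ttrue\tfalse\t3\t1000000\n"
            "v2\tNM_001080\tc.100A>G\t\tmissense\t\t28.0\t\tfalse\tfalse\t1\t1000000\n"
            "v3\tNM_017040\tc.5G>T\t\tsynonymous\t\t\t0.05\tfalse\tfalse\t0\t1000000\n"
        )
        records = read_variant_table(self.write(tmp_path, body))
        assert len(records) == 3
        assert records[0].reported_in_affected
        assert records[1].cadd_phred == 28.0
        assert records[2].spliceai_max == 0.05

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_variant_table(self.write(tmp_path, "")) == []

    def test_ac_exceeding_an_names_the_row(self, tmp_path):
        body = (
            "v1\tNM_001080\tc.1A>G\t\tmissense\t\t\t\tfalse\tfalse\t1\t1000\n"
            "v2\tNM_001080\tc.2A>G\t\tmissense\t\t\t\tfalse\tfalse\t2000\t1000\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_variant_table(self.write(tmp_path, body))

    def test_duplicate_variant_id_rejected(self, tmp_path):
        body = (
            "v1\tNM_001080\tc.1A>G\t\tmissense\t\t\t\tfalse\tfalse\t1\t1000\n"
            "v1\tNM_001080\tc.2A>G\t\tmissense\t\t\t\tfalse\tfalse\t1\t1000\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_variant_table(self.write(tmp_path, body))

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("variant_id\thgvs_c\nv1\tc.1A>G\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_variant_table(p)

    def test_malformed_number_names_the_row(self, tmp_path):
        body = "v1\tNM_001080\tc.1A>G\t\tmissense\t\tnot-a-number\t\tfalse\tfalse\t1\t1000\n"
        with pytest.raises(ValueError, match="row 1"):
            read_variant_table(self.write(tmp_path, body))


class TestAlleleCounting:
    def test_repeated_allele_counts_once(self):
        assert unique_variant_count(["c.612G>A"] * 4) == 1

    def test_dash_normalization_merges_identical_alleles(self):
        assert unique_variant_count(["c.1015–2A>C", "c.1015-2A>C"]) == 1

    def test_truncation_not_rounding(self):
        assert truncate_percent(3, 19) == 15.7   # 15.789...
        assert truncate_percent(10, 24) == 41.6  # 41.666...

    def test_novel_fraction(self):
        alleles = ["c.1A>G", "c.2A>G", "c.3A>G", "c.1A>G"]
        assert novel_fraction(alleles, {"c.2A>G", "c.3A>G"}) == pytest.approx(33.3)

    def test_case_series_unique_and_novel(self, case_series_subjects, novel_alleles):
        alleles = [a for s in case_series_subjects[:16] for a in s.alleles]
        assert unique_variant_count(alleles) == 19
        known = set(alleles) - novel_alleles
        assert novel_fraction(alleles, known) == 15.7
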