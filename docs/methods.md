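# Methods

## Variant classification rules

A variant qualifies as pathogenic/likely pathogenic for prevalence purposes
when it truncates the SSADH protein or has prior evidence in an affected
individual. The rule order is fixed and total:

1. benign/likely-benign assertion → excluded (takes precedence over
   everything, including frequency);
2. allele frequency above `max_credible_af` in **any** population →
   excluded. The threshold defaults to 0.01 — far above any plausible
   allele frequency for an ultra-rare recessive disorder, so it acts as a
   permissive guard rather than a calibrated filter; it is configurable.
3. previously reported in a confirmed affected individual → pathogenic
   (except stop-loss, below);
4. stop-gain, frameshift, start-loss, or canonical splice-site change at
   ±1/±2 bp → likely pathogenic (a canonical-splice record without a
   splice offset is a validation error, since the window cannot be applied);
5. everything else → VUS. Stop-loss variants are always VUS — the C-terminal
   extension mechanism is not predictably loss-of-function — even when
   reported, so they never enter the prevalence sums.

The *extended* inclusion tier adds VUS that stringent in-silico predictions
flag: missense with CADD PHRED ≥ 28.0, or SpliceAI max delta ≥ 0.2, both
boundaries inclusive. "Nonsynonymous" is read as missense only — in-frame
indels need explicit evidence, as the PHRED calibration underlying the 28.0
cutoff concerns missense substitutions — while the SpliceAI branch applies
to any class not already base-tier (spliceogenicity is not confined to
annotated splice variants). P/LP variants are base-tier by construction, so
the extended variant set is always a superset of the base set, and a variant
never appears in both (`extended_only` excludes base by construction).

Variant identity is cDNA HGVS string equality on a single transcript
(NM_001080); records on the minor transcript are expected to be lifted by
the caller before deduplication. Protein-level annotation discrepancies
(e.g. two frameshift names for the same duplication) therefore do not split
a variant. Cohort percentages are **truncated**, not rounded, to one decimal
(3/19 → 15.7%), matching how such fractions are conventionally reported in
the source clinical summaries this package reproduces.

## Hardy-Weinberg estimation

The cumulative pathogenic allele frequency q for a population sums AC/AN
over qualifying variants, assuming no linkage between the rare pathogenic
alleles and ignoring phase; homozygote counts receive no special treatment.
Carrier frequency is the exact 2q(1−q) and prevalence q². The exact form
matters: inverting a printed carrier frequency of 1/376 gives 1 in 564,000,
which the 2q approximation misses at the printed precision. The inversion
uses the smaller root q = (1 − √(1 − 2c))/2, which round-trips with
2q(1−q) to < 1e-12 over q ∈ (0, 0.25].

"1 in N" rendering rounds N = 1/freq to 1–3 significant figures
(default 3), except that an exactly integral 1/freq is displayed exactly
(22,000 samples / 16 cases → "1 in 1,375"). Integrality is detected with an
absolute tolerance of 1e-6 on N, so float division noise does not break the
exact display and near-integral large N (10⁷-scale) are still rounded.
Fold-increase between tiers is the ratio of the two *displayed* denominators
N_base/N_extended to one decimal, because the published tables it mirrors
print denominators at heterogeneous precision and compute the fold from
them. Populations with q = 0 report "not estimable" and no fold-increase.

## Metabolomics pipeline

Semiquantitative LC-MS intensities are comparable only within a batch, so
each value is divided by the per-batch **median** across anchor specimens
for that metabolite (median for robustness to a single bad anchor
injection). This makes every per-batch multiplicative factor cancel
exactly: scaling a whole batch, anchors included, leaves every downstream
z-score unchanged (a tested invariant). Urine intensities are first divided
by the sample's creatinine; a shared creatinine factor likewise cancels in
the z-scores when the reference is built from the same normalized data.

Values are natural-log transformed (the base is internal: z-scores are
invariant to it when reference statistics use the same base) and scored
against a reference cohort of normal samples (default n = 395):
z = (log x − μ_log)/σ_log with the sample SD (ddof = 1). Non-positive
values cannot be logged and are treated as not reported; constant
metabolites are excluded from the reference. |z| ≥ 2 (inclusive) is
abnormal, two-sided; the signature logic uses only the high side.

**SSADHD plasma signature**: positive requires both 2-pyrrolidinone and
4-guanidinobutanoate high; a missing core marker makes the call
indeterminate. The supportive band — exactly one core marker high, or
4-guanidinobutanoate z ≥ 1.7 — encodes the attenuated adult pattern, in
which 4-guanidinobutanoate sits high-normal (z ≈ 1.7–2.4) with normal
2-pyrrolidinone; elevated argininate or succinamic acid reinforces the
supportive evidence but is not required (the 1.7 threshold is
configurable). All remaining profiles are negative; sub-band elevations of
2-pyrrolidinone alone (z ∈ [1.7, 2)) deliberately fall through to negative,
as that marker alone is not discriminating at sub-threshold levels.
**Urine**: core markers are 4-guanidinobutanoate and succinimide; urinary
2-pyrrolidinone is uninformative and carries no weight. **GABA-TD plasma**:
2-pyrrolidinone plus succinamic acid, same positive/supportive/negative
ladder. CSF has no validated signature and is rejected.

Age statistics per marker: ordinary least squares of z on age with the
two-sided slope p-value, and a pooled-variance two-sample two-tailed
Student's t-test between pediatric (age ≤ 18 y) and adult (age > 18 y)
groups; a group with fewer than two members makes the t-test not estimable.
Ages are decimal years (6 months = 0.5).

## Integrated diagnosis

Molecular criterion: two P/LP alleles (homozygous or compound
heterozygous). Phase confirmation is carried when provided but not
required — biallelic listings in diagnostic reports are routinely unphased.
Biochemical criterion: urine GHB above the 0–7 mmol/mol creatinine normal
range (strictly greater than 7; a free-text "elevated GHB" report counts),
or a positive SSADHD metabolomic signature. Both → comprehensively
confirmed; one → molecularly confirmed / biochemically supported; neither
but suggestive clinical features (developmental delay, hypotonia, seizures,
ataxia, autistic features, speech delay, failure to thrive, stroke,
abnormal urine organic acids — configurable) or suggestive brain imaging →
suspected; otherwise not supported. Adding a positive evidence channel can
only move a subject up this ladder (a tested invariant).

Cohort summaries report sex counts with truncated percentages, mean age to
one decimal, exact median, sample SD to two decimals, the pediatric/adult
split at 18/19 years, per-subject homozygote counts (siblings sharing a
genotype count separately), and unique/novel allele counts via the
cDNA-identity rules above.

## Synthetic-data generators

The generators define the conditions under which the pipeline is tested;
all draw from `numpy.random.default_rng(seed)` and emit a truth object next
to every dataset.

**Variant tables.** Base-tier variants (stop-gain, frameshift, canonical
splice ±1/±2, start-loss; half marked as previously reported), extended-tier
variants (missense with CADD ≥ 28 or spliceogenic with SpliceAI ≥ 0.2), and
decoys (synonymous, sub-threshold missense at the reported median PHRED of
25.7, stop-loss, benign-asserted, an implausibly common allele, sub-threshold
spliceogenic) are planted with per-variant allele frequencies that sum to
the target cumulative q per tier. Defaults plant the pan-ethnic conditions
of the population analysis this package emulates: q matching carrier
frequencies of 1/376 (base) and 1/236 (base + extended) at AN = 1,000,000.
In *exact* mode AC = round-half-even(AF·AN) and the truth records the
realized Σ AC/AN (the planted frequencies are the post-rounding ones; the
requested target differs by at most 0.5·n/AN). In *binomial* mode
AC ~ Binomial(AN, AF) and the truth records the requested q; the estimator
is then checked to 3 binomial standard errors over 500 replicates.

**Intensity matrices.** Reference samples are log-normal per metabolite
(location U(2, 8), scale U(0.2, 0.6) in log space — typical spreads for
semiquantitative LC-MS features); anchors are near-invariant pooled
aliquots (technical log-noise SD 0.02); every batch gets a multiplicative
gain factor (log-SD 0.5) applied to all its samples including anchors, so
anchor normalization is genuinely exercised. Case samples receive a
deterministic per-marker log shift of z_target·σ_log with z_target drawn
uniformly from the group's target range — the observed z then differs from
the target only through finite-reference estimation error (empirically
within ±0.35 at n = 395), which is what makes a 100% pediatric sensitivity
test meaningful. Default case groups plant the observed disease ranges:
pediatric plasma 2-pyrrolidinone z ∈ [+3.12, +6.50] and
4-guanidinobutanoate ∈ [+2.61, +4.03]; adult plasma [+0.02, +1.24] and
[+1.70, +2.38]; pediatric urine succinimide [+2.09, +3.16] and
4-guanidinobutanoate [+1.91, +2.78]; adult urine succinimide
[+1.02, +1.72]. For GABA-TD plasma no ranges are published beyond "clearly
elevated", so both markers are planted at z ∈ [2.5, 5.0].

What the generator does **not** emulate: within-disease correlation between
markers (no published covariance — markers are shifted independently),
heteroscedastic or missing-not-at-random intensity noise (missingness is
injected uniformly at a configurable rate, default 0), retention-time drift
or any other raw-spectral artifact, and individual biological variability
*on the shifted markers* of case samples. Passing tests therefore
demonstrate the pipeline's arithmetic and invariances, not its behaviour on
real instrument output.

**Cohorts.** Subject tables mirror the bundled case series: by default an
exact 18:6 pediatric:adult and 10:14 male:female quota at n = 24 (Bernoulli
sampling optional), genotypes drawn from the case-series allele pool, and
urine GHB above/below the 0–7 normal range for cases/controls.

## Problem sizes and numerical choices

The test suite and analysis scripts use the study-scale designs throughout:
reference n = 395 with 8 batches of 3 anchors, case groups of 5–8, variant
tables of ~18 rows at AN = 10⁶, 500 replicates for the binomial-recovery
check and 1,000 for the Monte-Carlo age-separation property. The whole
suite runs in well under a minute. Ties and boundaries: CADD 28.0,
SpliceAI 0.2 and z = ±2 are all inclusive; GHB 7.0 is the top of the normal
range (flagged normal); allele-count rounding is half-even and documented
because the exact-mode recovery tolerance depends on it.

## Known limitations

- The frequency guard behind "more common than expected for disease"
  (0.01) is this package's choice; no calibrated threshold is published.
- Adult case profiles are scored against a pediatric reference population,
  mirroring clinical practice for this assay; a dedicated adult reference
  would shift the adult bands.
- The printed group-contrast p-values of the source cohort cannot be
  recomputed without per-sample data; the suite substitutes a seeded
  Monte-Carlo separation property over the published ranges.
- The five-rule classifier is deliberately narrower than a full ACMG/AMP
  engine; it exists to make population-frequency sums reproducible, not to
  issue clinical assertions.
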