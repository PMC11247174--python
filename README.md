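# ssadhdx

Integrated molecular and metabolomic diagnostics for **succinic semialdehyde
dehydrogenase deficiency (SSADHD)**, an autosomal recessive disorder of GABA
catabolism caused by biallelic *ALDH5A1* variants. The package is aimed at
biochemical-genetics and bioinformatics analysts who need to (a) estimate how
common the disease could be from population allele-frequency databases, and
(b) call its metabolomic signature from untargeted LC-MS profiles.

## What it computes

**Variant classification and prevalence.** *ALDH5A1* variants from a
gnomAD-style export are classified by rule: protein-truncating changes
(stop-gain, frameshift, start-loss, canonical ±1/±2 splice) or variants
previously reported in confirmed affected individuals are pathogenic /
likely pathogenic; stop-loss variants stay VUS; benign-asserted or
implausibly common variants are excluded. A second, *extended* tier adds
unreported variants that stringent in-silico predictions flag as deleterious
(missense with CADD PHRED ≥ 28.0, or SpliceAI max delta ≥ 0.2). For each
population, the cumulative pathogenic allele frequency

&nbsp;&nbsp;&nbsp;&nbsp;q = Σᵢ ACᵢ / ANᵢ

over qualifying variants gives, under Hardy-Weinberg equilibrium, a carrier
frequency **2q(1−q)** and a disease prevalence **q²** (the exact form, not
the 2q approximation). Reported carrier frequencies can also be inverted via
q = (1 − √(1 − 2c))/2 to reconstruct prevalence figures.

**Metabolomics z-score pipeline.** Raw spectral intensities are divided by
the per-batch median of invariant anchor specimens, log transformed, and
scored against a normal reference population (n = 395):
z = (log x − μ_log)/σ_log per metabolite, with |z| ≥ 2 abnormal. Signature
calls encode the GABA-pathway patterns: SSADHD plasma requires joint
elevation of 2-pyrrolidinone and 4-guanidinobutanoate (with a supportive
band for the attenuated adult pattern), SSADHD urine uses
4-guanidinobutanoate plus succinimide, and GABA-transaminase deficiency
plasma uses 2-pyrrolidinone plus succinamic acid.

**Integrated diagnosis.** Genotype (biallelic P/LP variants), biochemistry
(urine GHB > 7 mmol/mol creatinine), and the metabolomic signature combine
into a diagnostic status (comprehensively confirmed / molecularly confirmed /
biochemically supported / suspected / not supported), plus cohort-level
summaries.

**Synthetic data.** Seeded generators emulate gnomAD-like variant tables
(with planted cumulative q, exact or binomially sampled allele counts) and
anchored LC-MS matrices (reference cohort, per-batch gain factors, case
groups with planted z-shifts), each emitting its ground truth for recovery
tests.

## Worked example

The numbered scripts under `analysis/` run the full study flow and write
their tables under `results/`:

```bash
python analysis/01_simulate_population_variants.py
python analysis/02_classify_and_estimate_prevalence.py
python analysis/03_metabolomics_signatures.py
python analysis/04_cohort_and_diagnosis.py
```

Step 02 prints, for the synthetic pan-ethnic table (planted to carrier
frequencies of 1/376 base and 1/236 with predictions):

```
estimated q: base 0.001332 (planted 0.001332), base+extended 0.002124 (planted 0.002124)
carrier 1/376 -> prevalence 1/564,000 (base tier); carrier 1/236 -> prevalence 1/222,000 (with predictions); fold-increase 2.5
pan-ethnic: carrier 1/376 -> prevalence 1/564,000 (base tier)
african: fold-increase 13.0 (1/1,000,000 -> 1/77,000)
clinically referred cohort (16 cases / 22,000 samples): 1 in 1,375
```

i.e. the classifier recovers the planted cumulative frequency exactly, a
carrier frequency of 1 in 376 corresponds to a recessive prevalence of about
1 in 564,000, and adding CADD/SpliceAI-predicted variants raises the
estimate ~2.5-fold pan-ethnically (13-fold in the African/African American
population, where reported variants are scarcest). Step 03 prints:

```
pediatric SSADHD plasma: 8/8 positive (both core markers z >= +2)
adult SSADHD plasma: calls ['supportive', 'supportive', 'supportive', 'supportive', 'supportive']
2-pyrrolidinone: slope -0.113/y (p=0.0011); pediatric mean z 4.52 vs adult 0.66 (t-test p=8e-05)
```

— every simulated pediatric plasma case is signature-positive, adults show
the attenuated (supportive) pattern, and both core markers decline
significantly with age. Step 04 summarizes the bundled 24-subject case
series: mean age 11.5 ± 12.67 y (median 7), 10 M / 14 F, 18 pediatric /
6 adult, and 19 unique variants among the 16 referral-cohort subjects, 3 of
them novel (15.7%).

There is also a thin CLI (`ssadhdx classify|prevalence|zscore|signature|
diagnose|cohort-summary|simulate ...`) over the same library functions.

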