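#!/usr/bin/env python
"""Generate the synthetic population variant table used by the prevalence analysis.

Emulates a gnomAD-style *ALDH5A1* export for the pan-ethnic population:
truncating (base-tier) variants and CADD/SpliceAI-qualifying variants are
planted so that the cumulative pathogenic allele frequencies match carrier
frequencies of 1/376 (base) and 1/236 (base + extended) at AN = 1,000,000,
alongside decoy variants that the classifier must reject.  Writes the table
and its planted truth under results/.
"""

from pathlib import Path

from ssadhdx import simulate as sim

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240601


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = sim.VariantSimConfig(seed=SEED, mode="exact")
    table, truth = sim.simulate_variant_table(cfg)
    table.to_csv(OUT / "synthetic_variants.tsv", sep="\t", index=False)
    truth.to_json(OUT / "synthetic_variants_truth.json")

    q = truth.q_planted["pan_ethnic"]
    print(f"wrote {len(table)} variants ({cfg.n_base} base-tier, "
          f"{cfg.n_extended} extended-tier, {cfg.n_decoy} decoys)")
    print(f"planted cumulative q (pan-ethnic): base {q['base']:.6g}, "
          f"extended-only {q['extended_only']:.6g}")


if __name__ == "__main__":
    main()
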