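"""Bundled example data.

``load_case_series`` returns the 24-subject SSADHD case series used as the
package's worked example: demographics, clinical flags, urine GHB results
(numeric where measured, a reported-elevated flag where only free text was
available), and both *ALDH5A1* alleles as cDNA HGVS strings on NM_001080.

``load_reported_carrier_frequencies`` returns previously reported
per-population carrier-frequency and prevalence estimates for *ALDH5A1*
(derived from the gnomAD v4.0.0 database), as the "1 in N" denominators for
the base inclusion tier and the CADD/SpliceAI-extended tier.  These serve as
inputs to the Hardy-Weinberg inversion analysis.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: cDNA alleles of the case series absent from variant databases at curation
#: time (all three are protein-truncating).
NOVEL_ALLELES = frozenset({"c.111_122delinsG", "c.768_784del", "c.380G>A"})


def _data_path(name: str):
    return resources.files("ssadhdx.data").joinpath(name)


def load_case_series() -> pd.DataFrame:
    """The 24-subject case series as a DataFrame (one row per subject)."""
    with resources.as_file(_data_path("case_series.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"subject_id": str}, keep_default_na=False)


def load_reported_carrier_frequencies() -> pd.DataFrame:
    """Reported per-population carrier/prevalence "1 in N" denominators."""
    with resources.as_file(_data_path("reported_carrier_frequencies.tsv")) as p:
        return pd.read_csv(p, sep="\t")
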