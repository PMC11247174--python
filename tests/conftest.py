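import pytest

from ssadhdx import diagnosis as dx
from ssadhdx import simulate as sim
from ssadhdx.datasets import NOVEL_ALLELES, load_case_series


@pytest.fixture(scope="session")
def case_series_subjects():
    return dx.subjects_from_frame(load_case_series())


@pytest.fixture(scope="session")
def novel_alleles():
    return set(NOVEL_ALLELES)


@pytest.fixture(scope="session")
def plasma_dataset():
    """One simulated plasma dataset (reference n=395 + case groups), scored."""
    cfg = sim.default_plasma_config(seed=11)
    matrix, sheet, truth = sim.simulate_metabolomics(cfg)
    ref, profiles = sim.score_simulated(matrix, sheet)
    return {
        "cfg": cfg,
        "matrix": matrix,
        "sheet": sheet,
        "truth": truth,
        "ref": ref,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def urine_dataset():
    cfg = sim.default_urine_config(seed=12)
    matrix, sheet, truth = sim.simulate_metabolomics(cfg)
    ref, profiles = sim.score_simulated(matrix, sheet)
    return {
        "cfg": cfg,
        "matrix": matrix,
        "sheet": sheet,
        "truth": truth,
        "ref": ref,
        "profiles": profiles,
    }
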