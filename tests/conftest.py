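import pandas as pd
import pytest

from cypcna import (
    CallingConfig,
    CtTable,
    SamplePair,
    SimulationConfig,
    default_panel,
    simulate_pair,
)

#: Published per-gene score sums for the OK18 patient's three tumour sites
#: (primary lung adenocarcinoma, lung metastasis, liver metastasis).
OK18_SCORE_SUMS = {
    "primary": {
        "RPPH1": 6, "ALB": -3, "B2M": -3, "BCKDHA": 3, "CD36": -2,
        "F5": 6, "MPO": -4, "TBP": -2, "CYP3A4": 3, "CYP2C8": -5,
    },
    "lung_met": {
        "RPPH1": 0, "ALB": -8, "B2M": 0, "BCKDHA": 7, "CD36": 2,
        "F5": 7, "MPO": 1, "TBP": -1, "CYP3A4": -1, "CYP2C8": -7,
    },
    "liver_met": {
        "RPPH1": 7, "ALB": -8, "B2M": -2, "BCKDHA": 3, "CD36": 3,
        "F5": 8, "MPO": -1, "TBP": 0, "CYP3A4": -1, "CYP2C8": -7,
    },
}


@pytest.fixture
def panel():
    return default_panel()


@pytest.fixture
def config():
    return CallingConfig()


@pytest.fixture
def ok18_like():
    """Noiseless pair mimicking the published primary tumour: 40% of cells
    with a one-copy CYP2C8 loss on an otherwise diploid background."""
    sim = SimulationConfig(
        true_cn={"CYP2C8": 1.0}, tumour_cell_fraction=0.4, noise_sd=0.0, seed=7
    )
    ct, truth = simulate_pair(sim, "OK18")
    pair = SamplePair("OK18", "OK18_T", "OK18_C", "normal_lung")
    return sim, ct, pair, truth


def make_ct_table(rows, panel):
    """Build a CtTable from (sample_id, gene, replicate, ct) tuples."""
    df = pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
    return CtTable(df, panel)
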