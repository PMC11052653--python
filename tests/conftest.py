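import numpy as np
import pandas as pd
import pytest

import cosmix as cx


@pytest.fixture(scope="session")
def small_panel() -> cx.ReferencePanel:
    """Two populations with distinct LD (different AR parameters), 200 SNPs."""
    cfg = cx.SyntheticConfig(
        n_pops=2, n_per_pop=150, m_variants=200, fst=[0.1, 0.2],
        rho=[0.8, 0.5], block_size=25, seed=1,
    )
    return cx.simulate_panel(cfg)


@pytest.fixture(scope="session")
def pi_60_40(small_panel) -> cx.MixingProportions:
    return cx.MixingProportions(small_panel.populations, np.array([0.6, 0.4]))


@pytest.fixture()
def toy_panel() -> cx.ReferencePanel:
    """Hand-built 2-population, 4-variant panel with exact dosage columns."""
    variants = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3", "rs4"],
            "chr": ["1", "1", "1", "1"],
            "bp": [100, 200, 300, 400],
            "a1": ["A", "C", "G", "T"],
            "a2": ["G", "T", "A", "C"],
        }
    )
    genotypes = {
        "POP1": np.array(
            [[0, 2, 1, 0],
             [1, 2, 0, 0],
             [2, 2, 1, 2],
             [1, 0, 2, 0]]
        ),
        "POP2": np.array(
            [[2, 1, 0, 1],
             [2, 0, 0, 1],
             [0, 1, 2, 1]]
        ),
    }
    return cx.ReferencePanel(variants=variants, populations=["POP1", "POP2"],
                             genotypes=genotypes)
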