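import numpy as np
import pandas as pd
import pytest

from gwasfig import GwasTable, SimConfig, simulate_pvalue_table


@pytest.fixture
def toy_table() -> GwasTable:
    """Three chromosomes, five markers, two traits; Trait1 holds the toy
    P set {1e-8, 1e-3, 0.2, 0.5} plus one missing value."""
    frame = pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "chrom": ["1", "1", "2", "2", "3"],
            "position": [100, 1100, 200, 700, 500],
            "Trait1": [1e-8, 1e-3, 0.2, 0.5, np.nan],
            "Trait2": [0.9, 0.8, 0.7, 0.6, 0.5],
        }
    )
    return GwasTable(frame=frame, trait_names=("Trait1", "Trait2"))


@pytest.fixture
def small_sim_table() -> GwasTable:
    """Seeded 3-chromosome, 2-trait simulated table with an unknown block."""
    return simulate_pvalue_table(
        SimConfig(n_chrom=3, markers_per_chrom=40, n_traits=2,
                  include_unknown_chrom=True, unknown_markers=10, seed=11)
    )
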