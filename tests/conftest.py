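import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scbn import OrthologTable, SimConfig, simulate_dataset

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


def make_table(x1, x2, L1=None, L2=None, ids=None) -> OrthologTable:
    n = len(x1)
    return OrthologTable(
        pd.DataFrame(
            {
                "gene_id": ids if ids is not None else [f"g{i}" for i in range(n)],
                "x1": np.asarray(x1, dtype=np.int64),
                "L1": np.asarray(L1 if L1 is not None else [100] * n, dtype=np.int64),
                "x2": np.asarray(x2, dtype=np.int64),
                "L2": np.asarray(L2 if L2 is not None else [100] * n, dtype=np.int64),
            }
        )
    )


@pytest.fixture
def toy_table() -> OrthologTable:
    return make_table([5, 2, 0], [0, 2, 7])


@pytest.fixture(scope="session")
def null_sim():
    """A fully null dataset (no DE, no unique genes): every gene satisfies
    the equal-expression hypothesis and the true scaling factor is known."""
    cfg = SimConfig(
        n_orth=4000,
        prop_de=0.0,
        n_unique=(0, 0),
        n_unmapped=(0, 0),
        m_conserved=500,
        depth=(4e6, 8e6),
        seed=20240901,
    )
    return simulate_dataset(cfg)
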