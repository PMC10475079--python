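import numpy as np
import pandas as pd
import pytest

from lrcausal.datatypes import CellMetadata, ExpressionMatrix
from lrcausal.synthetic import SimulationConfig, simulate_embryo


@pytest.fixture(scope="session")
def embryo():
    """Default planted embryo simulation, shared across read-only tests."""
    cfg = SimulationConfig(seed=1)
    mat, meta, lr, tfs, truth = simulate_embryo(cfg)
    return {"config": cfg, "mat": mat, "meta": meta, "lr": lr, "tfs": tfs, "truth": truth}


@pytest.fixture
def toy_matrix():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [0.0, 0.0, 5.0, 5.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


@pytest.fixture
def toy_meta():
    table = pd.DataFrame(
        {
            "stage": ["early", "early", "late", "late"],
            "pseudotime": [0.1, 0.5, 0.2, 0.9],
        },
        index=["c1", "c2", "c3", "c4"],
    )
    return CellMetadata(table, ["early", "late"])
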