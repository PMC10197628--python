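import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pantissue import ExpressionTensor, SimulationConfig, PlantedSignal, TissueSpec


def make_tensor(matrices: dict[str, np.ndarray], individuals=None,
                genes=None) -> ExpressionTensor:
    """Small-tensor builder: arrays become gene x individual DataFrames."""
    n = next(iter(matrices.values())).shape[1]
    individuals = individuals or [f"I{i}" for i in range(n)]
    frames = {}
    for tissue, arr in matrices.items():
        g = genes[tissue] if genes else [f"g{i}" for i in range(arr.shape[0])]
        frames[tissue] = pd.DataFrame(np.asarray(arr, float), index=g,
                                      columns=individuals)
    return ExpressionTensor(individuals=list(individuals), matrices=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_archive():
    """Small archive with one planted cross-tissue module (rho=0.8, m=20)."""
    from pantissue import simulate_archive

    cfg = SimulationConfig(
        n_individuals=150,
        tissues=(TissueSpec("liver", 120), TissueSpec("adipose", 120),
                 TissueSpec("muscle", 120)),
        signals=(PlantedSignal("liver", "SEED", "adipose", 20, 0.8),),
        seed=7,
    )
    return simulate_archive(cfg)
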