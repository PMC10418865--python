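import numpy as np
import pandas as pd
import pytest

from metabosig import QuantMatrix, generate_matrix
from metabosig.simulate import SimulationConfig, BlockSpec


def small_quant_matrix(values: np.ndarray, groups, lloq=None, uloq=None,
                       tissue="plasma", weights=None) -> QuantMatrix:
    """Hand-built QuantMatrix from a raw array, for unit fixtures."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    mets = [f"m{j + 1}" for j in range(m)]
    sids = [f"S{i + 1}" for i in range(n)]
    loq = pd.DataFrame(
        {
            "lloq": np.zeros(m) if lloq is None else np.asarray(lloq, dtype=float),
            "uloq": np.full(m, np.inf) if uloq is None else np.asarray(uloq, dtype=float),
        },
        index=pd.Index(mets, name="metabolite_id"),
    )
    samples = pd.DataFrame(
        {
            "group": list(groups),
            "tissue": tissue,
            "weight_mg": np.nan if weights is None else list(weights),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    return QuantMatrix(
        values=pd.DataFrame(values, index=samples.index, columns=mets),
        loq=loq,
        samples=samples,
    )


@pytest.fixture
def tiny_config():
    """A small, fast simulation design used across tests."""
    return SimulationConfig(
        n_group_a=28,
        n_group_b=12,
        n_metabolites=60,
        n_informative=5,
        effect_sizes=(1.5,) * 5,
        blocks=[BlockSpec("AA", 26, 0.3), BlockSpec("PC", 20, 0.5), BlockSpec("other", 14, 0.0)],
        censor_rules=(),
        base_censor_fraction=0.05,
        seed=42,
    )


@pytest.fixture
def tiny_matrix(tiny_config):
    matrix, truth = generate_matrix(tiny_config)
    return matrix, truth
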