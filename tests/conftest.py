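import numpy as np
import pandas as pd
import pytest

from circanet.io import TimeSeriesMatrix
from circanet.simulate import SimulationConfig, simulate_expression

CT12 = np.arange(0, 48, 4.0)


def make_matrix(values: np.ndarray, condition: str = "LD", gene_ids=None) -> TimeSeriesMatrix:
    """Wrap a genes x 12 array into a TimeSeriesMatrix for one condition."""
    values = np.atleast_2d(values)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{condition}_{int(t):02d}" for t in CT12]
    sheet = pd.DataFrame(
        {"condition": condition, "ct": CT12}, index=pd.Index(samples, name="sample_id")
    )
    return TimeSeriesMatrix(pd.DataFrame(values, index=genes, columns=samples), sheet)


@pytest.fixture(scope="session")
def sim_study():
    """Default synthetic study: 1000 genes, all five classes, A/sigma in [2,4]."""
    config = SimulationConfig(n_genes=1000, seed=11)
    ld, dd, truth = simulate_expression(config)
    return config, ld, dd, truth
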