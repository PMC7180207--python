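import numpy as np
import pytest

from scdmfk.data_io import CountMatrix
from scdmfk.model import ModelConfig, build_model
from scdmfk.preprocess import prepare
from scdmfk.simulator import SimParams, simulate


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Hand-written 4 cells x 5 genes matrix with no zero rows/columns."""
    counts = np.array(
        [
            [3, 0, 1, 2, 0],
            [0, 2, 0, 1, 1],
            [5, 1, 2, 0, 0],
            [1, 0, 0, 3, 2],
        ]
    )
    return CountMatrix(counts, [f"c{i}" for i in range(4)], [f"g{j}" for j in range(5)])


def small_sim(seed: int = 0, strong_de: bool = False):
    """A quick 3-group synthetic dataset for training-level tests."""
    params = SimParams(
        n_groups=3,
        cells_per_group=[200, 200, 200],
        n_genes=400,
        de_fac_scale=0.5 if strong_de else 0.2,
        de_fac_loc=0.3 if strong_de else 0.1,
        dropout=False,
        seed=seed,
    )
    return simulate(params)


@pytest.fixture(scope="session")
def separable_data():
    """Prepared 3-group data with strong DE, recoverable from the latent space."""
    sim = small_sim(seed=7, strong_de=True)
    data = prepare(sim.counts, n_top_genes=200)
    return sim, data


@pytest.fixture(scope="session")
def pretrained_small(separable_data):
    """A model pretrained briefly on the separable dataset."""
    from scdmfk.training import pretrain

    sim, data = separable_data
    model = build_model(ModelConfig(seed=7, batch_size=256), data.n_genes)
    pretrain(model, data, epochs=150)
    return sim, data, model
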