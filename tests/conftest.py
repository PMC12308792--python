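import numpy as np
import pytest

import molorb as mo
from molorb.regressor import Hyperparameters


@pytest.fixture(scope="session")
def small_params():
    cfg = mo.FingerprintConfig(n_layers=3, fp_length=32, hidden_width=16)
    return mo.init_fingerprint_params(cfg, seed=7)


@pytest.fixture(scope="session")
def random_graphs():
    """20 generated molecules (graphs) shared across structural tests."""
    ds = mo.generate_synthetic_dataset(20, seed=42)
    return [mo.parse_smiles(s, id=i) for i, s in
            zip(ds.df["id"], ds.df["smiles"])]


@pytest.fixture(scope="session")
def tiny_hyper():
    return Hyperparameters(
        gcn_layers=3, ann_layers=2, batch_size=32, learning_rate=0.003,
        l2=0.0, fp_length=32, hidden_width=16, ann_width=32, max_epochs=15,
    )


@pytest.fixture(scope="session")
def tiny_surrogate_split():
    ds = mo.generate_synthetic_dataset(240, seed=5)
    return mo.split_dataset(ds, mo.SplitSpec(seed=5))


@pytest.fixture(scope="session")
def tiny_members(tiny_surrogate_split, tiny_hyper):
    """Three small trained models sharing the surrogate target."""
    train, _, val = tiny_surrogate_split
    members = []
    for i in range(3):
        hyper = Hyperparameters(**{**tiny_hyper.__dict__, "seed": 100 + i})
        spec = mo.NeuralFingerprintRegression(train, val, "surrogate", hyper)
        members.append(spec.fit(seed=100 + i).model)
    return members
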