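import warnings

import numpy as np
import pytest

from fluidsim.chem_features import FeatureMatrix
from fluidsim.synthetic_data import WorldConfig, generate_world

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture(scope="session")
def tiny_world():
    """Small abstract-mode world shared by integration-style unit tests."""
    cfg = WorldConfig(
        n_partners=3, n_train_per_partner=300, n_test_per_partner=120,
        n_public=300, n_pool=1500, n_pool_eval=300, seed=42,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def tiny_smiles_world():
    """Small grammar-SMILES world for end-to-end chemistry runs."""
    cfg = WorldConfig(
        n_partners=2, n_train_per_partner=120, n_test_per_partner=60,
        n_public=120, n_pool=300, mode="smiles", seed=7,
    )
    return generate_world(cfg)


def make_fm(physchem, fingerprints, labels=None, config_hash="testcfg", ids=None):
    physchem = np.asarray(physchem, dtype=float)
    n = physchem.shape[0]
    if ids is None:
        ids = [f"m{i}" for i in range(n)]
    return FeatureMatrix(
        ids=list(ids), physchem=physchem,
        fingerprints=np.asarray(fingerprints, dtype=np.uint8),
        labels=None if labels is None else np.asarray(labels),
        config_hash=config_hash,
    )


@pytest.fixture
def fm_factory():
    return make_fm
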