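import numpy as np
import pytest

from molscale.pipeline import TrainConfig, pretrain
from molscale.synthetic import make_corpus


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=5.0, size=3)


@pytest.fixture(scope="session")
def smoke_corpus():
    return make_corpus(200, seed=0)


@pytest.fixture(scope="session")
def smoke_run(smoke_corpus):
    """One desk-scale pre-training run shared across tests.

    200 synthetic conformers, 5 epochs, batch 32, per-scale queues of 512.
    """
    cfg = TrainConfig.smoke(in_dim=smoke_corpus[0].atom_features.shape[1], seed=0)
    params, manifest = pretrain(smoke_corpus, cfg)
    return params, cfg, manifest
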