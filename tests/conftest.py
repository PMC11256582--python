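import numpy as np
import pytest

from pairsage import (
    DTPFeatures,
    DTPIndex,
    EmbeddingMatrix,
    SynthConfig,
    generate,
)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small planted-cluster dataset shared by fast pipeline-level tests."""
    return generate(
        SynthConfig(
            n_drugs=16,
            n_targets=20,
            n_diseases=16,
            n_side_effects=12,
            n_drug_clusters=2,
            n_target_clusters=2,
            fingerprint_bits=32,
            seq_length=80,
            assoc_noise=0.05,
            seed=7,
        )
    )


@pytest.fixture
def small_index():
    return DTPIndex([f"D{i}" for i in range(3)], [f"T{j}" for j in range(4)])


@pytest.fixture
def random_pair_features():
    """Random embeddings over a 3x4 pair grid (12 pair nodes)."""

    def make(seed=0, dim_d=6, dim_t=5, n_drugs=3, n_targets=4):
        rng = np.random.default_rng(seed)
        fd = EmbeddingMatrix(
            [f"D{i}" for i in range(n_drugs)], rng.normal(size=(n_drugs, dim_d))
        )
        ft = EmbeddingMatrix(
            [f"T{j}" for j in range(n_targets)], rng.normal(size=(n_targets, dim_t))
        )
        index = DTPIndex(fd.entity_ids, ft.entity_ids)
        return DTPFeatures(fd, ft, index)

    return make
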