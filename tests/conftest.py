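"""Shared fixtures: a tiny synthetic study dataset, its featurized form, and
a small untrained model.  Everything is generated at session start from
fixed seeds; nothing is read from disk."""
from __future__ import annotations

import numpy as np
import pytest

from pocketdti.embeddings import DRUG_DIM, PROTEIN_DIM, stub_provider
from pocketdti.model import DTIModel, ModelConfig, featurize
from pocketdti.synthetic import FixtureSpec, make_dataset

TINY_SPEC = FixtureSpec(n_proteins=6, n_drugs=8, n_pairs=40, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_dataset(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_featurized(tiny_dataset):
    return featurize(tiny_dataset.drugs, tiny_dataset.proteins,
                     tiny_dataset.assignments,
                     stub_provider(PROTEIN_DIM, 1), stub_provider(DRUG_DIM, 2), M=30)


@pytest.fixture(scope="session")
def small_model():
    # d=32 keeps unit tests quick; the width is architecture-agnostic
    return DTIModel(ModelConfig(d=32, ff_dim=64, gcn_layers=2, M=30), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
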