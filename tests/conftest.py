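"""Shared fixtures: a small BB2 corpus, its vocabulary, and a small cage
VAE trained once per session on a synthetic dataset for the behavioural
tests that need a non-random model."""

from __future__ import annotations

import numpy as np
import pytest

from cagevae import CageVAE, TrainConfig, build_vocabulary
from cagevae.synthetic import FixtureSpec, make_dataset

CORPUS = [
    "[Lr]C[Lr]",
    "[Lr]c1ccc([Lr])cc1",
    "[Lr]CCOC[Lr]",
    "[Lr]Cc1ccc(C[Lr])o1",
    "[Lr]C#Cc1ccc(C#C[Lr])cc1",
    "[Lr]Cc1ccc(C(=O)[Lr])cc1",
]


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary(CORPUS)


@pytest.fixture(scope="session")
def small_dataset():
    spec = FixtureSpec(n_bb1=2, n_reactions=2, n_bb2=32, n_cages=120,
                       unlabeled_fraction=0.25, rng_seed=11)
    records, bb1, reactions = make_dataset(spec)
    return spec, records, bb1, reactions


@pytest.fixture(scope="session")
def trained(small_dataset):
    """A small model trained for 45 epochs on 120 synthetic cages (about a
    minute; reconstructs >80% of training sequences)."""
    _, records, bb1, reactions = small_dataset
    model = CageVAE(records, bb1_catalog=bb1, reaction_catalog=reactions,
                    latent_dim=12, encoder_hidden=48, decoder_hidden=96,
                    embedding_dim=24, categorical_hidden=16, predictor_hidden=16,
                    encoder_decoder_dropout=0.05, predictor_dropout=0.1)
    cfg = TrainConfig(epochs=45, batch_size=8, learning_rate=0.005,
                      n_cycles=4, split_original=0.9, rng_seed=3,
                      final_lr_fraction=0.1)
    return model.fit(cfg)
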