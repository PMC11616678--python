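"""Shared fixtures: the synthetic study pipeline is built once per session.

The expensive fixtures (trained translation model, CNN head, the noise-only
negative-control model) are session-scoped; everything downstream reuses
them so the whole suite stays within a desk-scale CPU budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from pro3di.curation import CurationConfig, apply_filters, cluster_split
from pro3di.io import default_tdi_matrix
from pro3di.nn import ModelConfig, Seq2SeqModel
from pro3di.seq2seq import TrainConfig, encoder_embed_batch, train
from pro3di.structure_head import HeadConfig, train_head
from pro3di.synthetic import WorldConfig, generate_world
from pro3di.vocabulary import BilingualVocabulary

SEED = 11

WORLD = WorldConfig(n_proteins=6500, noise_rate=0.0, seed=SEED)
NOISY_WORLD = WorldConfig(n_proteins=1500, noise_rate=1.0, seed=SEED)
CURATION = CurationConfig(val_size=250, test_size=250, seed=SEED)
TRAINING = TrainConfig(seed=SEED)
# the no-signal control needs only enough steps to reach its (flat) optimum
NOISY_TRAINING = TrainConfig(
    seed=SEED, phase1_steps=40, phase2_max_len_schedule=((250, 64),), eval_every=250
)
HEAD = HeadConfig(epochs=10, seed=SEED)
N_HEAD_TRAIN = 3000


@pytest.fixture(scope="session")
def vocab() -> BilingualVocabulary:
    return BilingualVocabulary(n_sentinel=16)


@pytest.fixture(scope="session")
def tdi_matrix():
    return default_tdi_matrix()


@pytest.fixture(scope="session")
def curated_world():
    """Noise-free synthetic proteome, filtered and split by whole clusters."""
    records = generate_world(WORLD)
    kept, _report = apply_filters(records, CURATION)
    return cluster_split(kept, CURATION)


@pytest.fixture(scope="session")
def trained(curated_world):
    """The two-phase-trained toy translation model (the slow fixture)."""
    return train(curated_world, TRAINING)


@pytest.fixture(scope="session")
def trained_head(trained, curated_world):
    train_recs = [r for r in curated_world if r.split == "train"][:N_HEAD_TRAIN]
    embeddings = encoder_embed_batch(trained.model, train_recs, trained.vocab)
    return train_head(embeddings, [r.tdi_seq for r in train_recs], HEAD)


@pytest.fixture(scope="session")
def noisy_trained():
    """Negative control: identical pipeline on a noise_rate=1 world."""
    records = generate_world(NOISY_WORLD)
    kept, _ = apply_filters(records, CurationConfig(val_size=150, test_size=150, seed=SEED))
    kept = cluster_split(kept, CurationConfig(val_size=150, test_size=150, seed=SEED))
    return train(kept, NOISY_TRAINING), kept


@pytest.fixture(scope="session")
def untrained_model(vocab):
    """A freshly initialized (never trained) model for negative controls."""
    return Seq2SeqModel(
        ModelConfig(vocab_size=vocab.size, d_model=64, n_heads=4, d_ff=128,
                    n_encoder_layers=1, n_decoder_layers=1, seed=SEED)
    )
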