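"""Named configuration presets.

`FULL_SCALE` mirrors the protocol for the ~1.2-million-cage dataset
(latent 128, hidden 256/384, 100 epochs, batch 64, Adam 1e-4). The
`fixture_*` presets are the desk-scale counterparts used on synthetic
datasets of a few hundred cages: latent 16, smaller hidden sizes, 30
epochs, and an optimiser (batch 16, lr 5e-3) and dropout (0.05/0.1) chosen
for that data volume — at 500 records the full-scale regularisation is far
too strong and the full-scale learning rate far too slow to converge within
the shorter schedule.
"""

from __future__ import annotations

from .training import TrainConfig

__all__ = ["FIXTURE_MODEL_KWARGS", "fixture_train_config"]

# ModelConfig overrides for desk-scale fits (vocab/catalog sizes come from
# the data).
FIXTURE_MODEL_KWARGS = dict(
    latent_dim=16,
    encoder_hidden=64,
    decoder_hidden=128,
    embedding_dim=32,
    categorical_hidden=32,
    predictor_hidden=32,
    encoder_decoder_dropout=0.05,
    predictor_dropout=0.1,
)


def fixture_train_config(rng_seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Desk-scale training protocol (same schedulers as full scale)."""
    return TrainConfig(
        epochs=epochs,
        batch_size=16,
        learning_rate=0.005,
        n_cycles=5,
        beta_max=0.0025,
        gamma_max=1.0,
        split_original=0.900,
        split_augmented=0.998,
        final_lr_fraction=0.1,
        rng_seed=rng_seed,
    )
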