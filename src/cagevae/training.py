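"""Training loop, loss schedulers and the greedy dataset split.

Two schedulers stabilise joint training. The KL weight beta follows a
cyclic schedule (rising linearly from 0 to its maximum over the first part
of each cycle, then holding) to counteract KL vanishing in the
autoregressive decoder. A monotone linear weight, growing 0 -> 1 over the
whole run, scales both the BB1+reaction reconstruction component and the
predictor loss, so the model first learns the BB2 sequence and only later
balances the full molecule and the latent-space organisation.

The split is greedy: most of both the original and the augmented datasets
go to training (defaults 90.0% / 99.8%), the complements forming the two
held-out sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._nn import Adam
from .model import CageVAENetwork, EncodedBatch, LossBreakdown, LossWeights

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "cyclic_beta",
    "linear_weight",
    "split_dataset",
    "train",
    "evaluate_predictor",
    "reconstruction_accuracy",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; defaults are the full-scale protocol
    (100 epochs, batch 64, Adam at 1e-4, five beta cycles, beta 0.0025)."""

    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-4
    n_cycles: int = 5
    beta_max: float = 0.0025
    gamma_max: float = 1.0
    ramp_fraction: float = 0.5
    split_original: float = 0.900
    split_augmented: float = 0.998
    grad_clip: float = 5.0  # global gradient-norm ceiling; 0 disables
    final_lr_fraction: float = 1.0  # cosine decay floor; 1.0 = constant lr
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.split_original <= 1.0 and 0.0 < self.split_augmented <= 1.0):
            raise ValueError("split fractions must lie in (0, 1]")
        if not 0.0 < self.ramp_fraction <= 1.0:
            raise ValueError("ramp_fraction must lie in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1 or self.n_cycles < 1:
            raise ValueError("epochs, batch_size and n_cycles must be positive")


def cyclic_beta(epoch: int, epochs: int, n_cycles: int, beta_max: float,
                ramp_fraction: float = 0.5) -> float:
    """Cyclic KL-annealing weight for `epoch` (constant within an epoch).

    Each of the `n_cycles` cycles spans ``epochs / n_cycles`` epochs; within
    a cycle the weight rises linearly from 0 to `beta_max` over the first
    `ramp_fraction` of the cycle and then holds the maximum.
    """
    if not 0 <= epoch < epochs:
        raise ValueError(f"epoch {epoch} outside [0, {epochs})")
    cycle_len = epochs / n_cycles
    position = epoch % cycle_len
    ramp_len = cycle_len * ramp_fraction
    return beta_max * min(1.0, position / ramp_len)


def linear_weight(epoch: int, epochs: int) -> float:
    """Monotone 0 -> 1 weight: epoch / (epochs - 1)."""
    if not 0 <= epoch < epochs:
        raise ValueError(f"epoch {epoch} outside [0, {epochs})")
    return 1.0 if epochs == 1 else epoch / (epochs - 1)


def split_dataset(original: list, augmented: list, config: TrainConfig):
    """Greedy random split into (train, test_original, test_augmented).

    Training takes ``floor(split_original * N_original)`` original records
    plus ``floor(split_augmented * N_augmented)`` augmented records; the
    complements are held out. Selection is uniform under `rng_seed`.
    """
    if not original:
        raise ValueError("original dataset is empty")
    rng = np.random.default_rng(config.rng_seed)

    def _partition(records, fraction):
        n_train = math.floor(fraction * len(records))
        perm = rng.permutation(len(records))
        train = [records[i] for i in perm[:n_train]]
        test = [records[i] for i in perm[n_train:]]
        return train, test

    train_orig, test_orig = _partition(original, config.split_original)
    train_aug, test_aug = ([], []) if not augmented else _partition(
        augmented, config.split_augmented)
    return train_orig + train_aug, test_orig, test_aug


def _clip_gradients(network: CageVAENetwork, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most max_norm;
    guards the recurrent decoder against occasional exploding steps."""
    params = [p for p in network.parameters() if p.grad is not None]
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            p.grad *= scale


@dataclass
class TrainingHistory:
    """Per-epoch loss curves (train plus each held-out set)."""

    train: list[LossBreakdown]
    test_original: list[LossBreakdown]
    test_augmented: list[LossBreakdown]
    schedule: list[dict]


def train(
    network: CageVAENetwork,
    train_data: EncodedBatch,
    config: TrainConfig,
    test_original: EncodedBatch | None = None,
    test_augmented: EncodedBatch | None = None,
    callback=None,
) -> TrainingHistory:
    """Fit the network with Adam under the two schedulers.

    Labeled and unlabeled records are mixed uniformly at random into every
    batch. The predictor sees sampled z during training and the posterior
    mean at evaluation. Aborts with ``FloatingPointError`` on a non-finite
    loss.
    """
    rng = np.random.default_rng(config.rng_seed)
    sample_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    opt = Adam(network.parameters(), lr=config.learning_rate)
    history = TrainingHistory([], [], [], [])

    n = len(train_data)
    for epoch in range(config.epochs):
        beta = cyclic_beta(epoch, config.epochs, config.n_cycles,
                           config.beta_max, config.ramp_fraction)
        w = linear_weight(epoch, config.epochs)
        weights = LossWeights(beta=beta, gamma=config.gamma_max * w,
                              w_bb2=1.0, w_bb1rxn=w)
        if config.final_lr_fraction < 1.0:
            progress = epoch / max(config.epochs - 1, 1)
            cos = 0.5 * (1.0 + math.cos(math.pi * progress))
            opt.lr = config.learning_rate * (
                config.final_lr_fraction + (1.0 - config.final_lr_fraction) * cos)
        history.schedule.append({"epoch": epoch, "beta": beta,
                                 "linear_weight": w, "learning_rate": opt.lr})

        perm = rng.permutation(n)
        epoch_terms = np.zeros(5)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = train_data.subset(perm[start:start + config.batch_size])
            network.zero_grad()
            total, bd = network.compute_loss(batch, weights, rng=sample_rng,
                                             dropout_rng=dropout_rng)
            if not np.isfinite(bd.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {bd}"
                )
            total.backward()
            if config.grad_clip > 0:
                _clip_gradients(network, config.grad_clip)
            opt.step()
            epoch_terms += [bd.recon_bb2, bd.recon_bb1rxn, bd.kl, bd.pred, bd.total]
            n_batches += 1
        epoch_terms /= n_batches
        history.train.append(LossBreakdown(*epoch_terms))

        for data, curve in ((test_original, history.test_original),
                            (test_augmented, history.test_augmented)):
            if data is not None and len(data):
                _, bd = network.compute_loss(data, weights)
                curve.append(bd)
        if callback is not None:
            callback(epoch, history)
    return history


def evaluate_predictor(network: CageVAENetwork, data: EncodedBatch) -> float:
    """Accuracy of collapse/persist decisions at threshold 0.5, computed on
    posterior means of fully labeled records."""
    if len(data) == 0:
        raise ValueError("empty evaluation set")
    if not data.labeled.all():
        raise ValueError("evaluation records must all be labeled")
    mean, _ = network.encode(data)
    p = network.predict_persistence(mean.data)
    return float(((p >= 0.5) == (data.y >= 0.5)).mean())


def reconstruction_accuracy(network: CageVAENetwork, data: EncodedBatch) -> dict:
    """Greedy-decode posterior means and score exact reconstruction.

    Returns the fraction of records whose BB2 token sequence round-trips
    exactly, the BB1/reaction argmax accuracies, and the fraction where all
    three components match.
    """
    from ._autodiff import Tensor

    mean, _ = network.encode(data)
    seqs = network.decode_bb2(mean.data, mode="greedy")
    bb2_exact = (seqs == data.tokens).all(axis=1)
    bb1_logits, rxn_logits = network.decode_bb1_reaction(Tensor(mean.data))
    bb1_ok = bb1_logits.data.argmax(axis=1) == data.bb1
    rxn_ok = rxn_logits.data.argmax(axis=1) == data.reaction
    return {
        "bb2_exact": float(bb2_exact.mean()),
        "bb1_accuracy": float(bb1_ok.mean()),
        "reaction_accuracy": float(rxn_ok.mean()),
        "cage_exact": float((bb2_exact & bb1_ok & rxn_ok).mean()),
    }
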