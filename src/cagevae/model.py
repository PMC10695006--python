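"""The multi-component cage VAE with a jointly trained shape-persistence
predictor.

Architecture
------------
The disassembled cage is encoded by two cooperating branches. A
bidirectional GRU reads the tokenised BB2 SMILES; the final hidden states of
both directions summarise the sequence. An MLP reads the one-hot BB1 and
reaction ordinals. The two summaries are concatenated and mapped by two
affine heads to the mean and log-variance of a diagonal-Gaussian posterior
q(z|X) over a shared continuous latent space, regularised toward the
standard-normal prior through the KL term of the beta-weighted ELBO.

Decoding mirrors the split: a single-direction GRU, initialised from z and
fed z alongside every input embedding, reconstructs the BB2 token sequence
autoregressively, while an MLP with two categorical heads reconstructs the
BB1 and reaction ordinals — generation therefore can never leave the
catalogs. A dropout-regularised MLP predictor maps z to the probability of
collapse (label 1 = collapsed), trained semi-supervised through a mask so
unlabeled cages contribute no predictive loss.

The training objective is the weighted sum
``w_bb2*CE(bb2) + w_bb1rxn*(CE(bb1)+CE(rxn)) + beta*KL + gamma*BCE(masked)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, stack
from ._nn import Embedding, GRUCell, Linear, MLP, Module, dropout_mask
from .representation import (
    COLLAPSED,
    CageRecord,
    NOT_COLLAPSED,
    TokenVocabulary,
    tokenize,
)

__all__ = [
    "ModelConfig",
    "LossWeights",
    "LossBreakdown",
    "CageVAENetwork",
    "kl_divergence",
    "encode_records",
    "EncodedBatch",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults are the full-scale settings: encoder hidden 256, decoder hidden
    384, latent 128, encoder/decoder dropout 0.25, predictor dropout 0.5.
    Embedding and auxiliary MLP widths are implementation choices.
    """

    vocab_size: int
    n_bb1: int
    n_reactions: int
    max_len: int
    latent_dim: int = 128
    encoder_hidden: int = 256
    decoder_hidden: int = 384
    embedding_dim: int = 64
    categorical_hidden: int = 64
    predictor_hidden: int = 64
    encoder_decoder_dropout: float = 0.25
    predictor_dropout: float = 0.5

    def __post_init__(self):
        for name in ("vocab_size", "n_bb1", "n_reactions", "max_len", "latent_dim",
                     "encoder_hidden", "decoder_hidden", "embedding_dim",
                     "categorical_hidden", "predictor_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("encoder_decoder_dropout", "predictor_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the four loss components (training schedulers rescale
    beta, gamma and w_bb1rxn per epoch)."""

    beta: float = 0.0025
    gamma: float = 1.0
    w_bb2: float = 1.0
    w_bb1rxn: float = 1.0

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0 or self.w_bb2 < 0 or self.w_bb1rxn < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    recon_bb2: float
    recon_bb1rxn: float
    kl: float
    pred: float
    total: float


@dataclass(frozen=True)
class EncodedBatch:
    """Integer-encoded dataset ready for the network."""

    tokens: np.ndarray      # (N, max_len) int
    bb1: np.ndarray         # (N,) int
    reaction: np.ndarray    # (N,) int
    y: np.ndarray           # (N,) float, 1 = collapsed (0 where unlabeled)
    labeled: np.ndarray     # (N,) bool mask

    def __len__(self) -> int:
        return self.tokens.shape[0]

    def subset(self, idx) -> "EncodedBatch":
        return EncodedBatch(self.tokens[idx], self.bb1[idx], self.reaction[idx],
                            self.y[idx], self.labeled[idx])


def encode_records(records: list[CageRecord], vocab: TokenVocabulary) -> EncodedBatch:
    tokens = np.stack([tokenize(r.bb2, vocab) for r in records])
    bb1 = np.array([r.bb1_id for r in records], dtype=np.int64)
    rxn = np.array([r.reaction_id for r in records], dtype=np.int64)
    labeled = np.array([r.label != "unlabeled" for r in records])
    y = np.array([1.0 if r.label == COLLAPSED else 0.0 for r in records])
    return EncodedBatch(tokens, bb1, rxn, y, labeled)


def kl_divergence(mean: Tensor, log_var: Tensor) -> Tensor:
    """Closed-form KL(q || N(0, I)) for a diagonal Gaussian posterior:
    0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2), averaged over the batch."""
    per_dim = 0.5 * (mean * mean + log_var.exp() - 1.0 - log_var)
    return per_dim.sum(axis=-1).mean() if per_dim.data.ndim > 1 else per_dim.sum()


class CageVAENetwork(Module):
    """Parameters and differentiable operations of the cage VAE."""

    def __init__(self, config: ModelConfig, rng_seed: int = 0):
        rng = np.random.default_rng(rng_seed)
        c = config
        self.config = c
        self.embedding = Embedding(c.vocab_size, c.embedding_dim, rng)
        self.enc_fwd = GRUCell(c.embedding_dim, c.encoder_hidden, rng)
        self.enc_bwd = GRUCell(c.embedding_dim, c.encoder_hidden, rng)
        self.enc_cat = MLP([c.n_bb1 + c.n_reactions, c.categorical_hidden,
                            c.categorical_hidden], rng)
        fused = 2 * c.encoder_hidden + c.categorical_hidden
        self.to_mean = Linear(fused, c.latent_dim, rng)
        self.to_log_var = Linear(fused, c.latent_dim, rng)
        self.dec_init = Linear(c.latent_dim, c.decoder_hidden, rng)
        self.dec_gru = GRUCell(c.embedding_dim + c.latent_dim, c.decoder_hidden, rng)
        self.dec_out = Linear(c.decoder_hidden, c.vocab_size, rng)
        self.dec_cat = MLP([c.latent_dim, c.categorical_hidden, c.categorical_hidden], rng)
        self.head_bb1 = Linear(c.categorical_hidden, c.n_bb1, rng)
        self.head_rxn = Linear(c.categorical_hidden, c.n_reactions, rng)
        self.predictor = MLP([c.latent_dim, c.predictor_hidden, 1], rng)

    # -- encoder -----------------------------------------------------------

    def encode(self, batch: EncodedBatch,
               dropout_rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Map a batch to per-cage posterior (mean, log_variance).

        `dropout_rng` enables training-mode dropout; None gives the
        deterministic evaluation path.
        """
        c = self.config
        n, t_len = batch.tokens.shape
        inputs = [self.embedding(batch.tokens[:, t]) for t in range(t_len)]
        h0 = Tensor(np.zeros((n, c.encoder_hidden)))
        h_fwd = self.enc_fwd.run(inputs, h0)[-1]
        h_bwd = self.enc_bwd.run(inputs, h0, reverse=True)[0]
        onehot = np.zeros((n, c.n_bb1 + c.n_reactions))
        onehot[np.arange(n), batch.bb1] = 1.0
        onehot[np.arange(n), c.n_bb1 + batch.reaction] = 1.0
        h_cat = self.enc_cat(Tensor(onehot), dropout=c.encoder_decoder_dropout
                             if dropout_rng is not None else 0.0, rng=dropout_rng)
        fused = concat([h_fwd, h_bwd, h_cat], axis=-1)
        if dropout_rng is not None and c.encoder_decoder_dropout > 0:
            fused = fused * dropout_mask(fused.shape, c.encoder_decoder_dropout, dropout_rng)
        return self.to_mean(fused), self.to_log_var(fused)

    @staticmethod
    def reparameterize(mean: Tensor, log_var: Tensor,
                       rng: np.random.Generator) -> Tensor:
        """z = mean + exp(log_var / 2) * eps with eps ~ N(0, I)."""
        eps = Tensor(rng.standard_normal(mean.shape))
        return mean + (log_var * 0.5).exp() * eps

    # -- decoders ----------------------------------------------------------

    def decode_bb2_teacher_forced(self, z: Tensor, tokens: np.ndarray,
                                  dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Per-position next-token logits (N, max_len-1, vocab) under teacher
        forcing: position t predicts tokens[:, t+1] from tokens[:, :t+1]."""
        c = self.config
        h = self.dec_init(z).tanh()
        logits = []
        for t in range(tokens.shape[1] - 1):
            x = concat([self.embedding(tokens[:, t]), z], axis=-1)
            h = self.dec_gru(x, h)
            out = h
            if dropout_rng is not None and c.encoder_decoder_dropout > 0:
                out = out * dropout_mask(out.shape, c.encoder_decoder_dropout, dropout_rng)
            logits.append(self.dec_out(out))
        return stack(logits, axis=1)

    def decode_bb2(self, z: np.ndarray, mode: str = "greedy",
                   rng: np.random.Generator | None = None) -> np.ndarray:
        """Autoregressive generation from latent vectors (no gradients).

        Starts at [sos]; each step feeds back the argmax (greedy) or a
        multinomial draw from the softmax; stops at [eos] or max_len.
        Returns full padded index sequences (N, max_len).
        """
        if mode not in ("greedy", "multinomial"):
            raise ValueError(f"unknown decoding mode {mode!r}")
        if mode == "multinomial" and rng is None:
            raise ValueError("multinomial decoding needs an rng")
        c = self.config
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        n = z.shape[0]
        zt = Tensor(z)
        h = self.dec_init(zt).tanh()
        current = np.full(n, 1, dtype=np.int64)  # [sos] index
        seqs = np.full((n, c.max_len), 0, dtype=np.int64)  # [pad]
        seqs[:, 0] = current
        done = np.zeros(n, dtype=bool)
        for t in range(1, c.max_len):
            x = concat([self.embedding(current), zt], axis=-1)
            h = self.dec_gru(x, h)
            logits = self.dec_out(h).data
            if mode == "greedy":
                nxt = logits.argmax(axis=-1)
            else:
                shifted = logits - logits.max(axis=-1, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=-1, keepdims=True)
                nxt = np.array([rng.choice(c.vocab_size, p=p) for p in probs])
            nxt = np.where(done, 0, nxt)
            seqs[:, t] = nxt
            done |= nxt == 2  # [eos] index
            if done.all():
                break
            current = np.where(done, 0, nxt)
        return seqs

    def decode_bb1_reaction(self, z: Tensor,
                            dropout_rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Categorical logits over the BB1 catalog and the reaction catalog."""
        c = self.config
        h = self.dec_cat(z, dropout=c.encoder_decoder_dropout
                         if dropout_rng is not None else 0.0, rng=dropout_rng)
        return self.head_bb1(h), self.head_rxn(h)

    # -- predictor ---------------------------------------------------------

    def predict_logit(self, z: Tensor,
                      dropout_rng: np.random.Generator | None = None) -> Tensor:
        c = self.config
        return self.predictor(
            z, dropout=c.predictor_dropout if dropout_rng is not None else 0.0,
            rng=dropout_rng,
        )

    def predict_persistence(self, z: np.ndarray) -> np.ndarray:
        """Probability of collapse for latent vectors (evaluation mode)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        return self.predict_logit(Tensor(z)).sigmoid().data[:, 0]

    # -- loss --------------------------------------------------------------

    def compute_loss(
        self,
        batch: EncodedBatch,
        weights: LossWeights,
        rng: np.random.Generator | None = None,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, LossBreakdown]:
        """Forward pass and the four-term objective on one batch.

        `rng` drives the reparameterisation draw (None uses the posterior
        mean); `dropout_rng` enables dropout. The predictive BCE runs on the
        labeled subset only and is exactly zero for an all-unlabeled batch.
        """
        mean, log_var = self.encode(batch, dropout_rng=dropout_rng)
        z = self.reparameterize(mean, log_var, rng) if rng is not None else mean

        logits = self.decode_bb2_teacher_forced(z, batch.tokens, dropout_rng=dropout_rng)
        targets = batch.tokens[:, 1:]
        mask = targets != 0  # [pad] index
        logp = logits.log_softmax(axis=-1)
        n, t_len = targets.shape
        rows = np.repeat(np.arange(n), t_len)
        cols = np.tile(np.arange(t_len), n)
        picked = logp[rows, cols, targets.reshape(-1)]
        recon_bb2 = -(picked * Tensor(mask.reshape(-1).astype(float))).sum() * (
            1.0 / max(int(mask.sum()), 1)
        )

        bb1_logits, rxn_logits = self.decode_bb1_reaction(z, dropout_rng=dropout_rng)
        ce_bb1 = -bb1_logits.log_softmax(axis=-1)[np.arange(n), batch.bb1].mean()
        ce_rxn = -rxn_logits.log_softmax(axis=-1)[np.arange(n), batch.reaction].mean()
        recon_bb1rxn = ce_bb1 + ce_rxn

        kl = kl_divergence(mean, log_var)

        labeled_idx = np.flatnonzero(batch.labeled)
        if labeled_idx.size:
            logit = self.predict_logit(z[labeled_idx], dropout_rng=dropout_rng)
            p = logit.sigmoid()
            y = Tensor(batch.y[labeled_idx][:, None])
            pred = -(y * (p + _EPS).log() + (1.0 - y) * (1.0 - p + _EPS).log()).mean()
        else:
            pred = Tensor(0.0)

        total = (weights.w_bb2 * recon_bb2 + weights.w_bb1rxn * recon_bb1rxn
                 + weights.beta * kl + weights.gamma * pred)
        breakdown = LossBreakdown(
            recon_bb2=float(recon_bb2.data),
            recon_bb1rxn=float(recon_bb1rxn.data),
            kl=float(kl.data),
            pred=float(pred.data),
            total=float(total.data),
        )
        return total, breakdown
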