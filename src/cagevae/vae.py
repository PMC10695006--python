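"""Model/Results interface to the cage VAE.

`CageVAE` binds a dataset (original, optionally augmented, cage records) to
the network architecture; `fit()` runs the scheduled training loop and
returns a `CageVAEResults` carrying the trained parameters, the per-epoch
loss curves and diagnostics, with generation strategies (prior sampling,
repeated reconstruction, interpolation, Bayesian optimisation) and the
filter cascade hanging off it.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._autodiff import Tensor
from .filters import compute_metrics, filter_cage, generate_with_filter, pca_latent
from .model import (
    CageVAENetwork,
    EncodedBatch,
    ModelConfig,
    encode_records,
)
from .representation import (
    BB1Catalog,
    CageRecord,
    ReactionCatalog,
    TokenVocabulary,
    build_vocabulary,
    cage_key,
    detokenize,
)
from .sampling import (
    AcquisitionConfig,
    bayesian_optimize,
    latent_bounds,
    lerp,
    sample_prior,
    slerp,
)
from .training import (
    TrainConfig,
    evaluate_predictor,
    reconstruction_accuracy,
    split_dataset,
    train,
)

__all__ = ["CageVAE", "CageVAEResults"]


class CageVAE:
    """The cage VAE bound to a dataset.

    Parameters
    ----------
    original : list of CageRecord
        Curated records (labels allowed).
    augmented : list of CageRecord
        Combinatorially enumerated unlabeled records.
    bb1_catalog, reaction_catalog :
        The categorical vocabularies for vertex precursors and reactions.
    vocab : TokenVocabulary, optional
        Built from the BB2 corpus of all records when omitted.
    **config_overrides :
        ModelConfig fields (latent_dim, encoder_hidden, ...).
    """

    def __init__(self, original, augmented=(),
                 bb1_catalog: BB1Catalog = None,
                 reaction_catalog: ReactionCatalog = None,
                 vocab: TokenVocabulary | None = None,
                 **config_overrides):
        if bb1_catalog is None or reaction_catalog is None:
            raise ValueError("bb1_catalog and reaction_catalog are required")
        self.original = list(original)
        self.augmented = list(augmented)
        self.bb1_catalog = bb1_catalog
        self.reaction_catalog = reaction_catalog
        if vocab is None:
            corpus = {r.bb2 for r in self.original + self.augmented}
            vocab = build_vocabulary(sorted(corpus))
        self.vocab = vocab
        self.config = ModelConfig(
            vocab_size=len(vocab),
            n_bb1=len(bb1_catalog),
            n_reactions=len(reaction_catalog),
            max_len=vocab.max_len,
            **config_overrides,
        )

    def fit(self, train_config: TrainConfig | None = None, callback=None) -> "CageVAEResults":
        """Split, train under the schedulers, and wrap the outcome."""
        cfg = train_config or TrainConfig()
        train_records, test_orig, test_aug = split_dataset(
            self.original, self.augmented, cfg)
        train_data = encode_records(train_records, self.vocab)
        test_orig_data = encode_records(test_orig, self.vocab) if test_orig else None
        test_aug_data = encode_records(test_aug, self.vocab) if test_aug else None
        network = CageVAENetwork(self.config, rng_seed=cfg.rng_seed)
        history = train(network, train_data, cfg,
                        test_original=test_orig_data,
                        test_augmented=test_aug_data,
                        callback=callback)
        return CageVAEResults(self, network, cfg, history,
                              train_records, test_orig, test_aug)


class CageVAEResults:
    """A fitted cage VAE: trained parameters, curves, diagnostics and the
    latent-space generation strategies."""

    def __init__(self, model: CageVAE, network: CageVAENetwork,
                 train_config: TrainConfig, history,
                 train_records, test_original, test_augmented):
        self.model = model
        self.network = network
        self.train_config = train_config
        self.history = history
        self.train_records = train_records
        self.test_original = test_original
        self.test_augmented = test_augmented
        self._train_latents: np.ndarray | None = None

    # -- core mappings -----------------------------------------------------

    def encode_records(self, records: list[CageRecord]) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (means, log_variances) for records, evaluation mode."""
        batch = encode_records(records, self.model.vocab)
        mean, log_var = self.network.encode(batch)
        return mean.data, log_var.data

    def decode_latent(self, z: np.ndarray, mode: str = "greedy",
                      rng_seed: int | None = None) -> list[CageRecord]:
        """Decode latent vectors to (unvalidated) cage records."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        rng = None if rng_seed is None else np.random.default_rng(rng_seed)
        seqs = self.network.decode_bb2(z, mode=mode, rng=rng)
        bb1_logits, rxn_logits = self.network.decode_bb1_reaction(Tensor(z))
        bb1 = bb1_logits.data.argmax(axis=1)
        rxn = rxn_logits.data.argmax(axis=1)
        return [
            CageRecord(int(bb1[i]), detokenize(seqs[i], self.model.vocab), int(rxn[i]))
            for i in range(z.shape[0])
        ]

    def predict_collapse(self, z: np.ndarray) -> np.ndarray:
        """Probability of collapse (1 = collapsed) for latent vectors."""
        return self.network.predict_persistence(z)

    def training_latents(self) -> np.ndarray:
        """Posterior means of the training records (cached)."""
        if self._train_latents is None:
            batch = encode_records(self.train_records, self.model.vocab)
            mean, _ = self.network.encode(batch)
            self._train_latents = mean.data
        return self._train_latents

    # -- diagnostics -------------------------------------------------------

    def evaluate_predictor(self, records: list[CageRecord] | None = None) -> float:
        """Shape-persistence accuracy on labeled held-out originals."""
        if records is None:
            records = [r for r in self.test_original if r.label != "unlabeled"]
        return evaluate_predictor(self.network,
                                  encode_records(records, self.model.vocab))

    def reconstruction_accuracy(self, records: list[CageRecord] | None = None) -> dict:
        if records is None:
            records = self.train_records
        return reconstruction_accuracy(self.network,
                                       encode_records(records, self.model.vocab))

    def pca_latent(self, latents: np.ndarray | None = None, n_components: int = 2):
        return pca_latent(self.training_latents() if latents is None else latents,
                          n_components)

    def reference_keys(self, include_augmented: bool = True) -> set[str]:
        records = self.model.original + (self.model.augmented if include_augmented else [])
        return {cage_key(r) for r in records}

    # -- generation strategies ---------------------------------------------

    def sample(self, n: int, rng_seed: int = 0, mode: str = "greedy") -> list[CageRecord]:
        """Decode n random draws from the standard-normal prior."""
        z = sample_prior(n, self.model.config.latent_dim, rng_seed)
        return self.decode_latent(z, mode=mode, rng_seed=rng_seed + 1)

    def sample_metrics(self, n: int = 1000, rng_seed: int = 0):
        """Prior-sample a batch and score the benchmark metric rates."""
        batch = self.sample(n, rng_seed=rng_seed)
        return compute_metrics(batch, self.reference_keys(include_augmented=False),
                               self.reference_keys(include_augmented=True))

    def reconstruct_repeated(self, record: CageRecord, n_samples: int,
                             rng_seed: int = 0) -> list[dict]:
        """Encode once, draw `n_samples` latent samples, decode each.

        Returns decoded-cage counts sorted descending, each entry with the
        mean Euclidean latent distance of its draws from the posterior mean.
        """
        mean, log_var = self.encode_records([record])
        rng = np.random.default_rng(rng_seed)
        eps = rng.standard_normal((n_samples, mean.shape[1]))
        zs = mean + np.exp(log_var / 2.0) * eps
        decoded = self.decode_latent(zs)
        groups: dict[tuple, dict] = {}
        for z, rec in zip(zs, decoded):
            key = (rec.bb1_id, rec.bb2, rec.reaction_id)
            entry = groups.setdefault(key, {"record": rec, "count": 0, "distances": []})
            entry["count"] += 1
            entry["distances"].append(float(np.linalg.norm(z - mean[0])))
        out = [
            {"record": e["record"], "count": e["count"],
             "mean_latent_distance": float(np.mean(e["distances"]))}
            for e in groups.values()
        ]
        out.sort(key=lambda e: e["count"], reverse=True)
        return out

    def interpolate(self, start: CageRecord, end: CageRecord, steps: int = 10,
                    method: str = "slerp"):
        """Path between the posterior means of two cages, with the decoded
        cage and predicted collapse probability at every point."""
        mean, _ = self.encode_records([start, end])
        path = (slerp if method == "slerp" else lerp)(mean[0], mean[1], steps)
        decoded = self.decode_latent(path.points)
        probs = self.predict_collapse(path.points)
        return path, decoded, probs

    def interpolation_generate(self, start: CageRecord, end: CageRecord,
                               threshold: float = 0.8, steps: int = 10,
                               method: str = "slerp"):
        """Conditional generation along an interpolation path.

        The start cage's predicted shape-persistence probability must reach
        the threshold; path points whose decoded cages also reach it are
        returned as ``(record, p_persist)`` pairs.
        """
        mean, _ = self.encode_records([start, end])
        p_start = 1.0 - float(self.predict_collapse(mean[0][None, :])[0])
        if p_start < threshold:
            raise ValueError(
                f"start cage persistence probability {p_start:.3f} below "
                f"threshold {threshold}"
            )
        path, decoded, probs = self.interpolate(start, end, steps, method)
        persist = 1.0 - probs
        return [(rec, float(p)) for rec, p in zip(decoded, persist) if p >= threshold]

    def acquisition_config(self, omega: float = 0.1, target: int = 0) -> AcquisitionConfig:
        return AcquisitionConfig(bounds=latent_bounds(self.training_latents()),
                                 omega=omega, target=target)

    def optimize(self, n_iterations: int = 50, rng_seed: int = 0,
                 omega: float = 0.1, method: str = "gp",
                 config: AcquisitionConfig | None = None):
        """Bayesian optimisation toward shape-persistent cages.

        Returns ``(records, points, values)`` ranked best-first by the
        acquisition.
        """
        cfg = config or self.acquisition_config(omega=omega)
        points, values = bayesian_optimize(self.predict_collapse, cfg,
                                           n_iterations=n_iterations,
                                           rng_seed=rng_seed, method=method)
        return self.decode_latent(points), points, values

    def generate_filtered(self, n_required: int, max_attempts: int,
                          rng_seed: int = 0, include_augmented: bool = True):
        """Prior sampling through the five-stage filter with resampling."""
        rng = np.random.default_rng(rng_seed)
        latent_dim = self.model.config.latent_dim

        def sampler():
            return self.decode_latent(rng.standard_normal((1, latent_dim)))[0]

        return generate_with_filter(sampler, self.reference_keys(include_augmented),
                                    n_required, max_attempts)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        c = self.model.config
        lines = [
            "Cage VAE Results",
            "=" * 58,
            f"Original records:     {len(self.model.original):>8}",
            f"Augmented records:    {len(self.model.augmented):>8}",
            f"Training records:     {len(self.train_records):>8}",
            f"Held-out original:    {len(self.test_original):>8}",
            f"Held-out augmented:   {len(self.test_augmented):>8}",
            f"Vocabulary size:      {c.vocab_size:>8}",
            f"Max sequence length:  {c.max_len:>8}",
            f"Latent dimension:     {c.latent_dim:>8}",
            f"Epochs trained:       {self.train_config.epochs:>8}",
            "-" * 58,
        ]
        final = self.history.train[-1]
        lines += [
            "Final training losses:",
            f"  BB2 reconstruction (CE/token):   {final.recon_bb2:9.4f}",
            f"  BB1+reaction reconstruction:     {final.recon_bb1rxn:9.4f}",
            f"  KL divergence:                   {final.kl:9.4f}",
            f"  Predictor BCE (masked):          {final.pred:9.4f}",
            f"  Weighted total:                  {final.total:9.4f}",
        ]
        labeled_test = [r for r in self.test_original if r.label != "unlabeled"]
        if labeled_test:
            acc = self.evaluate_predictor(labeled_test)
            lines.append(f"Predictor accuracy (held-out original): {acc:9.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import save_checkpoint

        save_checkpoint(path, self.network, self.model.vocab,
                        self.model.bb1_catalog, self.model.reaction_catalog)
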