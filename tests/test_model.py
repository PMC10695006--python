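"""VAE network operations: posterior, reparameterisation, decoders, losses."""

import numpy as np
import pytest

from cagevae._autodiff import Tensor
from cagevae._nn import Adam
from cagevae.model import (
    CageVAENetwork,
    EncodedBatch,
    LossWeights,
    ModelConfig,
    encode_records,
    kl_divergence,
)
from cagevae.representation import CageRecord, build_vocabulary

from conftest import CORPUS


@pytest.fixture(scope="module")
def tiny_setup():
    vocab = build_vocabulary(CORPUS)
    records = [
        CageRecord(i % 2, s, i % 2, "collapsed" if i < 3 else "not_collapsed")
        for i, s in enumerate(CORPUS)
    ]
    batch = encode_records(records, vocab)
    config = ModelConfig(vocab_size=len(vocab), n_bb1=2, n_reactions=2,
                         max_len=vocab.max_len, latent_dim=8, encoder_hidden=16,
                         decoder_hidden=16, embedding_dim=8, categorical_hidden=8,
                         predictor_hidden=8)
    return vocab, batch, config


class TestKL:
    def test_posterior_equal_to_prior_gives_zero(self):
        mean = Tensor(np.zeros((4, 8)))
        log_var = Tensor(np.zeros((4, 8)))
        assert kl_divergence(mean, log_var).data == pytest.approx(0.0)

    def test_one_dimensional_closed_form(self):
        # KL(N(1,1) || N(0,1)) = 0.5 (mu^2 + sigma^2 - 1 - log sigma^2) = 0.5
        assert kl_divergence(Tensor([1.0]), Tensor([0.0])).data == pytest.approx(0.5)

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(0)
        mu = np.array([0.7, -0.3])
        log_var = np.array([0.4, -0.8])
        sigma = np.exp(log_var / 2)
        closed = float(kl_divergence(Tensor(mu), Tensor(log_var)).data)
        # E_q[log q(z) - log p(z)] over 1e6 draws
        z = mu + sigma * rng.standard_normal((1_000_000, 2))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + np.log(2 * np.pi) + log_var).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc = float((log_q - log_p).mean())
        assert closed == pytest.approx(mc, rel=0.01)

    def test_nonnegative_for_random_posteriors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mean = Tensor(rng.standard_normal((3, 5)))
            log_var = Tensor(rng.standard_normal((3, 5)))
            assert kl_divergence(mean, log_var).data >= 0.0


class TestReparameterize:
    def test_zero_variance_limit_returns_mean(self):
        mean = Tensor(np.array([[1.0, -2.0]]))
        log_var = Tensor(np.full((1, 2), -1e6))
        z = CageVAENetwork.reparameterize(mean, log_var, np.random.default_rng(0))
        np.testing.assert_allclose(z.data, mean.data, atol=1e-12)

    def test_sample_mean_converges_to_posterior_mean(self):
        mu = np.array([[0.5, -1.5]])
        mean = Tensor(np.repeat(mu, 100_000, axis=0))
        log_var = Tensor(np.zeros((100_000, 2)))
        z = CageVAENetwork.reparameterize(mean, log_var, np.random.default_rng(1))
        se = 1.0 / np.sqrt(100_000)
        assert np.abs(z.data.mean(axis=0) - mu[0]).max() < 3 * se

    def test_fixed_seed_reproducible(self):
        mean = Tensor(np.zeros((4, 3)))
        log_var = Tensor(np.zeros((4, 3)))
        z1 = CageVAENetwork.reparameterize(mean, log_var, np.random.default_rng(7))
        z2 = CageVAENetwork.reparameterize(mean, log_var, np.random.default_rng(7))
        np.testing.assert_array_equal(z1.data, z2.data)


class TestEncodeDecode:
    def test_encode_deterministic_without_dropout(self, tiny_setup):
        _, batch, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        m1, lv1 = net.encode(batch)
        m2, lv2 = net.encode(batch)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(lv1.data, lv2.data)

    def test_posterior_dimensions(self, tiny_setup):
        _, batch, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        mean, log_var = net.encode(batch)
        assert mean.data.shape == (len(batch), config.latent_dim)
        assert log_var.data.shape == (len(batch), config.latent_dim)

    def test_greedy_decode_deterministic(self, tiny_setup):
        _, _, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        z = np.random.default_rng(2).standard_normal((3, config.latent_dim))
        np.testing.assert_array_equal(net.decode_bb2(z), net.decode_bb2(z))

    def test_multinomial_decode_seeded(self, tiny_setup):
        _, _, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        z = np.zeros((2, config.latent_dim))
        s1 = net.decode_bb2(z, mode="multinomial", rng=np.random.default_rng(3))
        s2 = net.decode_bb2(z, mode="multinomial", rng=np.random.default_rng(3))
        np.testing.assert_array_equal(s1, s2)

    def test_multinomial_requires_rng(self, tiny_setup):
        _, _, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        with pytest.raises(ValueError, match="rng"):
            net.decode_bb2(np.zeros((1, config.latent_dim)), mode="multinomial")

    def test_categorical_head_shapes_and_normalisation(self, tiny_setup):
        _, _, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        z = Tensor(np.random.default_rng(4).standard_normal((5, config.latent_dim)))
        bb1_logits, rxn_logits = net.decode_bb1_reaction(z)
        assert bb1_logits.data.shape == (5, config.n_bb1)
        assert rxn_logits.data.shape == (5, config.n_reactions)
        p = np.exp(bb1_logits.log_softmax(axis=-1).data)
        np.testing.assert_allclose(p.sum(axis=-1), np.ones(5), atol=1e-12)

    def test_persistence_probability_in_unit_interval(self, tiny_setup):
        _, _, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        z = np.random.default_rng(5).standard_normal((50, config.latent_dim)) * 10
        p = net.predict_persistence(z)
        assert ((p >= 0.0) & (p <= 1.0)).all()


class TestLoss:
    def test_all_unlabeled_batch_has_zero_predictive_loss(self, tiny_setup):
        vocab, batch, config = tiny_setup
        unlabeled = EncodedBatch(batch.tokens, batch.bb1, batch.reaction,
                                 np.zeros(len(batch)), np.zeros(len(batch), bool))
        net = CageVAENetwork(config, rng_seed=0)
        _, bd = net.compute_loss(unlabeled, LossWeights())
        assert bd.pred == 0.0

    def test_semi_supervision_mask_invariance(self, tiny_setup):
        """Adding unlabeled records must not change the predictive term
        computed on a fixed labeled subset."""
        vocab, batch, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        _, bd_small = net.compute_loss(batch.subset(np.arange(3)), LossWeights())
        grown = EncodedBatch(batch.tokens, batch.bb1, batch.reaction, batch.y,
                             np.array([True] * 3 + [False] * (len(batch) - 3)))
        _, bd_grown = net.compute_loss(grown, LossWeights())
        labeled_small = EncodedBatch(
            batch.tokens[:3], batch.bb1[:3], batch.reaction[:3], batch.y[:3],
            np.array([True] * 3))
        _, bd_ref = net.compute_loss(labeled_small, LossWeights())
        assert bd_grown.pred == pytest.approx(bd_ref.pred, rel=1e-12)

    def test_total_is_weighted_sum(self, tiny_setup):
        _, batch, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        w = LossWeights(beta=0.01, gamma=0.5, w_bb2=2.0, w_bb1rxn=0.25)
        _, bd = net.compute_loss(batch, w)
        expected = (2.0 * bd.recon_bb2 + 0.25 * bd.recon_bb1rxn
                    + 0.01 * bd.kl + 0.5 * bd.pred)
        assert bd.total == pytest.approx(expected, rel=1e-12)

    def test_autoencoder_limit(self, tiny_setup):
        """beta = gamma = 0 reduces the objective to pure reconstruction."""
        _, batch, config = tiny_setup
        net = CageVAENetwork(config, rng_seed=0)
        _, bd = net.compute_loss(batch, LossWeights(beta=0.0, gamma=0.0))
        assert bd.total == pytest.approx(bd.recon_bb2 + bd.recon_bb1rxn, rel=1e-12)

    def test_hand_computed_cross_entropy(self):
        """Two-token toy sequence against a by-hand softmax cross-entropy."""
        vocab = build_vocabulary(["[Lr]C[Lr]"], max_len=4)
        config = ModelConfig(vocab_size=len(vocab), n_bb1=1, n_reactions=1,
                             max_len=4, latent_dim=2, encoder_hidden=4,
                             decoder_hidden=4, embedding_dim=2,
                             categorical_hidden=2, predictor_hidden=2)
        net = CageVAENetwork(config, rng_seed=0)
        # sequence [sos] C [eos] [pad]; targets C, [eos], [pad](masked)
        c_idx = vocab.token_to_index["C"]
        tokens = np.array([[vocab.sos, c_idx, vocab.eos, vocab.pad]])
        batch = EncodedBatch(tokens, np.array([0]), np.array([0]),
                             np.array([0.0]), np.array([False]))
        mean, log_var = net.encode(batch)
        logits = net.decode_bb2_teacher_forced(mean, tokens).data[0]
        shifted = logits - logits.max(axis=-1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        expected = -(logp[0, c_idx] + logp[1, vocab.eos]) / 2  # pad masked out
        _, bd = net.compute_loss(batch, LossWeights(beta=0.0, gamma=0.0))
        assert bd.recon_bb2 == pytest.approx(float(expected), rel=1e-10)

    def test_perfect_logits_drive_reconstruction_to_zero(self):
        """Cross-entropy vanishes as logits approach one-hot certainty."""
        from cagevae._autodiff import Tensor as T
        logits = np.full((1, 2, 3), -1e3)
        logits[0, 0, 1] = 1e3
        logits[0, 1, 2] = 1e3
        t = T(logits)
        logp = t.log_softmax(axis=-1).data
        assert -(logp[0, 0, 1] + logp[0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_overfit_four_records_loss_decreases(self, tiny_setup):
        """Total loss falls monotonically-ish over 200 steps on a 4-record
        batch (final well below half the initial)."""
        _, batch, config = tiny_setup
        small = batch.subset(np.arange(4))
        net = CageVAENetwork(config, rng_seed=1)
        opt = Adam(net.parameters(), lr=0.01)
        rng = np.random.default_rng(2)
        w = LossWeights(beta=0.0025)
        losses = []
        for _ in range(200):
            net.zero_grad()
            total, bd = net.compute_loss(small, w, rng=rng)
            total.backward()
            opt.step()
            losses.append(bd.total)
        assert losses[-1] < 0.5 * losses[0]

    def test_trained_toy_model_reconstructs_and_separates(self, trained):
        """On the session toy model: greedy decode of posterior means
        recovers most training cages and the predictor separates labels."""
        rec = trained.reconstruction_accuracy()
        assert rec["bb1_accuracy"] > 0.9
        assert rec["reaction_accuracy"] > 0.9
        assert rec["bb2_exact"] > 0.5
        assert trained.evaluate_predictor(
            [r for r in trained.train_records if r.label != "unlabeled"]) > 0.9
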