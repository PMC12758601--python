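"""Vocabulary learning: quantization, loss contracts, training, baselines."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scglang import (
    Codebook,
    TrainConfig,
    codebook_utilization,
    gen_fragment_mixture,
    quantize,
    train_kmeans_vocab,
    train_vqvae,
    vq_losses,
)
from scglang.constants import N_FEATURES
from scglang.features import Standardization
from scglang.vocabulary import VQVAE, quantize_batch


class TestQuantize:
    def test_nearest_by_inspection(self):
        cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
        r = quantize(np.array([0.1, 0.1]), cb)
        assert r.token == 0
        np.testing.assert_array_equal(r.z_q, [0.0, 0.0])
        assert r.distance == pytest.approx(np.hypot(0.1, 0.1))

    def test_equidistant_tie_breaks_to_lowest_index(self):
        cb = Codebook(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert quantize(np.array([0.5, 0.5]), cb).token == 0

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            K = int(rng.integers(2, 6))
            d = int(rng.integers(1, 5))
            cb = Codebook(rng.normal(size=(K, d)))
            z = rng.normal(size=d)
            # independent oracle: full scan with explicit first-min tie-break
            dists = [float(np.linalg.norm(z - row)) for row in cb.vectors]
            best = min(range(K), key=lambda j: (dists[j], j))
            r = quantize(z, cb)
            assert r.token == best
            assert r.distance == pytest.approx(dists[best])

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(12)
        cb = Codebook(rng.normal(size=(7, 3)))
        zs = rng.normal(size=(40, 3))
        batch = quantize_batch(zs, cb)
        assert [quantize(z, cb).token for z in zs] == batch.tolist()

    def test_shape_mismatch_raises(self):
        cb = Codebook(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            quantize(np.zeros(5), cb)


class TestVqLosses:
    def test_identical_distributions_zero_recons(self):
        x = np.random.default_rng(0).normal(size=(4, 74))
        lb = vq_losses(x, x.copy(), np.zeros((4, 2)), np.zeros((4, 2)))
        assert lb.recons == pytest.approx(0.0, abs=1e-12)
        assert lb.codebook == 0.0 and lb.commit == 0.0

    def test_pythagorean_example(self):
        lb = vq_losses(np.zeros((1, 74)), np.zeros((1, 74)),
                       z_e=np.array([[0.0, 0.0]]), z_q=np.array([[3.0, 4.0]]),
                       beta=0.25)
        assert lb.codebook == pytest.approx(25.0)
        assert lb.commit == pytest.approx(25.0)
        assert lb.total == pytest.approx(lb.recons + 25.0 + 6.25)

    def test_total_decomposition_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=(8, 74))
            x_hat = rng.normal(size=(8, 74))
            z_e = rng.normal(size=(8, 16))
            z_q = rng.normal(size=(8, 16))
            beta = float(rng.uniform(0, 1))
            lb = vq_losses(x, x_hat, z_e, z_q, beta)
            assert lb.total == pytest.approx(
                lb.recons + lb.codebook + beta * lb.commit, abs=1e-9)
            assert lb.recons >= -1e-9

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            vq_losses(np.zeros((1, 74)), np.zeros((1, 74)),
                      np.zeros((1, 2)), np.zeros((1, 2)), beta=-0.1)


class TestGradientRouting:
    """Stop-gradient contracts of the three loss terms on the live graph."""

    @pytest.fixture()
    def model_and_batch(self):
        cfg = TrainConfig(K=8, d=6, hidden=8, epochs=1, seed=0,
                          encoder_kind="mlp", recon_loss="mse",
                          warmup_epochs=0)
        model = VQVAE(cfg)
        x = np.random.default_rng(1).normal(size=(16, N_FEATURES))
        return model, x

    def test_codebook_term_updates_only_codebook(self, model_and_batch):
        model, x = model_and_batch
        terms = model.loss_graph(x)
        terms["codebook"].backward()
        assert model.codes.grad is not None and np.any(model.codes.grad)
        for p in model.encoder.params() + model.decoder.params():
            assert p.grad is None or not np.any(p.grad)

    def test_commit_term_updates_only_encoder(self, model_and_batch):
        model, x = model_and_batch
        terms = model.loss_graph(x)
        terms["commit"].backward()
        assert model.codes.grad is None or not np.any(model.codes.grad)
        assert any(p.grad is not None and np.any(p.grad)
                   for p in model.encoder.params())
        for p in model.decoder.params():
            assert p.grad is None or not np.any(p.grad)

    def test_recons_reaches_decoder_and_encoder_not_codebook(
            self, model_and_batch):
        model, x = model_and_batch
        terms = model.loss_graph(x)
        terms["recons"].backward()
        assert any(p.grad is not None and np.any(p.grad)
                   for p in model.decoder.params())
        # straight-through: encoder receives the decoder-input gradient
        assert any(p.grad is not None and np.any(p.grad)
                   for p in model.encoder.params())
        assert model.codes.grad is None or not np.any(model.codes.grad)

    def test_total_matches_sum_of_terms(self, model_and_batch):
        model, x = model_and_batch
        terms = model.loss_graph(x)
        total = float(terms["total"].data)
        parts = (float(terms["recons"].data) + float(terms["codebook"].data)
                 + model.config.beta * float(terms["commit"].data))
        assert total == pytest.approx(parts, abs=1e-9)


class TestEncoders:
    @pytest.mark.parametrize("kind", ["attention", "mlp"])
    def test_encode_shape_and_determinism(self, kind):
        cfg = TrainConfig(K=4, d=10, hidden=8, attention_heads=2, seed=3,
                          encoder_kind=kind)
        model = VQVAE(cfg)
        x = np.random.default_rng(4).normal(size=(5, N_FEATURES))
        z1, z2 = model.encode(x), model.encode(x)
        assert z1.shape == (5, 10)
        np.testing.assert_array_equal(z1, z2)
        single = model.encode(x[0])
        # single-row and batched BLAS paths may differ in the last ulp
        np.testing.assert_allclose(single, z1[0], rtol=1e-12)

    def test_wrong_input_length_raises(self):
        model = VQVAE(TrainConfig(K=4, d=4, hidden=8, seed=0))
        with pytest.raises(ValueError):
            model.encode(np.zeros(10))


class TestUtilization:
    @pytest.mark.parametrize("tokens,K,expected", [
        (list(range(8)), 8, 1.0),
        ([3] * 10, 8, 1 / 8),
        ([0, 0, 2], 4, 0.5),
    ])
    def test_examples(self, tokens, K, expected):
        assert codebook_utilization(tokens, K) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            codebook_utilization([0, 9], 4)


class TestTrainVqvae:
    def test_loss_decreases_and_is_reproducible(self, mixture16):
        X, _ = mixture16
        cfg = TrainConfig(K=16, epochs=6, seed=9, recon_loss="mse",
                          encoder_kind="mlp")
        cb1, _, log = train_vqvae(X[:1000], cfg)
        assert log.epochs[-1]["total"] <= log.epochs[0]["total"]
        cb2, _, _ = train_vqvae(X[:1000], cfg)
        np.testing.assert_array_equal(cb1.vectors, cb2.vectors)

    def test_recovers_generator_clusters(self, mixture16):
        X, labels = mixture16
        cfg = TrainConfig(K=16, epochs=20, seed=0, recon_loss="mse")
        cb, model, _ = train_vqvae(X, cfg)
        tokens = model.tokenize_features(
            cb.feature_standardization.apply(X))
        assert adjusted_rand_score(labels, tokens) >= 0.9

    def test_nonfinite_loss_aborts(self, mixture16):
        X, _ = mixture16
        cfg = TrainConfig(K=8, epochs=2, seed=0, encoder_kind="mlp",
                          recon_loss="mse")
        bad = X[:256].copy()
        bad[3, 7] = np.nan
        with pytest.raises(FloatingPointError):
            train_vqvae(bad, cfg)


class TestKmeansVocab:
    def test_two_far_clouds_recover_means(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.1, (50, N_FEATURES))
        b = rng.normal(5, 0.1, (50, N_FEATURES))
        X = np.vstack([a, b])
        cb = train_kmeans_vocab(X, K=2, seed=0)
        z = cb.feature_standardization.apply(X)
        cents = sorted(cb.vectors.tolist(), key=lambda r: r[0])
        want = sorted([z[:50].mean(axis=0), z[50:].mean(axis=0)],
                      key=lambda r: r[0])
        np.testing.assert_allclose(cents, want, atol=0.05)

    def test_k_equals_m_gives_one_token_each(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, N_FEATURES))
        cb = train_kmeans_vocab(X, K=8, seed=1)
        tokens = quantize_batch(cb.feature_standardization.apply(X), cb)
        assert len(set(tokens.tolist())) == 8

    def test_m_below_k_raises(self):
        with pytest.raises(ValueError):
            train_kmeans_vocab(np.zeros((3, N_FEATURES)), K=5, seed=0)

    def test_same_seed_same_centroids(self, mixture16):
        X, _ = mixture16
        cb1 = train_kmeans_vocab(X[:500], K=8, seed=3)
        cb2 = train_kmeans_vocab(X[:500], K=8, seed=3)
        np.testing.assert_array_equal(cb1.vectors, cb2.vectors)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"beta": -0.5}, {"encoder_kind": "cnn"}, {"recon_loss": "l1"},
        {"K": 0}, {"epochs": 0},
    ])
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)
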