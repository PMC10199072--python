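"""LSTM language model: gradients, losses, determinism, sampling."""

import numpy as np
import pytest

from npforge import langmodel as lm
from npforge import tokenizer as tk


TINY = dict(n_layers=2, hidden_dim=8, embedding_dim=6, batch_size=4,
            dtype="float64", seed=3)


@pytest.fixture(scope="module")
def tiny_setup():
    vocab = tk.build_vocabulary(["CCO", "c1ccccc1", "CC(N)C(=O)O"])
    cfg = lm.LMConfig(**TINY)
    rng = np.random.default_rng(0)
    params = lm._init_parameters(len(vocab), cfg, rng)
    seqs = [tk.encode(s, vocab) for s in ["CCO", "c1ccccc1", "CC(N)C(=O)O", "CC"]]
    X, Y, mask = lm._make_batch(seqs, vocab.pad_index)
    return cfg, vocab, params, X, Y, mask


class TestGradients:
    def test_analytic_matches_finite_differences(self, tiny_setup):
        cfg, vocab, params, X, Y, mask = tiny_setup
        loss, cache = lm._forward_loss(params, cfg, X, Y, mask, with_cache=True)
        grads = lm._backward(params, cfg, X, Y, mask, cache)
        rng = np.random.default_rng(1)
        eps = 1e-6
        for k in params:
            flat = params[k].ravel()
            for i in rng.choice(flat.size, size=min(15, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = lm._forward_loss(params, cfg, X, Y, mask)
                flat[i] = orig - eps
                lmn = lm._forward_loss(params, cfg, X, Y, mask)
                flat[i] = orig
                num = (lp - lmn) / (2 * eps)
                ana = grads[k].ravel()[i]
                assert abs(num - ana) / max(1e-4, abs(num) + abs(ana)) < 1e-4, k


class TestLoss:
    def test_untrained_loss_close_to_log_vocab(self, tiny_setup):
        cfg, vocab, params, *_ = tiny_setup
        state = lm.LanguageModelState(cfg, params, vocab, np.inf)
        loss = lm.evaluate_loss(state, ["CCO", "CC(N)C(=O)O", "c1ccccc1"])
        assert loss == pytest.approx(np.log(len(vocab)), rel=0.05)

    def test_loss_equals_per_step_probability_walk(self, tiny_setup):
        cfg, vocab, params, *_ = tiny_setup
        state = lm.LanguageModelState(cfg, params, vocab, np.inf)
        corpus = ["CCO", "CC", "c1ccccc1"]
        total, n = 0.0, 0
        for s in corpus:
            seq = tk.encode(s, vocab)
            for t in range(1, len(seq)):
                p = lm.next_token_probabilities(state, seq[:t])
                total -= np.log(p[seq[t]])
                n += 1
        assert lm.evaluate_loss(state, corpus) == pytest.approx(total / n, rel=1e-6)

    def test_per_step_distributions_normalized(self, tiny_setup):
        cfg, vocab, params, *_ = tiny_setup
        state = lm.LanguageModelState(cfg, params, vocab, np.inf)
        seq = tk.encode("CC(N)C(=O)O", vocab)
        for t in range(1, len(seq)):
            p = lm.next_token_probabilities(state, seq[:t])
            assert p.sum() == pytest.approx(1.0, abs=1e-6)
            assert (p >= 0).all()

    def test_empty_corpus_rejected(self, tiny_setup):
        cfg, vocab, params, *_ = tiny_setup
        state = lm.LanguageModelState(cfg, params, vocab, np.inf)
        with pytest.raises(ValueError):
            lm.evaluate_loss(state, [])


class TestTraining:
    def test_training_reduces_validation_loss(self):
        corpus = ["CCO", "CCN", "CCC", "CC=O", "COC"] * 20
        cfg = lm.LMConfig(n_layers=1, hidden_dim=64, embedding_dim=16,
                          batch_size=16, max_epochs=15,
                          eval_every_minibatches=20, seed=2)
        state = lm.train(corpus, corpus[:10], cfg)
        untrained = np.log(len(state.vocab))
        assert state.best_validation_loss < untrained

    def test_best_loss_is_min_of_log(self):
        corpus = ["CCO", "CCN"] * 10
        cfg = lm.LMConfig(n_layers=1, hidden_dim=16, embedding_dim=8,
                          batch_size=8, max_epochs=5,
                          eval_every_minibatches=5, seed=2)
        state = lm.train(corpus, corpus[:4], cfg)
        assert state.best_validation_loss == pytest.approx(
            min(v for _, _, v in state.training_log))

    def test_identical_seed_gives_identical_log(self):
        corpus = ["CCO", "CCN", "COC"] * 8
        cfg = lm.LMConfig(n_layers=1, hidden_dim=16, embedding_dim=8,
                          batch_size=8, max_epochs=3,
                          eval_every_minibatches=5, seed=9)
        log1 = lm.train(corpus, corpus[:6], cfg).training_log
        log2 = lm.train(corpus, corpus[:6], cfg).training_log
        assert log1 == log2

    def test_oov_validation_string_reported_with_line(self):
        with pytest.raises(ValueError, match="line"):
            lm._encode_corpus(["CCO", "CC[Se]C"], tk.build_vocabulary(["CCO"]))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            lm.train([], ["CCO"], lm.LMConfig(**TINY))


@pytest.fixture(scope="module")
def memorized_model():
    cfg = lm.LMConfig(n_layers=1, hidden_dim=32, embedding_dim=16, batch_size=16,
                      max_epochs=400, eval_every_minibatches=50, seed=1)
    return lm.train(["CCO"] * 64, ["CCO"] * 8, cfg)


class TestSampling:
    def test_memorized_string_dominates_samples(self, memorized_model):
        samples = lm.sample(memorized_model, 100, seed=5)
        assert sum(s == "CCO" for s in samples) >= 95

    def test_greedy_limit_is_deterministic_argmax(self, memorized_model):
        samples = lm.sample(memorized_model, 10, seed=6, temperature=0.0)
        assert set(samples) == {"CCO"}

    def test_returns_exactly_n(self, memorized_model):
        assert len(lm.sample(memorized_model, 17, seed=0)) == 17

    def test_n_zero_rejected(self, memorized_model):
        with pytest.raises(ValueError):
            lm.sample(memorized_model, 0, seed=0)

    def test_seed_reproducibility(self, memorized_model):
        a = lm.sample(memorized_model, 20, seed=3)
        b = lm.sample(memorized_model, 20, seed=3)
        assert a == b


class TestCheckpoint:
    def test_round_trip(self, tmp_path, memorized_model):
        lm.save_checkpoint(memorized_model, tmp_path / "w.npz", tmp_path / "w.json")
        loaded = lm.load_checkpoint(tmp_path / "w.npz", tmp_path / "w.json")
        assert loaded.vocab.tokens == memorized_model.vocab.tokens
        assert loaded.best_validation_loss == memorized_model.best_validation_loss
        assert lm.sample(loaded, 5, seed=1) == lm.sample(memorized_model, 5, seed=1)
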