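"""Token-level LSTM language model over SMILES, implemented in NumPy.

The model is a stacked LSTM with a token embedding and a softmax output head,
trained by teacher forcing on next-token prediction with the Adam optimizer
and early stopping on validation loss.  Losses are mean per-token
cross-entropies in nats.  All randomness (initialization, batch shuffling,
sampling) is funneled through seeded NumPy generators, so runs are exactly
reproducible for a fixed seed.

Forward/backward passes are written explicitly (stacked-LSTM BPTT); PAD
positions are masked out of the loss, and because padded outputs carry zero
loss, gradients through post-END states vanish without special casing.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import tokenizer as tk
from .tokenizer import Vocabulary, OutOfVocabularyError

log = logging.getLogger(__name__)


@dataclass
class LMConfig:
    n_layers: int = 3
    hidden_dim: int = 512
    dropout: float = 0.0
    embedding_dim: int = 128
    batch_size: int = 128
    learning_rate: float = 0.001
    optimizer: str = "Adam"
    max_epochs: int = 1000
    patience_minibatches: int = 10_000
    eval_every_minibatches: int = 500
    max_sample_length: int = 250
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if min(self.n_layers, self.hidden_dim, self.embedding_dim,
               self.batch_size, self.max_epochs, self.patience_minibatches,
               self.eval_every_minibatches, self.max_sample_length) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.optimizer != "Adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class LanguageModelState:
    config: LMConfig
    parameters: dict[str, np.ndarray]
    vocab: Vocabulary
    best_validation_loss: float
    training_log: list[tuple[int, float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameters and network math

def _init_parameters(vocab_size: int, cfg: LMConfig, rng: np.random.Generator):
    dt = np.dtype(cfg.dtype)
    H, E = cfg.hidden_dim, cfg.embedding_dim
    params = {"emb": rng.uniform(-0.1, 0.1, (vocab_size, E)).astype(dt)}
    for l in range(cfg.n_layers):
        in_dim = E if l == 0 else H
        scale = 1.0 / np.sqrt(in_dim + H)
        params[f"Wx{l}"] = rng.uniform(-scale, scale, (in_dim, 4 * H)).astype(dt)
        params[f"Wh{l}"] = rng.uniform(-scale, scale, (H, 4 * H)).astype(dt)
        b = np.zeros(4 * H, dtype=dt)
        b[H:2 * H] = 1.0  # forget-gate bias: remember by default
        params[f"b{l}"] = b
    # 1/sqrt(H) output head: small enough that the untrained predictive
    # distribution stays near-uniform (loss ~ ln V), large enough that
    # useful gradient reaches the recurrent layers from the first updates
    params["Wy"] = rng.uniform(-1, 1, (H, vocab_size)).astype(dt) / np.sqrt(H)
    params["by"] = np.zeros(vocab_size, dtype=dt)
    return params


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_step(x, h_prev, c_prev, Wx, Wh, b, H):
    z = x @ Wx + h_prev @ Wh + b
    i = _sigmoid(z[:, :H])
    f = _sigmoid(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = _sigmoid(z[:, 3 * H:])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    return h, c, (x, h_prev, c_prev, i, f, g, o, tc)


def _softmax(logits):
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_loss(params, cfg, X, Y, mask, with_cache=False):
    """Mean masked cross-entropy for inputs X predicting targets Y.

    X, Y: (B, T) int arrays; mask: (B, T) float, 1 where Y is a real token.
    Layers are processed one at a time over the whole sequence so the input
    projections become single large matrix products; only the recurrent
    ``h @ Wh`` term is stepwise.
    """
    B, T = X.shape
    H, L = cfg.hidden_dim, cfg.n_layers
    dt = params["emb"].dtype
    x_seq = params["emb"][X]  # (B, T, in_dim)
    layer_caches = []
    for l in range(L):
        Wx, Wh, b = params[f"Wx{l}"], params[f"Wh{l}"], params[f"b{l}"]
        zx = x_seq @ Wx + b  # (B, T, 4H)
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        hs = np.empty((B, T, H), dtype=dt)
        gates = np.empty((B, T, 4 * H), dtype=dt)  # i, f, g, o post-activation
        tcs = np.empty((B, T, H), dtype=dt)
        c_prevs = np.empty((B, T, H), dtype=dt)
        for t in range(T):
            z = zx[:, t] + h @ Wh
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prevs[:, t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            gates[:, t, :H] = i
            gates[:, t, H:2 * H] = f
            gates[:, t, 2 * H:3 * H] = g
            gates[:, t, 3 * H:] = o
            tcs[:, t] = tc
        layer_caches.append((x_seq, hs, gates, tcs, c_prevs))
        x_seq = hs
    logits = x_seq @ params["Wy"] + params["by"]  # (B, T, V)
    probs = _softmax(logits)
    n_tok = mask.sum()
    picked = np.take_along_axis(probs, Y[:, :, None], axis=2)[:, :, 0]
    loss = float(-(np.log(np.maximum(picked, 1e-30)) * mask).sum() / n_tok)
    if with_cache:
        return loss, (layer_caches, probs, n_tok)
    return loss


def _backward(params, cfg, X, Y, mask, cache):
    layer_caches, probs, n_tok = cache
    B, T = X.shape
    H, L = cfg.hidden_dim, cfg.n_layers
    dt = params["emb"].dtype
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = probs.copy()
    np.put_along_axis(
        dlogits, Y[:, :, None],
        np.take_along_axis(dlogits, Y[:, :, None], axis=2) - 1.0, axis=2)
    dlogits *= (mask / n_tok)[:, :, None].astype(dt)
    h_top = layer_caches[-1][1]
    grads["Wy"] = h_top.reshape(B * T, H).T @ dlogits.reshape(B * T, -1)
    grads["by"] = dlogits.sum(axis=(0, 1))
    dh_seq = dlogits @ params["Wy"].T  # (B, T, H)

    for l in range(L - 1, -1, -1):
        x_seq, hs, gates, tcs, c_prevs = layer_caches[l]
        Wx, Wh = params[f"Wx{l}"], params[f"Wh{l}"]
        dz_seq = np.empty((B, T, 4 * H), dtype=dt)
        dh_next = np.zeros((B, H), dtype=dt)
        dc_next = np.zeros((B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H:2 * H]
            g = gates[:, t, 2 * H:3 * H]
            o = gates[:, t, 3 * H:]
            tc = tcs[:, t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = dz_seq[:, t]
            dz[:, :H] = dc * g * i * (1 - i)
            dz[:, H:2 * H] = dc * c_prevs[:, t] * f * (1 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1 - g * g)
            dz[:, 3 * H:] = do * o * (1 - o)
            dh_next = dz @ Wh.T
            dc_next = dc * f
        h_prev_seq = np.concatenate(
            [np.zeros((B, 1, H), dtype=dt), hs[:, :-1]], axis=1)
        dz_flat = dz_seq.reshape(B * T, 4 * H)
        grads[f"Wx{l}"] = x_seq.reshape(B * T, -1).T @ dz_flat
        grads[f"Wh{l}"] = h_prev_seq.reshape(B * T, H).T @ dz_flat
        grads[f"b{l}"] = dz_flat.sum(0)
        dh_seq = dz_seq @ Wx.T  # becomes d(input) for the layer below
    np.add.at(grads["emb"], X.reshape(-1), dh_seq.reshape(B * T, -1))
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# corpus encoding helpers

def _encode_corpus(corpus, vocab, drop_oov=False):
    """Encoded index lists; OOV strings raise (train) or are skipped (eval)."""
    seqs = []
    n_oov = 0
    for lineno, s in enumerate(corpus, start=1):
        try:
            seqs.append(tk.encode(s, vocab))
        except OutOfVocabularyError as e:
            if not drop_oov:
                raise ValueError(
                    f"out-of-vocabulary token {e.token!r} at line {lineno}") from None
            n_oov += 1
    if n_oov:
        log.info("excluded %d out-of-vocabulary string(s) from loss", n_oov)
    return seqs


def _bucketed_batches(seqs, batch_size, rng):
    """Shuffled minibatches with pooled length bucketing.

    Indices are shuffled, partitioned into pools of 16 batches, sorted by
    length within each pool, cut into batches and the batch order shuffled —
    retaining stochasticity while keeping padding waste low.
    """
    order = rng.permutation(len(seqs))
    pool_size = 16 * batch_size
    batches = []
    for p0 in range(0, len(order), pool_size):
        pool = sorted(order[p0:p0 + pool_size], key=lambda i: len(seqs[i]))
        for b0 in range(0, len(pool), batch_size):
            batches.append([seqs[i] for i in pool[b0:b0 + batch_size]])
    rng.shuffle(batches)
    return batches


def _make_batch(seqs, pad_index):
    """Pad to batch max length; returns inputs, targets and target mask."""
    T = max(len(s) for s in seqs)
    arr = np.full((len(seqs), T), pad_index, dtype=np.int64)
    for r, s in enumerate(seqs):
        arr[r, :len(s)] = s
    X, Y = arr[:, :-1], arr[:, 1:]
    mask = (Y != pad_index).astype(np.float64)
    return X, Y, mask


# ---------------------------------------------------------------------------
# public API

def train(train_corpus: list[str], validation_corpus: list[str],
          config: LMConfig) -> LanguageModelState:
    """Fit the LSTM by teacher forcing; return parameters at best val loss.

    Validation loss is evaluated every ``eval_every_minibatches``; training
    stops at ``max_epochs`` or once validation loss has not improved for
    ``patience_minibatches`` minibatches.  Fully seeded and deterministic.
    """
    if not train_corpus or not validation_corpus:
        raise ValueError("empty corpus")
    vocab = tk.build_vocabulary(list(train_corpus) + list(validation_corpus))
    train_seqs = _encode_corpus(train_corpus, vocab)
    val_seqs = _encode_corpus(validation_corpus, vocab)

    rng = np.random.default_rng(config.seed)
    params = _init_parameters(len(vocab), config, rng)
    opt = _Adam(params, config.learning_rate)

    best_loss = np.inf
    best_params = copy.deepcopy(params)
    best_at = 0
    training_log: list[tuple[int, float, float]] = []
    minibatch = 0
    running, n_running = 0.0, 0
    stop = False

    def _evaluate_val():
        return _loss_over(params, config, val_seqs, vocab)

    for _epoch in range(config.max_epochs):
        for batch in _bucketed_batches(train_seqs, config.batch_size, rng):
            X, Y, mask = _make_batch(batch, vocab.pad_index)
            loss, cache = _forward_loss(params, config, X, Y, mask, with_cache=True)
            grads = _backward(params, config, X, Y, mask, cache)
            opt.step(params, grads)
            minibatch += 1
            running += loss
            n_running += 1
            if minibatch % config.eval_every_minibatches == 0:
                val_loss = _evaluate_val()
                training_log.append((minibatch, running / n_running, val_loss))
                running, n_running = 0.0, 0
                if val_loss < best_loss:
                    best_loss, best_at = val_loss, minibatch
                    best_params = copy.deepcopy(params)
                if minibatch - best_at >= config.patience_minibatches:
                    stop = True
                    break
        if stop:
            break
    # final evaluation so short runs always log at least once
    if not training_log or training_log[-1][0] != minibatch:
        val_loss = _evaluate_val()
        training_log.append((minibatch, running / max(n_running, 1), val_loss))
        if val_loss < best_loss:
            best_loss, best_params = val_loss, copy.deepcopy(params)
    return LanguageModelState(config, best_params, vocab, float(best_loss), training_log)


def _loss_over(params, cfg, seqs, vocab, batch_size=512):
    total, n_tok = 0.0, 0.0
    for start in range(0, len(seqs), batch_size):
        X, Y, mask = _make_batch(seqs[start:start + batch_size], vocab.pad_index)
        loss = _forward_loss(params, cfg, X, Y, mask)
        total += loss * mask.sum()
        n_tok += mask.sum()
    return float(total / n_tok)


def evaluate_loss(state: LanguageModelState, corpus: list[str]) -> float:
    """Mean per-token cross-entropy (nats/token) of the corpus under the model."""
    if not corpus:
        raise ValueError("empty corpus")
    seqs = _encode_corpus(corpus, state.vocab, drop_oov=True)
    if not seqs:
        raise ValueError("no encodable strings in corpus")
    return _loss_over(state.parameters, state.config, seqs, state.vocab)


def next_token_probabilities(state: LanguageModelState, prefix: list[int]) -> np.ndarray:
    """Distribution over the next token given an index prefix (for oracles)."""
    cfg, params = state.config, state.parameters
    H, L = cfg.hidden_dim, cfg.n_layers
    dt = params["emb"].dtype
    h = [np.zeros((1, H), dtype=dt) for _ in range(L)]
    c = [np.zeros((1, H), dtype=dt) for _ in range(L)]
    for idx in prefix:
        x = params["emb"][np.array([idx])]
        for l in range(L):
            h[l], c[l], _ = _lstm_step(
                x, h[l], c[l], params[f"Wx{l}"], params[f"Wh{l}"], params[f"b{l}"], H)
            x = h[l]
    return _softmax(x @ params["Wy"] + params["by"])[0]


def sample(state: LanguageModelState, n: int, seed: int,
           temperature: float = 1.0) -> list[str]:
    """Draw ``n`` SMILES strings autoregressively from the model.

    Each string is generated from START by multinomial draws over the
    temperature-scaled next-token distribution until END or
    ``max_sample_length`` tokens.  Validity is not guaranteed.
    ``temperature=0`` is the greedy (argmax) limit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg, params, vocab = state.config, state.parameters, state.vocab
    H, L = cfg.hidden_dim, cfg.n_layers
    dt = params["emb"].dtype
    rng = np.random.default_rng(seed)
    out: list[str] = []
    chunk = 4096
    for start in range(0, n, chunk):
        B = min(chunk, n - start)
        h = [np.zeros((B, H), dtype=dt) for _ in range(L)]
        c = [np.zeros((B, H), dtype=dt) for _ in range(L)]
        tokens = np.full(B, vocab.start_index, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(B)]
        for _step in range(cfg.max_sample_length):
            x = params["emb"][tokens]
            for l in range(L):
                h[l], c[l], _ = _lstm_step(
                    x, h[l], c[l], params[f"Wx{l}"], params[f"Wh{l}"], params[f"b{l}"], H)
                x = h[l]
            logits = (x @ params["Wy"] + params["by"]).astype(np.float64)
            if temperature <= 0.0:
                nxt = logits.argmax(axis=1)
            else:
                p = _softmax(logits / temperature)
                u = rng.random((B, 1))
                nxt = (p.cumsum(axis=1) < u).sum(axis=1)
            nxt = np.where(done, vocab.pad_index, nxt)
            for r in range(B):
                if not done[r]:
                    if nxt[r] == vocab.end_index:
                        done[r] = True
                    elif nxt[r] != vocab.pad_index:
                        seqs[r].append(int(nxt[r]))
            tokens = nxt
            if done.all():
                break
        out.extend(tk.decode(s, vocab) for s in seqs)
    return out


# ---------------------------------------------------------------------------
# checkpointing: one binary weights file + a JSON sidecar

def save_checkpoint(state: LanguageModelState, weights_path, sidecar_path) -> None:
    np.savez(weights_path, **state.parameters)
    sidecar = {
        "config": asdict(state.config),
        "vocab": list(state.vocab.tokens),
        "best_validation_loss": state.best_validation_loss,
        "training_log": state.training_log,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh)


def load_checkpoint(weights_path, sidecar_path) -> LanguageModelState:
    with open(sidecar_path, encoding="utf-8") as fh:
        sidecar = json.load(fh)
    with np.load(weights_path) as npz:
        params = {k: npz[k] for k in npz.files}
    return LanguageModelState(
        config=LMConfig(**sidecar["config"]),
        parameters=params,
        vocab=Vocabulary(tuple(sidecar["vocab"])),
        best_validation_loss=sidecar["best_validation_loss"],
        training_log=[tuple(e) for e in sidecar["training_log"]],
    )
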