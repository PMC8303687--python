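"""Numpy implementation of the dual-branch LSTM descriptor classifier.

The network has two inputs — the 2n-step context-window sequence and the
length-1 target-word sequence — each processed by its own uni-directional
LSTM (256 units by default) followed by a dense layer (128 units). The two
branch outputs are concatenated and passed through a series of decreasing
dense layers ending in a 2-unit softmax that scores descriptor vs
non-descriptor. Training minimizes cross entropy over one-hot two-class
targets (identical to binary cross entropy for this output head) with Adam.

Everything — LSTM forward/backward, dense layers, softmax cross entropy and
the Adam update — is implemented here on float32 numpy arrays; gradients are
validated against central finite differences in the test suite. PAD
timesteps are processed as ordinary zero-vector inputs rather than masked,
consistent with PAD being "the zero vector" (no information) rather than a
skipped step.

Gate layout follows the common (input, forget, cell, output) block order;
kernels use Glorot-uniform initialization, recurrent kernels are orthogonal
per gate block, and the forget-gate bias starts at 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMParams", "DualBranchNet", "Adam", "softmax", "one_hot"]

_F32 = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


def _orthogonal_blocks(rng: np.random.Generator, n: int, blocks: int) -> np.ndarray:
    """(n, blocks*n) recurrent kernel: one orthogonal matrix per gate."""
    mats = []
    for _ in range(blocks):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # fix the sign ambiguity for determinism
        mats.append(q.astype(_F32))
    return np.concatenate(mats, axis=1)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=_F32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTMParams:
    """Weights of one uni-directional LSTM: kernel W, recurrent U, bias b."""

    def __init__(self, rng: np.random.Generator, input_dim: int, units: int):
        self.units = units
        self.W = _glorot(rng, input_dim, units * 4, (input_dim, units * 4))
        self.U = _orthogonal_blocks(rng, units, 4)
        b = np.zeros(units * 4, dtype=_F32)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.b = b

    @property
    def n_params(self) -> int:
        return self.W.size + self.U.size + self.b.size


def lstm_forward(p: LSTMParams, x: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the LSTM over ``x`` (B, T, d); return final hidden state (B, u)."""
    B, T, _ = x.shape
    u = p.units
    h = np.zeros((B, u), dtype=_F32)
    c = np.zeros((B, u), dtype=_F32)
    steps = []
    for t in range(T):
        xt = x[:, t, :]
        z = xt @ p.W + h @ p.U + p.b
        i = _sigmoid(z[:, :u])
        f = _sigmoid(z[:, u:2 * u])
        g = np.tanh(z[:, 2 * u:3 * u])
        o = _sigmoid(z[:, 3 * u:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        steps.append((xt, h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
    return h, {"steps": steps}


def lstm_backward(p: LSTMParams, cache: dict, dh_last: np.ndarray) -> dict:
    """Backprop d(loss)/d(final hidden) through time; input grads not needed."""
    u = p.units
    dW = np.zeros_like(p.W)
    dU = np.zeros_like(p.U)
    db = np.zeros_like(p.b)
    dh = dh_last
    dc = np.zeros_like(dh_last)
    for xt, h_prev, c_prev, i, f, g, o, tanh_c in reversed(cache["steps"]):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g * g),
            do * o * (1.0 - o),
        ], axis=1)
        dW += xt.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ p.U.T
        dc = dc * f
    return {"W": dW, "U": dU, "b": db}


class DualBranchNet:
    """The full context-branch + word-branch classifier network.

    Parameters are held in ``self.params`` as a flat name -> array dict so a
    generic optimizer can walk them; layer wiring lives in ``forward``.
    """

    def __init__(self, embedding_dim: int, context_length: int,
                 lstm_units: int = 256, branch_dense_units: int = 128,
                 head_layout: tuple[int, ...] = (64, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.embedding_dim = embedding_dim
        self.context_length = context_length
        self.lstm_units = lstm_units
        self.branch_dense_units = branch_dense_units
        self.head_layout = tuple(head_layout)

        self.ctx_lstm = LSTMParams(rng, embedding_dim, lstm_units)
        self.word_lstm = LSTMParams(rng, embedding_dim, lstm_units)
        self.params: dict[str, np.ndarray] = {
            "ctx_lstm/W": self.ctx_lstm.W, "ctx_lstm/U": self.ctx_lstm.U,
            "ctx_lstm/b": self.ctx_lstm.b,
            "word_lstm/W": self.word_lstm.W, "word_lstm/U": self.word_lstm.U,
            "word_lstm/b": self.word_lstm.b,
        }

        def dense(name: str, n_in: int, n_out: int) -> None:
            self.params[f"{name}/W"] = _glorot(rng, n_in, n_out, (n_in, n_out))
            self.params[f"{name}/b"] = np.zeros(n_out, dtype=_F32)

        dense("ctx_dense", lstm_units, branch_dense_units)
        dense("word_dense", lstm_units, branch_dense_units)
        widths = [2 * branch_dense_units, *self.head_layout]
        for k in range(len(self.head_layout)):
            dense(f"head{k}", widths[k], widths[k + 1])
        dense("out", widths[-1], 2)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())

    def _sync_lstm_views(self) -> None:
        """Re-point LSTMParams at the (possibly reloaded) param arrays."""
        self.ctx_lstm.W = self.params["ctx_lstm/W"]
        self.ctx_lstm.U = self.params["ctx_lstm/U"]
        self.ctx_lstm.b = self.params["ctx_lstm/b"]
        self.word_lstm.W = self.params["word_lstm/W"]
        self.word_lstm.U = self.params["word_lstm/U"]
        self.word_lstm.b = self.params["word_lstm/b"]

    # -- forward / backward ------------------------------------------------

    def forward(self, x_ctx: np.ndarray, x_word: np.ndarray,
                want_cache: bool = False):
        """Return class probabilities (B, 2); optionally keep the cache."""
        self._sync_lstm_views()
        p = self.params
        h_ctx, ctx_cache = lstm_forward(self.ctx_lstm, x_ctx.astype(_F32, copy=False))
        h_word, word_cache = lstm_forward(self.word_lstm, x_word.astype(_F32, copy=False))
        z_ctx = h_ctx @ p["ctx_dense/W"] + p["ctx_dense/b"]
        a_ctx = np.maximum(z_ctx, 0.0)
        z_word = h_word @ p["word_dense/W"] + p["word_dense/b"]
        a_word = np.maximum(z_word, 0.0)
        a = np.concatenate([a_ctx, a_word], axis=1)
        head_inputs = []
        for k in range(len(self.head_layout)):
            head_inputs.append(a)
            a = np.maximum(a @ p[f"head{k}/W"] + p[f"head{k}/b"], 0.0)
        logits = a @ p["out/W"] + p["out/b"]
        probs = softmax(logits)
        if not want_cache:
            return probs, None
        cache = {
            "ctx_cache": ctx_cache, "word_cache": word_cache,
            "h_ctx": h_ctx, "h_word": h_word,
            "a_ctx": a_ctx, "a_word": a_word,
            "head_inputs": head_inputs, "head_out": a, "probs": probs,
        }
        return probs, cache

    def loss_and_grads(self, x_ctx: np.ndarray, x_word: np.ndarray,
                       y_onehot: np.ndarray):
        """Mean cross-entropy loss, probabilities, and parameter gradients."""
        p = self.params
        probs, cache = self.forward(x_ctx, x_word, want_cache=True)
        B = len(y_onehot)
        eps = 1e-12
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / B)
        grads: dict[str, np.ndarray] = {}

        dlogits = (probs - y_onehot) / B
        grads["out/W"] = cache["head_out"].T @ dlogits
        grads["out/b"] = dlogits.sum(axis=0)
        da = dlogits @ p["out/W"].T
        for k in reversed(range(len(self.head_layout))):
            x_in = cache["head_inputs"][k]
            z = x_in @ p[f"head{k}/W"] + p[f"head{k}/b"]
            dz = da * (z > 0)
            grads[f"head{k}/W"] = x_in.T @ dz
            grads[f"head{k}/b"] = dz.sum(axis=0)
            da = dz @ p[f"head{k}/W"].T
        u = self.branch_dense_units
        da_ctx, da_word = da[:, :u], da[:, u:]

        dz_ctx = da_ctx * (cache["a_ctx"] > 0)
        grads["ctx_dense/W"] = cache["h_ctx"].T @ dz_ctx
        grads["ctx_dense/b"] = dz_ctx.sum(axis=0)
        lstm_grads = lstm_backward(self.ctx_lstm, cache["ctx_cache"],
                                   dz_ctx @ p["ctx_dense/W"].T)
        for name, g in lstm_grads.items():
            grads[f"ctx_lstm/{name}"] = g

        dz_word = da_word * (cache["a_word"] > 0)
        grads["word_dense/W"] = cache["h_word"].T @ dz_word
        grads["word_dense/b"] = dz_word.sum(axis=0)
        lstm_grads = lstm_backward(self.word_lstm, cache["word_cache"],
                                   dz_word @ p["word_dense/W"].T)
        for name, g in lstm_grads.items():
            grads[f"word_lstm/{name}"] = g
        return loss, probs, grads


class Adam:
    """Adam optimizer over a flat name -> array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2 ** self.t) / (1 - self.beta1 ** self.t)
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            params[k] -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(params[k].dtype)
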