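"""Minimal NumPy neural-network layer stack.

Implements exactly the layer types the classifiers need — word embedding,
length-preserving 1-D convolution (im2col), max pooling with floor division,
inverted dropout, flatten, dense — plus softmax cross-entropy with optional
per-sample weights and the Adam optimizer.  Forward/backward passes are plain
NumPy; the first dense layer also accepts a scipy.sparse matrix so the
32,768-dimensional graph vectors never densify.

All randomness (initialization, batch shuffling, dropout masks) flows through
an explicit ``numpy.random.Generator``, which makes training runs reproducible
for a fixed seed on a fixed platform.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy import sparse

__all__ = [
    "Embedding",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "MergedNetwork",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter/gradient lists plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, g):
        raise NotImplementedError


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.uniform(-0.05, 0.05, size=(vocab_size, dim))
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x, train=False, rng=None):
        self._x = np.asarray(x, dtype=np.int64)
        return self.W[self._x]

    def backward(self, g):
        self.grads[0][:] = 0.0
        np.add.at(self.grads[0], self._x, g)
        return None  # integer input has no gradient


class Conv1D(Layer):
    """Length-preserving 1-D convolution with ReLU (odd kernel, zero padding)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for symmetric zero padding")
        self.k = kernel_size
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = kernel_size * in_ch
        self.W = _glorot(rng, fan_in, out_ch, (fan_in, out_ch))
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        half = self.k // 2
        xp = np.zeros((B, L + 2 * half, C))
        xp[:, half : half + L] = x
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # cols: (B, L, C, k) -> (B, L, k*C) matching W layout (k, C) flattened
        cols = cols.transpose(0, 1, 3, 2).reshape(B, L, self.k * C)
        z = cols @ self.W + self.b
        self._cols = cols
        self._mask = z > 0
        self._shape = (B, L, C)
        return z * self._mask

    def backward(self, g):
        B, L, C = self._shape
        g = g * self._mask
        gf = g.reshape(-1, self.out_ch)
        self.grads[0][:] = self._cols.reshape(-1, self.k * C).T @ gf
        self.grads[1][:] = gf.sum(axis=0)
        dcols = (g @ self.W.T).reshape(B, L, self.k, C)
        half = self.k // 2
        dxp = np.zeros((B, L + 2 * half, C))
        for t in range(self.k):
            dxp[:, t : t + L] += dcols[:, :, t, :]
        return dxp[:, half : half + L]


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing partial windows are dropped."""

    def __init__(self, pool_size: int):
        super().__init__()
        self.p = pool_size

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        Lp = L // self.p
        xt = x[:, : Lp * self.p].reshape(B, Lp, self.p, C)
        self._argmax = xt.argmax(axis=2)
        self._shape = (B, L, C)
        return xt.max(axis=2)

    def backward(self, g):
        B, L, C = self._shape
        Lp = L // self.p
        dxt = np.zeros((B, Lp, self.p, C))
        bi, li, ci = np.ogrid[:B, :Lp, :C]
        dxt[bi, li, self._argmax, ci] = g
        dx = np.zeros((B, L, C))
        dx[:, : Lp * self.p] = dxt.reshape(B, Lp * self.p, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class L2Normalize(Layer):
    """Fixed row-wise L2 normalization (no trainable parameters).

    Scales each input vector to unit Euclidean norm; keeps sparse inputs
    sparse.  Used at the graph-branch input, where raw accumulated feature
    counts span several orders of magnitude.
    """

    def forward(self, x, train=False, rng=None):
        if sparse.issparse(x):
            norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1))).ravel()
            norms[norms == 0] = 1.0
            self._norms = norms
            return x.multiply(1.0 / norms[:, None]).tocsr()
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._norms = norms
        return x / norms

    def backward(self, g):
        return None  # input layer only; no gradient needed upstream


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; ``activation`` is 'relu' or None (logits)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None):
        super().__init__()
        self.W = _glorot(rng, in_dim, out_dim, (in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._sparse = sparse.issparse(x)
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        self._mask = None
        return z

    def backward(self, g):
        if self._mask is not None:
            g = g * self._mask
        if self._sparse:
            self.grads[0][:] = np.asarray(self._x.T @ g)
        else:
            self.grads[0][:] = self._x.T @ g
        self.grads[1][:] = g.sum(axis=0)
        if self._sparse:
            return None  # no gradient needed upstream of the input
        return g @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    onehot: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and the gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    per_sample = -(onehot * np.log(p + eps)).sum(axis=1)
    if sample_weights is None:
        loss = per_sample.mean()
        dlogits = (p - onehot) / n
    else:
        w = np.asarray(sample_weights, dtype=float)
        loss = (per_sample * w).mean()
        dlogits = (p - onehot) * w[:, None] / n
    return float(loss), dlogits


class Sequential:
    """Plain layer chain ending in a logits layer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, train: bool = False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break
        return g

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        out = []
        n = x.shape[0]
        for i in range(0, n, batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.vstack(out)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[:] = w


class MergedNetwork:
    """Late-integration model: two branches concatenated before one softmax head.

    Input is a tuple ``(x_seq, x_graph)``; each branch ends in its 10-wide
    penultimate representation, concatenated to width 20 and fed to a single
    output layer.
    """

    def __init__(self, seq_branch: Sequential, graph_branch: Sequential, head: Dense):
        self.seq_branch = seq_branch
        self.graph_branch = graph_branch
        self.head = head

    @property
    def params(self):
        return self.seq_branch.params + self.graph_branch.params + self.head.params

    @property
    def grads(self):
        return self.seq_branch.grads + self.graph_branch.grads + self.head.grads

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x, train: bool = False, rng=None):
        xs, xg = x
        a = self.seq_branch.forward(xs, train=train, rng=rng)
        b = self.graph_branch.forward(xg, train=train, rng=rng)
        self._widths = (a.shape[1], b.shape[1])
        return self.head.forward(np.hstack([a, b]), train=train, rng=rng)

    def backward(self, g):
        gc = self.head.backward(g)
        wa, _ = self._widths
        self.seq_branch.backward(gc[:, :wa])
        self.graph_branch.backward(gc[:, wa:])

    def predict_proba(self, x, batch_size: int = 256) -> np.ndarray:
        xs, xg = x
        out = []
        n = xs.shape[0]
        for i in range(0, n, batch_size):
            logits = self.forward(
                (xs[i : i + batch_size], xg[i : i + batch_size]), train=False
            )
            out.append(softmax(logits))
        return np.vstack(out)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[:] = w


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.beta1 * m + (1.0 - self.beta1) * g
            v[:] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clone_network(net):
    """Deep copy of a network (used for best-checkpoint bookkeeping)."""
    return copy.deepcopy(net)
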