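"""Minimal numpy neural-network primitives.

Dense/ReLU/Dropout layers with manual backprop, softmax losses, the optimizer
family used by the hyperparameter grid, and two desk-scale frozen backbones:
a 2-conv-block CNN and a tiny single-encoder-block transformer whose
attention parameters can be fine-tuned. Both emit 1000-wide feature vectors
so any enumerated head architecture plugs in unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Dropout",
    "ReLU",
    "TinyCNNBackbone",
    "TinyViTBackbone",
    "make_optimizer",
    "softmax",
    "softmax_loss",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_loss(logits: np.ndarray, y: np.ndarray, kind: str = "categorical_crossentropy"):
    """Mean loss and gradient w.r.t. logits for one-hot integer targets.

    With one-hot targets the Kullback-Leibler divergence equals the cross
    entropy up to a vanishing entropy term, so both names share the math.
    """
    if kind not in ("categorical_crossentropy", "kullback_leibler_divergence",
                    "sparse_categorical_crossentropy"):
        raise ValueError(f"unknown loss {kind!r}")
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, trainable: bool = True):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.trainable = trainable
        self.dW = self.db = None
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.trainable:
            self.dW = self._x.T @ g
            self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b} if self.trainable else {}

    def grads(self):
        return {"W": self.dW, "b": self.db} if self.trainable else {}


class ReLU:
    trainable = False

    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return {}

    def grads(self):
        return {}


class Dropout:
    trainable = False

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return {}

    def grads(self):
        return {}


# --------------------------------------------------------------------------
# optimizers


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self.state: dict = {}
        self.t = 0

    def step(self, layers) -> None:
        self.t += 1
        for i, layer in enumerate(layers):
            params, grads = layer.params(), layer.grads()
            for name, p in params.items():
                g = grads[name]
                if g is None:
                    continue
                self._update((i, name), p, g)

    def _update(self, key, p, g):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(_Optimizer):
    def __init__(self, lr, momentum: float = 0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, key, p, g):
        v = self.state.get(key, 0.0)
        v = self.momentum * v - self.lr * g
        self.state[key] = v
        p += v


class RMSProp(_Optimizer):
    def __init__(self, lr, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, p, g):
        s = self.state.get(key, 0.0)
        s = self.rho * s + (1 - self.rho) * g * g
        self.state[key] = s
        p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam(_Optimizer):
    def __init__(self, lr, b1=0.9, b2=0.999, eps=1e-8, weight_decay=0.0):
        super().__init__(lr)
        self.b1, self.b2, self.eps, self.wd = b1, b2, eps, weight_decay

    def _update(self, key, p, g):
        m, v = self.state.get(key, (0.0, 0.0))
        m = self.b1 * m + (1 - self.b1) * g
        v = self.b2 * v + (1 - self.b2) * g * g
        self.state[key] = (m, v)
        mh = m / (1 - self.b1**self.t)
        vh = v / (1 - self.b2**self.t)
        if self.wd:
            p -= self.lr * self.wd * p
        p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Adamax(_Optimizer):
    def __init__(self, lr, b1=0.9, b2=0.999, eps=1e-8):
        super().__init__(lr)
        self.b1, self.b2, self.eps = b1, b2, eps

    def _update(self, key, p, g):
        m, u = self.state.get(key, (0.0, 0.0))
        m = self.b1 * m + (1 - self.b1) * g
        u = np.maximum(self.b2 * u, np.abs(g))
        self.state[key] = (m, u)
        p -= self.lr * m / ((1 - self.b1**self.t) * (u + self.eps))


_OPTIMIZERS = {
    "sgd": SGD,
    "adam": Adam,
    "adamw": lambda lr: Adam(lr, weight_decay=0.01),
    "adamax": Adamax,
    "rmsprop": RMSProp,
}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        return _OPTIMIZERS[name.lower()](lr)
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None


# --------------------------------------------------------------------------
# backbones


def _pool_mean(x: np.ndarray, k: int) -> np.ndarray:
    n, h, w = x.shape[:3]
    rest = x.shape[3:]
    return x.reshape(n, h // k, k, w // k, k, *rest).mean(axis=(2, 4))


def _conv3x3(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution on (N,H,W,Cin) with kernel (3,3,Cin,Cout)."""
    n, h, w, _ = x.shape
    pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.zeros((n, h, w, W.shape[3]))
    for dy in range(3):
        for dx in range(3):
            out += pad[:, dy : dy + h, dx : dx + w, :] @ W[dy, dx]
    return out


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None].repeat(3, axis=-1)
    if x.max() > 1.5:
        x = x / 255.0
    side = x.shape[1]
    if side % 56 != 0:
        raise ValueError("backbone expects a side divisible by 56 (e.g. 224)")
    k = side // 56
    return _pool_mean(x, k) if k > 1 else x


class TinyCNNBackbone:
    """Frozen random-filter CNN: 2 conv blocks + pooled statistics, projected
    to a 1000-wide feature vector. Never trainable.
    """

    kind = "cnn"

    def __init__(self, feature_width: int = 1000, seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.feature_width = feature_width
        self.W1 = rng.normal(0.0, 0.5, size=(3, 3, 3, 8))
        self.W2 = rng.normal(0.0, 0.3, size=(3, 3, 8, 16))
        self.proj = rng.normal(0.0, 1.0 / np.sqrt(39), size=(39, feature_width))

    def features(self, images: np.ndarray) -> np.ndarray:
        x = _prep(images)  # (N,56,56,3)
        h1 = np.maximum(_conv3x3(x, self.W1), 0.0)
        h1 = _pool_mean(h1, 2)  # (N,28,28,8)
        h2 = np.maximum(_conv3x3(h1, self.W2), 0.0)
        lum = 0.299 * x[..., 0] + 0.587 * x[..., 1] + 0.114 * x[..., 2]
        stats = np.concatenate(
            [
                h2.mean(axis=(1, 2)),
                h2.std(axis=(1, 2)),
                x.mean(axis=(1, 2)),
                x.std(axis=(1, 2)),
                lum.mean(axis=(1, 2))[:, None],
            ],
            axis=1,
        )
        return stats @ self.proj

    def trainable_layers(self):
        return []

    def trainable_parameter_count(self) -> int:
        return 0


class TinyViTBackbone:
    """Tiny transformer: 8x8 luminance patches, one encoder block (MHSA +
    feed-forward), class token, 1000-wide output projection.

    Everything is frozen except — when enabled — the four attention
    projection matrices, for which manual backprop is implemented.
    """

    kind = "vit"
    n_heads = 2
    dim = 16

    def __init__(self, feature_width: int = 1000, seed: int = 4321):
        rng = np.random.default_rng(seed)
        d = self.dim
        self.feature_width = feature_width
        self.W_embed = rng.normal(0.0, 0.2, size=(64, d))
        self.cls_token = rng.normal(0.0, 0.2, size=(d,))
        self.pos_embed = rng.normal(0.0, 0.2, size=(50, d))
        self.Wq = rng.normal(0.0, 0.3, size=(d, d))
        self.Wk = rng.normal(0.0, 0.3, size=(d, d))
        self.Wv = rng.normal(0.0, 0.3, size=(d, d))
        self.Wo = rng.normal(0.0, 0.3, size=(d, d))
        self.W_ffn1 = rng.normal(0.0, 0.3, size=(d, 2 * d))
        self.W_ffn2 = rng.normal(0.0, 0.3, size=(2 * d, d))
        self.W_out = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, feature_width))
        self.attention_trainable = False
        self._grads: dict[str, np.ndarray] = {}
        self._cache: dict[str, np.ndarray] | None = None

    # -- forward -----------------------------------------------------------

    def _tokens(self, images: np.ndarray) -> np.ndarray:
        x = _prep(images)
        lum = 0.299 * x[..., 0] + 0.587 * x[..., 1] + 0.114 * x[..., 2]  # (N,56,56)
        n = lum.shape[0]
        patches = lum.reshape(n, 7, 8, 7, 8).transpose(0, 1, 3, 2, 4).reshape(n, 49, 64)
        tok = patches @ self.W_embed  # (N,49,d)
        cls = np.broadcast_to(self.cls_token, (n, 1, self.dim))
        return np.concatenate([cls, tok], axis=1) + self.pos_embed  # (N,50,d)

    def _attention(self, X: np.ndarray, cache: dict | None):
        n, t, d = X.shape
        h, dh = self.n_heads, d // self.n_heads
        scale = 1.0 / np.sqrt(dh)

        def split(M):
            return M.reshape(n, t, h, dh).transpose(0, 2, 1, 3)  # (N,h,T,dh)

        Q, K, V = split(X @ self.Wq), split(X @ self.Wk), split(X @ self.Wv)
        S = np.einsum("nhtd,nhsd->nhts", Q, K) * scale
        A = np.exp(S - S.max(axis=-1, keepdims=True))
        A /= A.sum(axis=-1, keepdims=True)
        O = np.einsum("nhts,nhsd->nhtd", A, V)
        Om = O.transpose(0, 2, 1, 3).reshape(n, t, d)
        Y = Om @ self.Wo + X
        if cache is not None:
            cache.update(X_in=X, Q=Q, K=K, V=V, A=A, Om=Om, scale=scale)
        return Y

    def features(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        cache: dict | None = {} if train and self.attention_trainable else None
        X = self._tokens(images)
        Y = self._attention(X, cache)
        H = Y @ self.W_ffn1
        Hr = np.maximum(H, 0.0)
        Z = Hr @ self.W_ffn2 + Y
        cls = Z[:, 0, :]
        if cache is not None:
            cache.update(H_mask=H > 0)
            self._cache = cache
        return cls @ self.W_out

    # -- backward (attention parameters only) ------------------------------

    def backward(self, dfeat: np.ndarray) -> None:
        if self._cache is None:
            raise RuntimeError("no cached forward pass for backward")
        c = self._cache
        n, t, d = c["X_in"].shape
        h, dh = self.n_heads, d // self.n_heads
        dcls = dfeat @ self.W_out.T
        dZ = np.zeros((n, t, d))
        dZ[:, 0, :] = dcls
        dHr = dZ @ self.W_ffn2.T
        dY = dZ + (dHr * c["H_mask"]) @ self.W_ffn1.T
        # attention backward
        dOm = dY @ self.Wo.T
        dWo = np.einsum("ntd,nte->de", c["Om"], dY)
        dO = dOm.reshape(n, t, h, dh).transpose(0, 2, 1, 3)
        A, V = c["A"], c["V"]
        dA = np.einsum("nhtd,nhsd->nhts", dO, V)
        dV = np.einsum("nhts,nhtd->nhsd", A, dO)
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQ = np.einsum("nhts,nhsd->nhtd", dS, c["K"]) * c["scale"]
        dK = np.einsum("nhts,nhtd->nhsd", dS, c["Q"]) * c["scale"]

        def merge(M):
            return M.transpose(0, 2, 1, 3).reshape(n, t, d)

        X = c["X_in"]
        self._grads = {
            "Wq": np.einsum("ntd,nte->de", X, merge(dQ)),
            "Wk": np.einsum("ntd,nte->de", X, merge(dK)),
            "Wv": np.einsum("ntd,nte->de", X, merge(dV)),
            "Wo": dWo,
        }
        self._cache = None

    def trainable_layers(self):
        if not self.attention_trainable:
            return []
        backbone = self

        class _AttnParams:
            trainable = True

            def params(self):
                return {k: getattr(backbone, k) for k in ("Wq", "Wk", "Wv", "Wo")}

            def grads(self):
                return {k: backbone._grads.get(k) for k in ("Wq", "Wk", "Wv", "Wo")}

        return [_AttnParams()]

    def trainable_parameter_count(self) -> int:
        if not self.attention_trainable:
            return 0
        return sum(getattr(self, k).size for k in ("Wq", "Wk", "Wv", "Wo"))
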