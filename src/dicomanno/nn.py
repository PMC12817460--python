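"""A small pure-numpy convolutional network used as the reference backbone.

Architecture: four conv blocks (3x3 conv, ReLU, 2x2 max-pool) with global
average pooling and a single linear head.  GAP + linear is deliberate: it
makes class activation maps exact (the classifier weights linearly score the
final feature maps).  The implementation is desk-scale — it trains in
minutes on one CPU for images of ~64 px — and exposes exactly the surface
the training harness and CAM need: ``forward``/``backward`` for training,
``feature_maps`` and ``class_weights`` for interpretation.

Internally all activations are channels-last (N, H, W, C) float32 so the
im2col patch matrices are contiguous and convolution reduces to one GEMM.
External backbones (e.g. a pretrained ResNet) can replace this class by
providing the same surface.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, 9*C) patch matrix for a 3x3 same-pad convolution."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9, c), dtype=np.float32)
    for di in range(3):
        for dj in range(3):
            cols[:, :, :, di * 3 + dj, :] = xp[:, di : di + h, dj : dj + w, :]
    return cols.reshape(n * h * w, 9 * c)


class _Conv3x3:
    """Same-padded 3x3 convolution; weight taps ordered (di, dj, c_in)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.W = (rng.standard_normal((9 * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        self._shape = x.shape
        self._cols = _im2col(x)
        return (self._cols @ self.W + self.b).reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        n, h, w, c = self._shape
        dflat = dout.reshape(n * h * w, self.c_out)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        if not need_dx:  # first layer: the input gradient is never used
            return None
        # dx = correlation of dout with the spatially flipped kernel (the
        # transposed convolution), expressed as one im2col + one GEMM.
        w_rot = self.W.reshape(3, 3, c, self.c_out)[::-1, ::-1]
        w_rot = np.ascontiguousarray(w_rot.transpose(0, 1, 3, 2)).reshape(9 * self.c_out, c)
        return (_im2col(dout) @ w_rot).reshape(n, h, w, c)


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        win = x.reshape(n, h // 2, 2, w // 2, 2, c)
        self._shape = x.shape
        a = np.maximum(win[:, :, 0, :, 0, :], win[:, :, 0, :, 1, :])
        b = np.maximum(win[:, :, 1, :, 0, :], win[:, :, 1, :, 1, :])
        out = np.maximum(a, b)
        self._win = win
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dwin = np.zeros((n, h // 2, 2, w // 2, 2, c), dtype=np.float32)
        taken = np.zeros(dout.shape, dtype=bool)  # route ties to the first max
        for i in range(2):
            for j in range(2):
                hit = (self._win[:, :, i, :, j, :] == self._out) & ~taken
                dwin[:, :, i, :, j, :] = dout * hit
                taken |= hit
        return dwin.reshape(n, h, w, c)


class ReferenceCNN:
    """4-block CNN with global average pooling and a linear classifier head.

    Parameters
    ----------
    n_classes
        Output dimension (leaf classes).
    in_size
        Input side length; must be divisible by 2 ** len(channels).
    channels
        Feature channels per conv block.
    seed
        Weight-initialization seed (fully determines the initial state).
    """

    def __init__(
        self,
        n_classes: int,
        in_size: int = 64,
        channels: tuple[int, ...] = (8, 16, 32, 64),
        seed: int = 0,
    ):
        if in_size % (2 ** len(channels)) != 0:
            raise ValueError(f"in_size {in_size} not divisible by {2 ** len(channels)}")
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.in_size = in_size
        self.channels = tuple(channels)
        self.blocks = []
        c_prev = 1
        for c in channels:
            self.blocks.append((_Conv3x3(c_prev, c, rng), _ReLU(), _MaxPool2()))
            c_prev = c
        scale = np.sqrt(1.0 / c_prev)
        self.W_head = (rng.standard_normal((c_prev, n_classes)) * scale).astype(np.float32)
        self.b_head = np.zeros(n_classes, dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, H, W) images -> (N, n_classes) logits."""
        h = np.asarray(x, dtype=np.float32)[:, :, :, None]
        for conv, relu, pool in self.blocks:
            h = pool.forward(relu.forward(conv.forward(h)))
        self._maps = h  # final feature maps, (N, h', w', C)
        self._gap = h.mean(axis=(1, 2))
        return self._gap @ self.W_head + self.b_head

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from dLoss/dlogits."""
        dlogits = np.asarray(dlogits, dtype=np.float32)
        self.dW_head = self._gap.T @ dlogits
        self.db_head = dlogits.sum(axis=0)
        dgap = dlogits @ self.W_head.T
        n, hh, ww, c = self._maps.shape
        dh = np.broadcast_to(dgap[:, None, None, :], (n, hh, ww, c)) / (hh * ww)
        dh = np.ascontiguousarray(dh)
        for i, (conv, relu, pool) in reversed(list(enumerate(self.blocks))):
            dh = conv.backward(relu.backward(pool.backward(dh)), need_dx=i > 0)

    # -- interpretation surface --------------------------------------------

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Final conv feature maps (N, C, h', w') for CAM."""
        self.forward(x)
        return self._maps.transpose(0, 3, 1, 2)

    @property
    def class_weights(self) -> np.ndarray:
        """Linear-head weights (C_features, n_classes)."""
        return self.W_head

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate (GAP) feature vectors, used for content-based retrieval."""
        self.forward(x)
        return self._gap.copy()

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, (conv, _, _) in enumerate(self.blocks):
            out += [(f"conv{i}.W", conv.W), (f"conv{i}.b", conv.b)]
        out += [("head.W", self.W_head), ("head.b", self.b_head)]
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for conv, _, _ in self.blocks:
            out += [conv.dW, conv.db]
        out += [self.dW_head, self.db_head]
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr in self.parameters()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, arr in self.parameters():
            arr[...] = state[name]


class Adam:
    """Adam optimizer over a model's parameter list."""

    def __init__(self, model: ReferenceCNN, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p in model.parameters()]
        self.v = [np.zeros_like(p) for _, p in model.parameters()]

    def step(self) -> None:
        self.t += 1
        grads = self.model.gradients()
        for (name, p), g, m, v in zip(self.model.parameters(), grads, self.m, self.v):
            g = g.astype(np.float32)
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(logits: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-logits))
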