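"""A small convolutional network, implemented in NumPy.

Architecture (``small_cnn``): three 3x3 convolution blocks (conv -> ReLU ->
2x2 average pool) with channel widths 8/16/32, global average pooling and a
single linear unit with sigmoid output — a deliberately small patch scorer
that trains in seconds on a CPU while exercising the same weak-label /
top-k machinery as a large backbone would.  Forward and backward passes are
written against im2col so convolutions reduce to matrix products; the
optimizer is plain SGD with momentum on binary cross-entropy.

Everything is deterministic: weights come from a seeded generator and no
step consults any global random state.
"""

from __future__ import annotations

import numpy as np

_K = 3  # conv kernel size, padding 1, stride 1


def im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*K*K, H*W) patch matrix for 3x3 same-conv."""
    n, c, h, w = x.shape
    pad = _K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, _K, _K, h, w), dtype=x.dtype)
    for i in range(_K):
        for j in range(_K):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * _K * _K, h * w)


def col2im(dcols: np.ndarray, x_shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add of overlapping windows)."""
    n, c, h, w = x_shape
    pad = _K // 2
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, _K, _K, h, w)
    for i in range(_K):
        for j in range(_K):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class SmallCNN:
    """Three conv blocks + global average pooling + linear sigmoid head.

    Parameters
    ----------
    input_px
        Side length of the (square) network input; must be divisible by 8.
    channels
        Widths of the three conv blocks.
    seed
        Seed for He-initialised weights.
    """

    def __init__(self, input_px: int = 32, channels: tuple[int, int, int] = (8, 16, 32), seed: int = 0):
        if input_px % 8 != 0 or input_px < 8:
            raise ValueError("input_px must be a positive multiple of 8")
        self.input_px = int(input_px)
        self.channels = tuple(int(c) for c in channels)
        rng = np.random.default_rng(seed)
        widths = (3,) + self.channels
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = widths[i] * _K * _K
            self.params[f"conv{i}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(widths[i + 1], fan_in))
            self.params[f"conv{i}_b"] = np.zeros(widths[i + 1])
        self.params["fc_W"] = rng.normal(0.0, np.sqrt(1.0 / self.channels[-1]), size=(self.channels[-1],))
        self.params["fc_b"] = np.zeros(1)
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """``x``: (N, 3, S, S) float in [-1, 1].  Returns probabilities (N,)."""
        cache = {"x0": x}
        h = x
        for i in range(3):
            cols = im2col(h)
            z = np.einsum("fk,nkp->nfp", self.params[f"conv{i}_W"], cols) + self.params[f"conv{i}_b"][None, :, None]
            side = h.shape[2]
            z = z.reshape(h.shape[0], -1, side, side)
            a = np.maximum(z, 0.0)
            pooled = _avgpool2(a)
            if want_cache:
                cache[f"cols{i}"] = cols
                cache[f"relu_mask{i}"] = z > 0
                cache[f"in_shape{i}"] = h.shape
            h = pooled
        feat = h.mean(axis=(2, 3))  # global average pool -> (N, C3)
        logit = feat @ self.params["fc_W"] + self.params["fc_b"][0]
        prob = sigmoid(logit)
        if want_cache:
            cache["feat"] = feat
            cache["pool_shape"] = h.shape
            cache["prob"] = prob
            return prob, cache
        return prob

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """BCE loss and parameter gradients for a batch."""
        n = x.shape[0]
        prob, cache = self.forward(x, want_cache=True)
        loss = bce_loss(prob, y)
        grads: dict[str, np.ndarray] = {}
        dlogit = (prob - y) / n  # d(BCE)/d(logit) through the sigmoid
        grads["fc_W"] = cache["feat"].T @ dlogit
        grads["fc_b"] = np.array([dlogit.sum()])
        dfeat = np.outer(dlogit, self.params["fc_W"])
        _, c3, hp, wp = cache["pool_shape"]
        dh = np.broadcast_to(dfeat[:, :, None, None], (n, c3, hp, wp)) / (hp * wp)
        dh = np.ascontiguousarray(dh)
        for i in reversed(range(3)):
            da = _avgpool2_back(dh)
            dz = da * cache[f"relu_mask{i}"]
            dz_flat = dz.reshape(n, dz.shape[1], -1)
            grads[f"conv{i}_W"] = np.einsum("nfp,nkp->fk", dz_flat, cache[f"cols{i}"])
            grads[f"conv{i}_b"] = dz_flat.sum(axis=(0, 2))
            dcols = np.einsum("fk,nfp->nkp", self.params[f"conv{i}_W"], dz_flat)
            dh = col2im(dcols, cache[f"in_shape{i}"])
        return loss, grads

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float, momentum: float = 0.9) -> None:
        for k, g in grads.items():
            self.velocity[k] = momentum * self.velocity[k] - lr * g
            self.params[k] += self.velocity[k]

    # ---- state --------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=np.float64)
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}


def preprocess(images: np.ndarray | list[np.ndarray], input_px: int) -> np.ndarray:
    """uint8 HWC patch images -> (N, 3, input_px, input_px) float64 in [-1, 1]."""
    from .tiling import resize_patch

    arrs = []
    for img in images:
        img = np.asarray(img)
        if img.shape[0] != input_px:
            img = resize_patch(img, input_px)
        arrs.append(img)
    x = np.stack(arrs).astype(np.float64) / 127.5 - 1.0
    return np.transpose(x, (0, 3, 1, 2))
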