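"""Minimal NumPy neural-network layers for the supervised baselines.

Two architectures are built from these layers:

* a feed-forward classifier (two ReLU hidden layers with dropout) for
  low-dimensional feature vectors, and
* a volumetric classifier (two 3x3x3 conv blocks with max-pooling, dropout
  on the input volume and on the flattened features) for 3D beta maps.

Training is full-precision Adam on softmax cross-entropy with an early stop
on a training-loss plateau. All randomness (init, dropout masks, batch
order) flows from a single ``numpy.random.Generator`` so runs are exactly
reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He initialisation for ReLU stacks
        self.W = rng.normal(scale=scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate):
        super().__init__()
        self.rate = float(rate)

    def forward(self, x, train, rng):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Conv3D(Layer):
    """3x3x3 'same' convolution via im2col + one BLAS matmul per pass."""

    KERNEL = 3

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        k = self.KERNEL
        self.c_in, self.c_out = c_in, c_out
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.W = rng.normal(scale=scale, size=(c_out, c_in * k**3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        # x: (n, c_in, D, H, W)
        k = self.KERNEL
        pad = k // 2
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c, D, H, W = x.shape
        self._spatial = (D, H, W)
        xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
        self._xp_shape = xp.shape
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
        # (n, c, D, H, W, k, k, k) -> (n*D*H*W, c*k^3)
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            n * D * H * W, c * k**3
        )
        self._col = col
        out = col @ self.W.T + self.b
        return out.reshape(n, D, H, W, self.c_out).transpose(0, 4, 1, 2, 3)

    def backward(self, grad):
        k = self.KERNEL
        pad = k // 2
        D, H, W = self._spatial
        n = grad.shape[0]
        g = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 4, 1), dtype=np.float32
        ).reshape(n * D * H * W, self.c_out)
        self.grads[0][...] = g.T @ self._col
        self.grads[1][...] = g.sum(axis=0)
        dcol = (g @ self.W).reshape(n, D, H, W, self.c_in, k, k, k)
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    dxp[:, :, dz : dz + D, dy : dy + H, dx : dx + W] += (
                        dcol[:, :, :, :, :, dz, dy, dx].transpose(0, 4, 1, 2, 3)
                    )
        return dxp[:, :, pad:-pad, pad:-pad, pad:-pad]


class MaxPool3D(Layer):
    """2x2x2 max pooling (spatial dims must be even)."""

    def forward(self, x, train, rng):
        n, c, D, H, W = x.shape
        r = x.reshape(n, c, D // 2, 2, H // 2, 2, W // 2, 2)
        out = r.max(axis=(3, 5, 7))
        self._mask = r == out[:, :, :, None, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, grad):
        g = grad[:, :, :, None, :, None, :, None] * self._mask
        return g.reshape(self._shape)


def softmax_xent(logits, y_onehot):
    """(loss, dlogits) for softmax cross-entropy, averaged over the batch."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.sum(y_onehot * np.log(probs + 1e-300)) / n
    return loss, (probs - y_onehot) / n


class Network:
    """Sequential layer stack trained with Adam on softmax cross-entropy."""

    def __init__(self, layers, rng):
        self.layers = layers
        self.rng = rng
        self._adam_m = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_v = [np.zeros_like(p) for l in layers for p in l.params]
        self._adam_t = 0

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train, self.rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
                self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g**2
                mhat = self._adam_m[i] / (1 - beta1**self._adam_t)
                vhat = self._adam_v[i] / (1 - beta2**self._adam_t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    def fit(
        self,
        X,
        y_onehot,
        max_epochs=60,
        batch_size=32,
        lr=1e-3,
        plateau_tol=1e-4,
        patience=8,
    ):
        """Train until ``max_epochs`` or a training-loss plateau."""
        n = X.shape[0]
        best_loss, stall = np.inf, 0
        for _ in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(X[idx], train=True)
                loss, dlogits = softmax_xent(logits, y_onehot[idx])
                epoch_loss += loss * len(idx)
                self.backward(dlogits)
                self._adam_step(lr)
            epoch_loss /= n
            if epoch_loss < best_loss - plateau_tol:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall >= patience:
                    break
        return self

    def predict(self, X, batch_size=64):
        preds = []
        for start in range(0, X.shape[0], batch_size):
            logits = self.forward(X[start : start + batch_size], train=False)
            preds.append(np.argmax(logits, axis=1))
        return np.concatenate(preds)


def feed_forward_net(n_features, n_classes, rng, hidden=(64, 32), dropout=0.25):
    layers = []
    n_in = n_features
    for width in hidden:
        layers += [Dense(n_in, width, rng), ReLU(), Dropout(dropout)]
        n_in = width
    layers.append(Dense(n_in, n_classes, rng))
    return Network(layers, rng)


def volumetric_net(
    grid_shape,
    n_classes,
    rng,
    channels=(8, 16),
    input_dropout=0.2,
    dropout=0.5,
):
    d, h, w = grid_shape
    if any(g % 4 for g in grid_shape):
        raise ValueError("volumetric net needs grid dimensions divisible by 4")
    c1, c2 = channels
    flat = (d // 4) * (h // 4) * (w // 4) * c2
    layers = [
        Dropout(input_dropout),
        Conv3D(1, c1, rng),
        ReLU(),
        MaxPool3D(),
        Conv3D(c1, c2, rng),
        ReLU(),
        MaxPool3D(),
        Flatten(),
        Dropout(dropout),
        Dense(flat, n_classes, rng),
    ]
    return Network(layers, rng)
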