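"""A small numpy CNN engine compiled from :class:`ArchitectureSpec`.

Implements exactly the layer vocabulary the three models need — 2-D
convolution (stride 1, valid or same padding), ReLU, 2x2/stride-2 max
pooling, dense, inverted dropout and a softmax head trained with two-class
cross-entropy under SGD with momentum.  Arrays are laid out (N, H, W, C);
convolutions run as im2col + matmul so the heavy lifting stays in BLAS.

Weights use seeded variance-scaling (He-style) uniform initialisation,
limit sqrt(6 / fan_in), biases zero, so runs are reproducible bit-for-bit
given a seed.
"""

from __future__ import annotations

import numpy as np

from .architectures import ArchitectureSpec, propagate_shapes

__all__ = ["Network", "SGDMomentum", "compile_network", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, OH*OW, kh*kw*C) patch matrix, stride 1, valid."""
    n, h, w, c = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    sN, sH, sW, sC = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, oh, ow, kh, kw, c),
        strides=(sN, sH, sW, sH, sW, sC),
        writeable=False,
    )
    return cols.reshape(n, oh * ow, kh * kw * c)


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _Conv2D(_Layer):
    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 padding: str, rng: np.random.Generator) -> None:
        super().__init__()
        self.kh, self.kw, self.in_ch, self.out_ch = kh, kw, in_ch, out_ch
        self.padding = padding
        fan_in = kh * kw * in_ch
        limit = np.sqrt(6.0 / fan_in)
        self.w = rng.uniform(-limit, limit, size=(fan_in, out_ch))
        self.b = np.zeros(out_ch)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _pad(self) -> tuple[tuple[int, int], tuple[int, int]]:
        # 'same' at stride 1: total pad k-1, split floor/ceil
        ph, pw = self.kh - 1, self.kw - 1
        return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.padding == "same":
            (pt, pb), (pl, pr) = self._pad()
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self._x_shape = x.shape
        self._cols = _im2col(x, self.kh, self.kw)
        n = x.shape[0]
        oh = x.shape[1] - self.kh + 1
        ow = x.shape[2] - self.kw + 1
        out = self._cols @ self.w + self.b
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, _ = grad.shape
        g = grad.reshape(n, oh * ow, self.out_ch)
        self.grads[0][...] = np.tensordot(self._cols, g, axes=([0, 1], [0, 1]))
        self.grads[1][...] = g.sum(axis=(0, 1))
        dcols = g @ self.w.T  # (n, oh*ow, kh*kw*c)
        dx = np.zeros(self._x_shape)
        dcols = dcols.reshape(n, oh, ow, self.kh, self.kw, self.in_ch)
        # scatter-add each kernel offset back onto the (padded) input
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        if self.padding == "same":
            (pt, pb), (pl, pr) = self._pad()
            h, w = self._x_shape[1] - pt - pb, self._x_shape[2] - pl - pr
            dx = dx[:, pt:pt + h, pl:pl + w, :]
        return dx


class _ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _MaxPool2x2(_Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        oh, ow = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :oh * 2, :ow * 2, :]
        windows = xc.reshape(n, oh, 2, ow, 2, c)
        out = windows.max(axis=(2, 4))
        # route gradient to the first maximum in each window
        eq = windows == out[:, :, None, :, None, :]
        flat = eq.transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        first = flat.argmax(axis=-1)
        self._sel = np.zeros_like(flat, dtype=bool)
        np.put_along_axis(self._sel, first[..., None], True, axis=-1)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c = grad.shape
        dflat = self._sel * grad[..., None]
        dwin = dflat.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, :oh * 2, :ow * 2, :] = dwin.reshape(n, oh * 2, ow * 2, c)
        return dx


class _Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class _Dropout(_Layer):
    """Inverted dropout: at train time scale kept units by 1/(1-rate)."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self._rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Network:
    """A compiled feed-forward stack ending in a 2-class softmax."""

    def __init__(self, layers: list[_Layer], spec: ArchitectureSpec) -> None:
        self.layers = layers
        self.spec = spec

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, rows summing to 1."""
        out = [softmax(self.forward_logits(x[i:i + batch_size], train=False))
               for i in range(0, len(x), batch_size)]
        return np.vstack(out)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray,
                          train: bool = True) -> tuple[float, float]:
        """Mean cross-entropy and batch accuracy; fills parameter gradients."""
        logits = self.forward_logits(x, train=train)
        probs = softmax(logits)
        n = len(y)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, acc


class SGDMomentum:
    """Classic momentum: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, params: list[np.ndarray], learning_rate: float,
                 momentum: float) -> None:
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        self.params = params
        self.lr = learning_rate
        self.mu = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.mu
            v -= self.lr * g
            p += v


def compile_network(spec: ArchitectureSpec, seed: int | None = 0) -> Network:
    """Instantiate a trainable numpy network from a layer specification."""
    rng = np.random.default_rng(seed)
    shapes = propagate_shapes(spec)
    layers: list[_Layer] = []
    in_shape: tuple[int, ...] = (spec.input_size, spec.input_size, 1)
    for layer_spec, out_shape in zip(spec.layers, shapes):
        kind = layer_spec.kind
        if kind == "conv":
            layers.append(_Conv2D(in_shape[2], layer_spec.filters,
                                  *layer_spec.kernel, layer_spec.padding, rng))
        elif kind == "relu":
            layers.append(_ReLU())
        elif kind == "maxpool":
            layers.append(_MaxPool2x2())
        elif kind == "dense":
            if len(in_shape) > 1:
                layers.append(_Flatten())
            layers.append(_Dense(int(np.prod(in_shape)), layer_spec.units, rng))
        elif kind == "dropout":
            layers.append(_Dropout(layer_spec.rate, rng))
        elif kind == "softmax":
            pass  # applied by predict_proba / the loss
        in_shape = out_shape
    return Network(layers, spec)
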