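"""A small, self-contained convolutional network with explicit backpropagation.

This module provides exactly what the training and attribution code needs and
nothing more: stride-1 'same' convolutions (im2col), ReLU, 2x2 max pooling,
global average pooling, a linear head, and SGD with classical momentum.  All
arithmetic is float32 NumPy, so runs are bit-reproducible on one machine for a
fixed seed.  The ``TinyCNN`` built here is the offline trainable backbone of
the package; it downsamples by 8, so input sides must be multiples of 8.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "velocity")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """Stride-1 'same' 2D convolution over (N, C, H, W) inputs."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        k = kernel_size
        if k % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.k = k
        self.pad = k // 2
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Param(rng.normal(0.0, scale, (out_channels, in_channels, k, k)))
        self.bias = Param(np.zeros(out_channels))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * h * w, c * self.k * self.k)
        self._cols = cols
        wf = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wf.T + self.bias.value
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)
                                     ).reshape(n * h * w, self.out_channels)
        self.weight.grad += (dflat.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += dflat.sum(axis=0)
        # gradient w.r.t. input: full correlation with the flipped kernels
        p = self.k - 1 - self.pad
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(dp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * h * w, -1)
        wflip = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx = cols @ wflip.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties share the gradient."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._xr = xr
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._xr == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (dout[:, :, :, None, :, None] / counts)
        n, c, h2, _, w2, _ = dxr.shape
        return dxr.reshape(n, c, h2 * 2, w2 * 2)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        dxr = np.broadcast_to(dout[:, :, :, None, :, None] / 4.0,
                              (n, c, h2, 2, w2, 2))
        return dxr.reshape(n, c, h2 * 2, w2 * 2).astype(dout.dtype)


class Standardize(Layer):
    """Per-image standardization: (x − mean) / sd over all pixels and channels."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        self._sd = np.maximum(sd, 1e-6)
        self._y = (x - mean) / self._sd
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        g_mean = dout.mean(axis=axes, keepdims=True)
        gy_mean = (dout * self._y).mean(axis=axes, keepdims=True)
        return (dout - g_mean - self._y * gy_mean) / self._sd


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._spatial
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w),
            dout.shape + (h, w)).astype(dout.dtype).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, scale, (out_features, in_features)))
        self.bias = Param(np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinyCNN:
    """Small offline-trainable CNN: a standardize + 2x2 average-pool stem,
    three conv blocks (conv-ReLU, max-pooled after the first two), global
    average pooling and a linear head.  Total downsampling before the last
    convolution is 8x, so a 96x128 input yields 12x16 feature maps there.
    Named layers expose the convolutional feature maps that Grad-CAM reads;
    ``conv_layer_names`` lists them in network order.
    """

    CHANNELS = (16, 32, 64)

    def __init__(self, num_classes: int, in_channels: int = 3, seed: int = 0):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        rng = np.random.default_rng(seed)
        self.num_classes = num_classes
        self.in_channels = in_channels
        self.seed = seed
        self.layers: list[tuple[str, Layer]] = [
            ("standardize", Standardize()),
            ("stem_pool", AvgPool2()),
        ]
        prev = in_channels
        for i, ch in enumerate(self.CHANNELS, start=1):
            self.layers.append((f"conv{i}", Conv2d(prev, ch, 3, rng)))
            self.layers.append((f"relu{i}", ReLU()))
            if i < len(self.CHANNELS):
                self.layers.append((f"pool{i}", MaxPool2()))
            prev = ch
        self.layers.append(("gap", GlobalAvgPool()))
        self.layers.append(("fc", Linear(prev, num_classes, rng)))

    @property
    def conv_layer_names(self) -> list[str]:
        return [n for n, l in self.layers if isinstance(l, Conv2d)]

    @property
    def last_conv_layer(self) -> str:
        return self.conv_layer_names[-1]

    def params(self) -> list[Param]:
        return [p for _, l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a float32 batch of shape (N, C, H, W)."""
        out = x
        for _, layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = dlogits
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def sgd_step(self, lr: float, momentum: float,
                 max_grad_norm: float | None = 5.0) -> None:
        """One SGD-with-momentum update; the global gradient norm is clipped
        (default 5.0) so loss reweighting cannot blow up early steps."""
        if max_grad_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params()))
            if total > max_grad_norm:
                scale = np.float32(max_grad_norm / total)
                for p in self.params():
                    p.grad *= scale
        for p in self.params():
            p.velocity = momentum * p.velocity + p.grad
            p.value -= np.float32(lr) * p.velocity

    # ------------------------------------------------------------------ #
    # attribution support
    # ------------------------------------------------------------------ #
    def logits_and_activation_grad(self, x: np.ndarray, class_idx: int,
                                   layer: str):
        """Logits, the rectified feature maps of ``layer``, and d(logit)/d(maps).

        ``layer`` names a convolution; its post-ReLU activation is read.
        Returns (logits (C,), A (K, h, w), dA (K, h, w)) for a single image
        given as (C, H, W) float32.
        """
        if layer not in self.conv_layer_names:
            raise KeyError(
                f"layer {layer!r} not found or has no spatial extent; "
                f"candidates: {self.conv_layer_names}"
            )
        relu_name = "relu" + layer[len("conv"):]
        names = [n for n, _ in self.layers]
        pos = names.index(relu_name)
        out = x[None].astype(np.float32)
        activation = None
        for i, (_, lay) in enumerate(self.layers):
            out = lay.forward(out)
            if i == pos:
                activation = out
        logits = out[0]
        donehot = np.zeros((1, self.num_classes), dtype=np.float32)
        donehot[0, class_idx] = 1.0
        grad = donehot
        for _, lay in reversed(self.layers[pos + 1:]):
            grad = lay.backward(grad)
        return logits, activation[0].copy(), grad[0].copy()

    # ------------------------------------------------------------------ #
    # persistence
    # ------------------------------------------------------------------ #
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(directory / "weights.npz", **arrays)
        meta = {"num_classes": self.num_classes,
                "in_channels": self.in_channels, "seed": self.seed}
        (directory / "model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory) -> "TinyCNN":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(meta["num_classes"], meta["in_channels"], meta["seed"])
        with np.load(directory / "weights.npz") as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model
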