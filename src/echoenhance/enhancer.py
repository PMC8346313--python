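"""Three-stage convolutional image-enhancement network.

The network is a shallow SRCNN-style pipeline over single-channel images:

* stage 1 — feature extraction: wide kernel, gated activation;
* stage 2..L-1 — nonlinear mapping of the feature maps;
* stage L — reconstruction: linear convolution back to one channel,
  initialized as a uniform mean filter but fully trainable.

Every convolution uses reflect padding and produces same-size output.  The
activation is either ReLU or a self-gated "swish" ``a(t) = t * sigmoid(alpha
* t)`` with a trainable per-layer ``alpha``.  Training minimizes mean
squared error between the network output and the clean target by mini-batch
stochastic gradient descent with hand-derived layer gradients (checked
against finite differences in the test suite).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import EchoImage

__all__ = [
    "Activation",
    "ConvLayer",
    "EnhancerNet",
    "TrainConfig",
    "conv2d",
    "relu",
    "relu_grad",
    "swish",
    "forward",
    "mse_loss",
    "sgd_step",
    "train",
    "loss_and_grads",
    "default_net",
    "identity_net",
    "save_net",
    "load_net",
]


class Activation(str, enum.Enum):
    RELU = "relu"
    SWISH = "swish"
    NONE = "none"


def relu(x):
    """Elementwise ``max(0, x)``."""
    return np.maximum(0.0, x)


def relu_grad(x):
    """Derivative of :func:`relu`; the subgradient at 0 is taken as 0."""
    return (np.asarray(x) > 0).astype(np.float64)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def swish(x, alpha: float = 1.0):
    """Self-gated activation ``x * sigmoid(alpha * x)``."""
    return np.asarray(x, dtype=np.float64) * _sigmoid(alpha * np.asarray(x))


def _swish_grads(x, alpha: float):
    """Returns (d/dx, d/dalpha) of swish at x."""
    x = np.asarray(x, dtype=np.float64)
    s = _sigmoid(alpha * x)
    dx = s + alpha * x * s * (1.0 - s)
    dalpha = x * x * s * (1.0 - s)
    return dx, dalpha


@dataclass
class ConvLayer:
    """One convolutional layer: weights ``(out, in, f, f)``, per-channel bias.

    ``alpha`` is the trainable gate parameter of the swish activation; it is
    carried (and updated) only when ``activation == Activation.SWISH``.
    """

    weights: np.ndarray
    bias: np.ndarray
    activation: Activation = Activation.SWISH
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 4:
            raise ValueError(f"weights must be 4-D (out, in, f, f), got ndim={self.weights.ndim}")
        out_ch, in_ch, fh, fw = self.weights.shape
        if fh != fw or fh % 2 == 0:
            raise ValueError(f"kernel must be square with odd size, got {fh}x{fw}")
        if self.bias.shape != (out_ch,):
            raise ValueError(f"bias shape {self.bias.shape} does not match {out_ch} output channels")
        self.activation = Activation(self.activation)
        self.alpha = float(self.alpha)

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]


def _reflect_index(n: int, pad: int) -> np.ndarray:
    """Index map realizing symmetric-without-edge-repeat reflect padding."""
    if pad == 0:
        return np.arange(n)
    if n == 1:
        return np.zeros(n + 2 * pad, dtype=np.intp)
    return np.pad(np.arange(n), pad, mode="reflect")


def _pad_reflect(x: np.ndarray, pad: int) -> np.ndarray:
    """Reflect-pad the trailing two axes of a (C, H, W) stack."""
    ri = _reflect_index(x.shape[-2], pad)
    ci = _reflect_index(x.shape[-1], pad)
    return x[..., ri[:, None], ci[None, :]]


def _pad_reflect_adjoint(dpad: np.ndarray, shape_hw: tuple[int, int], pad: int) -> np.ndarray:
    """Adjoint of :func:`_pad_reflect`: accumulate padded-gradient into the core."""
    h, w = shape_hw
    ri = _reflect_index(h, pad)
    ci = _reflect_index(w, pad)
    out = np.zeros(dpad.shape[:-2] + (h, w), dtype=np.float64)
    np.add.at(out, (..., ri[:, None], ci[None, :]), dpad)
    return out


def conv2d(inputs: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Multi-channel 2-D correlation with reflect padding and bias.

    ``inputs`` is a ``(C, H, W)`` feature-map stack (a bare 2-D array is
    promoted to one channel); returns ``(out_channels, H, W)``.  The layer's
    activation is deliberately NOT applied here.
    """
    x = np.asarray(inputs, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"inputs must be (C, H, W), got ndim={x.ndim}")
    if x.shape[0] != layer.in_channels:
        raise ValueError(
            f"input has {x.shape[0]} channels but layer expects {layer.in_channels}"
        )
    pad = layer.kernel_size // 2
    padded = _pad_reflect(x, pad)
    # windows: (C, H, W, f, f)
    windows = sliding_window_view(padded, (layer.kernel_size, layer.kernel_size), axis=(1, 2))
    out = np.einsum("ihwkl,oikl->ohw", windows, layer.weights, optimize=True)
    return out + layer.bias[:, None, None]


def _conv_backward(
    x: np.ndarray, layer: ConvLayer, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of ``sum(dout * conv2d(x, layer))`` w.r.t. x, weights, bias."""
    f = layer.kernel_size
    pad = f // 2
    padded = _pad_reflect(x, pad)
    windows = sliding_window_view(padded, (f, f), axis=(1, 2))
    dw = np.einsum("ohw,ihwkl->oikl", dout, windows, optimize=True)
    db = dout.sum(axis=(1, 2))
    dpad = np.zeros_like(padded)
    h, w = x.shape[1], x.shape[2]
    # scatter-add each kernel tap; f*f iterations, all vectorized inside
    for k in range(f):
        for l in range(f):
            dpad[:, k : k + h, l : l + w] += np.einsum(
                "ohw,oi->ihw", dout, layer.weights[:, :, k, l], optimize=True
            )
    dx = _pad_reflect_adjoint(dpad, (h, w), pad)
    return dx, dw, db


@dataclass
class EnhancerNet:
    """Ordered convolutional layers; the last layer is the linear reconstruction."""

    layers: list[ConvLayer]

    def __post_init__(self) -> None:
        if len(self.layers) < 3:
            raise ValueError(f"network needs >= 3 layers, got {len(self.layers)}")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if prev.out_channels != nxt.in_channels:
                raise ValueError(
                    f"channel mismatch: {prev.out_channels} -> {nxt.in_channels}"
                )
        if self.layers[0].in_channels != 1:
            raise ValueError("first layer must take a single-channel image")
        if self.layers[-1].out_channels != 1:
            raise ValueError("reconstruction layer must output a single channel")

    def parameters(self) -> list[np.ndarray | float]:
        """Flat parameter list: per layer weights, bias, then alpha if gated."""
        params: list[np.ndarray | float] = []
        for layer in self.layers:
            params.append(layer.weights)
            params.append(layer.bias)
            if layer.activation is Activation.SWISH:
                params.append(layer.alpha)
        return params

    def set_parameters(self, params: Sequence[np.ndarray | float]) -> None:
        it = iter(params)
        for layer in self.layers:
            layer.weights = np.asarray(next(it), dtype=np.float64)
            layer.bias = np.asarray(next(it), dtype=np.float64)
            if layer.activation is Activation.SWISH:
                layer.alpha = float(next(it))


def _forward_stack(net: EnhancerNet, x: np.ndarray, want_cache: bool = False):
    """Run the net on a (1, H, W) stack; reconstruction layer stays linear."""
    cache = []
    for idx, layer in enumerate(net.layers):
        pre = conv2d(x, layer)
        last = idx == len(net.layers) - 1
        if last or layer.activation is Activation.NONE:
            post = pre
        elif layer.activation is Activation.RELU:
            post = relu(pre)
        else:
            post = swish(pre, layer.alpha)
        if want_cache:
            cache.append((x, pre))
        x = post
    return (x, cache) if want_cache else x


def forward(net: EnhancerNet, image: EchoImage) -> EchoImage:
    """Enhance one image: all stages, output clipped to ``[0, 1]``."""
    out = _forward_stack(net, image.pixels[None])
    return EchoImage(np.clip(out[0], 0.0, 1.0), bit_depth=image.bit_depth)


def mse_loss(pred: EchoImage | np.ndarray, target: EchoImage | np.ndarray) -> float:
    """Mean over pixels of squared intensity difference."""
    p = pred.pixels if isinstance(pred, EchoImage) else np.asarray(pred, dtype=np.float64)
    t = target.pixels if isinstance(target, EchoImage) else np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def loss_and_grads(
    net: EnhancerNet, noisy: np.ndarray, clean: np.ndarray, clip: bool = True
) -> tuple[float, list[np.ndarray | float]]:
    """MSE loss for one (noisy, clean) pair and gradients w.r.t. ``net.parameters()``.

    When ``clip`` is set the loss is taken on the ``[0, 1]``-clipped output
    and the clip contributes its (zero-outside) subgradient.
    """
    x0 = np.asarray(noisy, dtype=np.float64)[None]
    target = np.asarray(clean, dtype=np.float64)
    out, cache = _forward_stack(net, x0, want_cache=True)
    raw = out[0]
    pred = np.clip(raw, 0.0, 1.0) if clip else raw
    n_pix = pred.size
    loss = float(np.mean((pred - target) ** 2))

    dpred = 2.0 * (pred - target) / n_pix
    if clip:
        dpred = dpred * ((raw >= 0.0) & (raw <= 1.0))
    dpost = dpred[None]

    grads_rev: list[np.ndarray | float] = []
    for idx in range(len(net.layers) - 1, -1, -1):
        layer = net.layers[idx]
        x_in, pre = cache[idx]
        last = idx == len(net.layers) - 1
        dalpha = None
        if last or layer.activation is Activation.NONE:
            dpre = dpost
        elif layer.activation is Activation.RELU:
            dpre = dpost * relu_grad(pre)
        else:
            dact, dact_alpha = _swish_grads(pre, layer.alpha)
            dpre = dpost * dact
            dalpha = float(np.sum(dpost * dact_alpha))
        dx, dw, db = _conv_backward(x_in, layer, dpre)
        if layer.activation is Activation.SWISH:
            grads_rev.append(0.0 if dalpha is None else dalpha)
        grads_rev.append(db)
        grads_rev.append(dw)
        dpost = dx
    return loss, grads_rev[::-1]


def sgd_step(
    params: Sequence[np.ndarray | float],
    grads: Sequence[np.ndarray | float],
    beta: float,
) -> list[np.ndarray | float]:
    """Plain gradient-descent update ``p <- p - beta * g`` on a parameter list."""
    if beta <= 0:
        raise ValueError(f"learning rate beta must be > 0, got {beta}")
    if len(params) != len(grads):
        raise ValueError("params and grads must have equal length")
    updated: list[np.ndarray | float] = []
    for p, g in zip(params, grads):
        if np.isscalar(p) or np.ndim(p) == 0:
            updated.append(float(p) - beta * float(g))
        else:
            p = np.asarray(p, dtype=np.float64)
            g = np.asarray(g, dtype=np.float64)
            if p.shape != g.shape:
                raise ValueError(f"gradient shape {g.shape} does not match parameter {p.shape}")
            updated.append(p - beta * g)
    return updated


def _tree_add(acc, new):
    if acc is None:
        return list(new)
    return [a + b for a, b in zip(acc, new)]


def _tree_scale(tree, s):
    return [t * s for t in tree]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.2
    batch_size: int = 2
    epochs: int = 100
    seed: int = 0
    semisup_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.semisup_weight < 0:
            raise ValueError(f"semisup_weight must be >= 0, got {self.semisup_weight}")


def train(
    net: EnhancerNet,
    pairs: Sequence[tuple[EchoImage, EchoImage]],
    config: TrainConfig,
    semisup_hook=None,
) -> tuple[EnhancerNet, list[float]]:
    """Mini-batch SGD on mean squared error over (clean, noisy) pairs.

    Each epoch shuffles the pairs (seeded), averages per-example gradients
    within each mini-batch, and applies one :func:`sgd_step` per batch.
    Returns the trained net (modified in place) and the per-epoch mean loss
    trace.  ``semisup_hook``, when given, is called once per epoch with
    ``(net, pairs, epoch)`` after the parameter updates — used by the
    optional discriminator bookkeeping; it never changes the enhancer's
    objective.
    """
    if len(pairs) == 0:
        raise ValueError("training requires at least one (clean, noisy) pair")
    rng = np.random.default_rng(config.seed)
    data = [
        (noisy.pixels.copy(), clean.pixels.copy()) for clean, noisy in pairs
    ]
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            grad_sum = None
            for idx in batch:
                noisy_px, clean_px = data[idx]
                loss, grads = loss_and_grads(net, noisy_px, clean_px)
                epoch_loss += loss
                grad_sum = _tree_add(grad_sum, grads)
            mean_grads = _tree_scale(grad_sum, 1.0 / len(batch))
            net.set_parameters(sgd_step(net.parameters(), mean_grads, config.learning_rate))
        trace.append(epoch_loss / len(data))
        if semisup_hook is not None:
            semisup_hook(net, pairs, epoch)
    return net, trace


def default_net(
    seed: int = 0,
    feature_channels: int = 16,
    mapping_channels: int = 8,
    n_mapping_layers: int = 1,
    activation: Activation | str = Activation.SWISH,
) -> EnhancerNet:
    """SRCNN-style default: 9x9/16 feature layer, 5x5 mapping, 5x5 reconstruction.

    Hidden weights use He-style fan-in scaling; the reconstruction kernel is
    initialized as a uniform mean filter over its receptive field (but stays
    trainable).
    """
    rng = np.random.default_rng(seed)
    activation = Activation(activation)

    def he(out_ch, in_ch, f):
        scale = math.sqrt(2.0 / (in_ch * f * f))
        return rng.normal(0.0, scale, size=(out_ch, in_ch, f, f))

    layers = [ConvLayer(he(feature_channels, 1, 9), np.zeros(feature_channels), activation)]
    ch = feature_channels
    for _ in range(n_mapping_layers):
        layers.append(ConvLayer(he(mapping_channels, ch, 5), np.zeros(mapping_channels), activation))
        ch = mapping_channels
    recon = np.full((1, ch, 5, 5), 1.0 / (ch * 25))
    layers.append(ConvLayer(recon, np.zeros(1), Activation.NONE))
    return EnhancerNet(layers)


def identity_net(n_layers: int = 3) -> EnhancerNet:
    """1x1 pass-through network: every layer is the identity, no activation."""
    if n_layers < 3:
        raise ValueError("network needs >= 3 layers")
    layers = [
        ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1), Activation.NONE)
        for _ in range(n_layers)
    ]
    return EnhancerNet(layers)


def save_net(net: EnhancerNet, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize the network (and optional run metadata) to a JSON checkpoint."""
    payload = {
        "format": "echoenhance-net-v1",
        "metadata": metadata or {},
        "layers": [
            {
                "weights": layer.weights.tolist(),
                "bias": layer.bias.tolist(),
                "activation": layer.activation.value,
                "alpha": layer.alpha,
            }
            for layer in net.layers
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_net(path: str | Path) -> EnhancerNet:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "echoenhance-net-v1":
        raise ValueError(f"{path}: not an echoenhance network checkpoint")
    layers = [
        ConvLayer(
            np.asarray(spec["weights"]),
            np.asarray(spec["bias"]),
            Activation(spec["activation"]),
            float(spec["alpha"]),
        )
        for spec in payload["layers"]
    ]
    return EnhancerNet(layers)
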