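"""Network building blocks: MLPs, a WGAN critic with an exact gradient
penalty for piecewise-linear activations, and a plain RNN cell.

The gradient penalty needs the gradient of the critic output with respect to
its *input* as a differentiable function of the weights. For leaky-ReLU
critics that gradient is a product of weight matrices and activation-slope
masks; since the activation is piecewise linear, the masks are locally
constant and the analytic product is an ordinary first-order expression in
the weights — no second-order autodiff required.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor(_glorot(rng, n_in, n_out))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Fully connected network with a configurable output activation."""

    def __init__(
        self,
        rng: np.random.Generator,
        sizes: list[int],
        hidden_activation: str = "relu",
        out_activation: str | None = None,
    ):
        self.layers = [Linear(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.hidden_activation = hidden_activation
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = getattr(h, self.hidden_activation)()
            elif self.out_activation is not None:
                h = getattr(h, self.out_activation)()
        return h

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class Critic:
    """Scalar-output leaky-ReLU MLP with an exact WGAN gradient penalty."""

    def __init__(self, rng: np.random.Generator, sizes: list[int], alpha: float = 0.2):
        # sizes = [d_in, hidden..., 1]
        assert sizes[-1] == 1
        self.layers = [Linear(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.alpha = alpha

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = h.leaky_relu(self.alpha)
        return h

    def input_gradient(self, x: np.ndarray) -> Tensor:
        """d critic / d input at ``x``, differentiable w.r.t. the weights.

        Runs a plain forward pass to record the activation slopes (constants
        for a piecewise-linear activation), then composes the backward product
        with Tensor ops so the result participates in the graph.
        """
        masks: list[np.ndarray] = []
        h = np.asarray(x, dtype=np.float64)
        for i, layer in enumerate(self.layers):
            pre = h @ layer.W.data + layer.b.data
            if i < len(self.layers) - 1:
                mask = np.where(pre > 0, 1.0, self.alpha)
                masks.append(mask)
                h = pre * mask
            else:
                h = pre
        # backward product: g = (((mask_L * W_out^T) @ W_L^T * mask_{L-1}) ...) @ W_1^T
        g = self.layers[-1].W.transpose()  # (1, H_last), broadcasts over the batch
        for layer, mask in zip(reversed(self.layers[:-1]), reversed(masks)):
            g = (g * mask) @ layer.W.transpose()
        return g  # (B, d_in)

    def gradient_penalty(self, x_interp: np.ndarray) -> Tensor:
        """Mean squared deviation of the input-gradient norm from 1."""
        g = self.input_gradient(x_interp)
        norm = ((g * g).sum(axis=1) + 1e-12).sqrt()
        dev = norm - 1.0
        return (dev * dev).mean()

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class RNNCell:
    """Vanilla tanh recurrence: h' = tanh(x W_ih + h W_hh + b)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        self.W_ih = Tensor(_glorot(rng, n_in, n_hidden))
        self.W_hh = Tensor(np.linalg.qr(rng.normal(size=(n_hidden, n_hidden)))[0] * 0.9)
        self.b = Tensor(np.zeros(n_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        return (x @ self.W_ih + h @ self.W_hh + self.b).tanh()

    @property
    def params(self) -> list[Tensor]:
        return [self.W_ih, self.W_hh, self.b]


def interpolate_pairs(
    rng: np.random.Generator, real: np.ndarray, fake: np.ndarray
) -> np.ndarray:
    """Uniform interpolates between matched real/fake rows (for the penalty)."""
    eps = rng.random((real.shape[0], 1))
    return eps * real + (1.0 - eps) * fake


__all__ = ["Linear", "MLP", "Critic", "RNNCell", "Tensor", "concat", "interpolate_pairs"]
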