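"""Minimal feed-forward networks with explicit backprop.

The networks used throughout the package (Q-network head, feature
extractor, conditional generator, critic) are small multilayer
perceptrons trained with bespoke losses (TD error, Wasserstein-style
critic scores, distillation and alignment penalties).  This module
provides the one primitive they all share: a dense MLP whose forward
pass caches activations and whose backward pass returns both parameter
gradients and the gradient with respect to the input, so losses can be
chained through several networks (e.g. critic score back into the
generator).

Everything is plain numpy; parameters are lists of (W, b) arrays and
initialisation is seeded through a caller-supplied Generator.
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = ("relu", "tanh", "linear")


def _act(name: str, z: np.ndarray, scale: float) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return scale * np.tanh(z)
    return z


def _act_grad(name: str, z: np.ndarray, scale: float) -> np.ndarray:
    if name == "relu":
        return (z > 0.0).astype(z.dtype)
    if name == "tanh":
        t = np.tanh(z)
        return scale * (1.0 - t * t)
    return np.ones_like(z)


class MLP:
    """Dense feed-forward network.

    Parameters
    ----------
    sizes:
        Layer widths, e.g. ``[52, 64, 2]``.
    activations:
        One name per weight layer from {"relu", "tanh", "linear"};
        length ``len(sizes) - 1``.
    rng:
        Seeded ``numpy.random.Generator`` used for He-style init.
    out_scale:
        Multiplier applied to a ``tanh`` activation (used to bound
        generator outputs without pinning them to (-1, 1)).
    """

    def __init__(self, sizes, activations, rng, out_scale: float = 1.0):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per weight layer")
        for a in activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        self.sizes = list(sizes)
        self.activations = list(activations)
        self.out_scale = float(out_scale)
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b, act in zip(self.W, self.b, self.activations):
            X = _act(act, X @ W + b, self.out_scale if act == "tanh" else 1.0)
        return X

    def forward_cache(self, X: np.ndarray):
        """Forward pass retaining pre-activations for backprop."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cache = {"inputs": [X], "pre": []}
        H = X
        for W, b, act in zip(self.W, self.b, self.activations):
            Z = H @ W + b
            cache["pre"].append(Z)
            H = _act(act, Z, self.out_scale if act == "tanh" else 1.0)
            cache["inputs"].append(H)
        return H, cache

    def backward(self, cache, dY: np.ndarray):
        """Backprop ``dY = dLoss/dOutput``; returns (dX, grads).

        ``grads`` is a list of (dW, db) aligned with the layers.
        """
        grads = [None] * len(self.W)
        delta = np.asarray(dY, dtype=float)
        for i in range(len(self.W) - 1, -1, -1):
            act = self.activations[i]
            scale = self.out_scale if act == "tanh" else 1.0
            delta = delta * _act_grad(act, cache["pre"][i], scale)
            H_in = cache["inputs"][i]
            grads[i] = (H_in.T @ delta, delta.sum(axis=0))
            delta = delta @ self.W[i].T
        return delta, grads

    # -- parameter plumbing -------------------------------------------------

    def clone(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.sizes = list(self.sizes)
        other.activations = list(self.activations)
        other.out_scale = self.out_scale
        other.W = [W.copy() for W in self.W]
        other.b = [b.copy() for b in self.b]
        return other

    def copy_from(self, other: "MLP") -> None:
        if other.sizes != self.sizes:
            raise ValueError("architecture mismatch")
        self.W = [W.copy() for W in other.W]
        self.b = [b.copy() for b in other.b]

    def params_equal(self, other: "MLP") -> bool:
        return (
            self.sizes == other.sizes
            and all(np.array_equal(a, b) for a, b in zip(self.W, other.W))
            and all(np.array_equal(a, b) for a, b in zip(self.b, other.b))
        )

    def add_output_bias(self, c: float) -> None:
        """Shift every output coordinate by a constant (test hook)."""
        self.b[-1] = self.b[-1] + c

    def clip_weights(self, c: float) -> None:
        for i in range(len(self.W)):
            np.clip(self.W[i], -c, c, out=self.W[i])
            np.clip(self.b[i], -c, c, out=self.b[i])

    def state_dict(self):
        return {
            "sizes": self.sizes,
            "activations": self.activations,
            "out_scale": self.out_scale,
            "W": [W.tolist() for W in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_state_dict(cls, d) -> "MLP":
        net = cls.__new__(cls)
        net.sizes = list(d["sizes"])
        net.activations = list(d["activations"])
        net.out_scale = float(d["out_scale"])
        net.W = [np.asarray(W, dtype=float) for W in d["W"]]
        net.b = [np.asarray(b, dtype=float) for b in d["b"]]
        return net


class Adam:
    """Adam optimiser over one MLP's parameter list."""

    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.mW = [np.zeros_like(W) for W in net.W]
        self.vW = [np.zeros_like(W) for W in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, (dW, db) in enumerate(grads):
            self.mW[i] = b1 * self.mW[i] + (1 - b1) * dW
            self.vW[i] = b2 * self.vW[i] + (1 - b2) * dW * dW
            self.mb[i] = b1 * self.mb[i] + (1 - b1) * db
            self.vb[i] = b2 * self.vb[i] + (1 - b2) * db * db
            self.net.W[i] -= self.lr * (self.mW[i] / corr1) / (
                np.sqrt(self.vW[i] / corr2) + self.eps)
            self.net.b[i] -= self.lr * (self.mb[i] / corr1) / (
                np.sqrt(self.vb[i] / corr2) + self.eps)


class RMSProp:
    """RMSProp, the conventional optimiser for weight-clipped critics."""

    def __init__(self, net: MLP, lr: float = 5e-3, rho: float = 0.9,
                 eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.sW = [np.zeros_like(W) for W in net.W]
        self.sb = [np.zeros_like(b) for b in net.b]

    def step(self, grads) -> None:
        for i, (dW, db) in enumerate(grads):
            self.sW[i] = self.rho * self.sW[i] + (1 - self.rho) * dW * dW
            self.sb[i] = self.rho * self.sb[i] + (1 - self.rho) * db * db
            self.net.W[i] -= self.lr * dW / (np.sqrt(self.sW[i]) + self.eps)
            self.net.b[i] -= self.lr * db / (np.sqrt(self.sb[i]) + self.eps)
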