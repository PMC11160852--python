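"""Multilayer-network data model, forward pass, and output error.

Sign convention used throughout the package: the error carried by layer ``l``
is ``e_l = -dL/dx_l`` -- it points *down* the loss gradient -- so every weight
update is additive, ``W <- (1 - gamma) W + eta * mean_batch(e_{l+1} x_l^T)``.

Arrays are batch-first: activations are ``(batch, features)`` for dense layers
and ``(batch, channels, height, width)`` for convolutional layers.  A dense
layer fed a 4-d input flattens it internally, which is how a dense read-out
head sits on top of a convolutional stack without an explicit flatten layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .exceptions import DimensionError, StateError


def relu(z):
    return np.maximum(z, 0.0)


def relu_prime(z):
    # Subgradient at exactly 0 is taken as 0; reduction tests rely on this.
    return (z > 0).astype(z.dtype)


def identity(z):
    return z


def identity_prime(z):
    return np.ones_like(z)


def tanh_prime(z):
    t = np.tanh(z)
    return 1.0 - t * t


ACTIVATIONS = {
    "relu": (relu, relu_prime),
    "identity": (identity, identity_prime),
    "tanh": (np.tanh, tanh_prime),
}


class DenseLayer:
    """A fully connected layer ``x -> sigma(W x + b)``.

    Parameters
    ----------
    W : ndarray, shape (n_out, n_in)
        Forward weights; row ``i`` feeds output unit ``i``.
    b : ndarray, shape (n_out,)
        Bias.
    activation : {"relu", "identity", "tanh"}

    The most recent forward pass caches the (flattened) input and the
    preactivation; the activation derivative for the backward pass is always
    evaluated at the cached preactivation.
    """

    def __init__(self, W, b, activation="relu"):
        W = np.asarray(W, dtype=float)
        b = np.asarray(b, dtype=float)
        if W.ndim != 2:
            raise DimensionError(f"dense W must be 2-d, got shape {W.shape}")
        if b.shape != (W.shape[0],):
            raise DimensionError(
                f"bias shape {b.shape} does not match n_out={W.shape[0]}"
            )
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.W = W
        self.b = b
        self.activation = activation
        self.cached_input = None
        self.cached_pre = None
        self.cached_input_shape = None  # original (unflattened) input shape

    @property
    def n_in(self) -> int:
        return self.W.shape[1]

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        self.cached_input_shape = x.shape
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.n_in:
            raise DimensionError(
                f"dense layer expects input dim {self.n_in}, got {x.shape[1]}"
            )
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite entries in W")
        z = x @ self.W.T + self.b
        self.cached_input = x
        self.cached_pre = z
        out = ACTIVATIONS[self.activation][0](z)
        return out[0] if squeeze else out

    def sigma_prime(self):
        """Activation derivative at the cached preactivation."""
        if self.cached_pre is None:
            raise StateError("forward pass has not been run; no cached preactivation")
        return ACTIVATIONS[self.activation][1](self.cached_pre)


class Network:
    """An ordered stack of layers mapping ``x_0`` to ``x_L``.

    ``layers[k]`` maps ``x_k`` to ``x_{k+1}``; the network depth ``L`` equals
    ``len(layers)``.  Layers may be :class:`DenseLayer` or
    :class:`~pfanet.conv_net.ConvLayer`.
    """

    def __init__(self, layers: List):
        if len(layers) < 1:
            raise DimensionError("network depth must be >= 1")
        for k in range(len(layers) - 1):
            a, b = layers[k], layers[k + 1]
            if isinstance(a, DenseLayer) and isinstance(b, DenseLayer):
                if b.n_in != a.n_out:
                    raise DimensionError(
                        f"layer {k + 1} expects input dim {b.n_in} but layer "
                        f"{k} outputs {a.n_out}"
                    )
        self.layers = list(layers)

    @property
    def depth(self) -> int:
        return len(self.layers)

    def forward(self, x0):
        """Run the forward pass, caching inputs/preactivations in every layer."""
        x = x0
        for k, layer in enumerate(self.layers):
            try:
                x = layer.forward(x)
            except DimensionError as err:
                raise DimensionError(f"layer {k}: {err}") from err
        return x

    def copy(self) -> "Network":
        """Deep copy of weights and structure (caches not copied)."""
        out = []
        for layer in self.layers:
            new = object.__new__(type(layer))
            new.__dict__.update(layer.__dict__)
            new.W = layer.W.copy()
            new.b = layer.b.copy()
            new.cached_input = None
            new.cached_pre = None
            out.append(new)
        return Network(out)


@dataclass
class ErrorStack:
    """Per-layer error signals ``e_l = -dL/dx_l`` for ``l = 1..L``.

    ``e[L]`` is the output error; hidden errors are gated by the activation
    derivative of the layer that produced them.
    """

    e: Dict[int, np.ndarray] = field(default_factory=dict)
    loss: float = float("nan")


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def output_error(logits, targets):
    """Softmax cross-entropy loss and its output error.

    Parameters
    ----------
    logits : ndarray, shape (batch, n_classes) or (n_classes,)
    targets : int array, shape (batch,) or scalar
        Class indices in ``[0, n_classes)``.

    Returns
    -------
    loss : float
        Mean cross-entropy over the batch.
    e_L : ndarray, same shape as ``logits``
        Per-sample error ``one_hot(y) - softmax(logits)``; the batch average
        is taken by the update rules, not here.
    """
    logits = np.asarray(logits, dtype=float)
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits[None, :]
    targets = np.atleast_1d(np.asarray(targets))
    if targets.shape[0] != logits.shape[0]:
        raise DimensionError(
            f"batch mismatch: {logits.shape[0]} logit rows, {targets.shape[0]} targets"
        )
    n_classes = logits.shape[1]
    if targets.min() < 0 or targets.max() >= n_classes:
        raise ValueError(
            f"targets must lie in [0, {n_classes}); got range "
            f"[{targets.min()}, {targets.max()}]"
        )
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    p = softmax(logits)
    rows = np.arange(logits.shape[0])
    # log-softmax evaluated stably for the loss
    zmax = logits.max(axis=1, keepdims=True)
    logz = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
    loss = float(np.mean(logz - logits[rows, targets]))
    e_L = -p
    e_L[rows, targets] += 1.0
    return loss, (e_L[0] if squeeze else e_L)
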