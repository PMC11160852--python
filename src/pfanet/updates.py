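"""Parameter updates with weight decay, the KP symmetric feedback update,
and sparsity-mask enforcement, plus the run configuration container.

All updates are plain SGD steps with multiplicative weight decay applied per
minibatch: ``W <- (1 - gamma) W + eta * mean_batch(e_{l+1} x_l^T)``.  The
plastic feedback receives the mirror-image step
``R <- (1 - gamma) R + eta * mean_batch(x_l e_bar^T)``, so with a
semi-orthogonal ``B`` the two sides of ``B^T dR^T = dW`` coincide and the
composed path tracks ``W^T``.  Biases take no decay and have no feedback
analogue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import yaml

from .core_net import DenseLayer
from .error_rules import LayerFeedback, PRODUCT_MODES, MODES
from .exceptions import DivergenceError, ModeError


@dataclass
class TrainConfig:
    """Everything a training run needs besides the data.

    Attributes
    ----------
    algorithm : one of bp, fa, dfa, sf, kp, pfa, pfa_o
    hidden_sizes : sizes of the hidden layers (dense protocol)
    lr : learning rate for W and b (per step)
    lr_r : learning rate for the plastic feedback; None means "same as lr";
        0 freezes R (which turns the product rule into plain FA)
    wd_initial, wd_main : two-phase multiplicative weight decay per step;
        the larger initial value runs for ``wd_initial_epochs`` epochs and
        wipes out the influence of the random initialization
    wd_r : decay for R; None means "follow the W schedule"
    expansion_ratio : intermediate-population size over next-layer size
    sparsity : fraction of feedback entries fixed at zero for the whole run
    r_init : "random" or "matched" (R0 = W0^T B^T, the exact-backprop start)
    """

    algorithm: str = "pfa"
    hidden_sizes: Tuple[int, ...] = (512, 512)
    activation: str = "relu"
    lr: float = 0.05
    lr_r: Optional[float] = None
    wd_initial: float = 1e-3
    wd_main: float = 1e-4
    wd_initial_epochs: int = 5
    wd_r: Optional[float] = None
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    expansion_ratio: float = 10.0
    sparsity: float = 0.0
    momentum: float = 0.0
    r_init: str = "random"

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.algorithm not in MODES:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.lr_r is not None and self.lr_r < 0:
            raise ValueError("lr_r must be >= 0")
        for g in (self.wd_initial, self.wd_main):
            if not 0.0 <= g < 1.0:
                raise ValueError("weight decay must lie in [0, 1)")
        if self.wd_r is not None and not 0.0 <= self.wd_r < 1.0:
            raise ValueError("wd_r must lie in [0, 1)")
        if self.expansion_ratio < 1.0:
            raise ValueError("expansion_ratio must be >= 1")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.r_init not in ("random", "matched"):
            raise ValueError(f"unknown r_init {self.r_init!r}")

    @property
    def effective_lr_r(self) -> float:
        """Feedback learning rate; defaults to ``lr``, density-compensated.

        With a sparsity mask on R only a fraction ``1 - p`` of entries
        receive updates, so the plastic path's equilibrium norm gain falls
        to ``sqrt(1 - p)`` of the dense case.  The default feedback rate is
        therefore ``lr / sqrt(1 - p)`` (the same norm-preserving convention
        as the sparse feedback initialization); an explicit ``lr_r``
        overrides this.
        """
        if self.lr_r is not None:
            return self.lr_r
        return self.lr / (1.0 - self.sparsity) ** 0.5

    def decay_at(self, epoch: int) -> float:
        """Per-step W decay for a 1-based epoch (two-phase schedule)."""
        return self.wd_initial if epoch <= self.wd_initial_epochs else self.wd_main

    def decay_r_at(self, epoch: int) -> float:
        return self.decay_at(epoch) if self.wd_r is None else self.wd_r

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        """Load from a flat YAML mapping of field names to values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a flat key-value mapping")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def apply_mask(matrix, mask):
    """Entrywise mask; idempotent, and the identity when mask is None."""
    if mask is None:
        return matrix
    return matrix * mask


def _check_finite(g, what):
    if not np.all(np.isfinite(g)):
        raise DivergenceError(f"non-finite {what} update")


def update_W(layer: DenseLayer, e_next, lr, decay, x_l=None, velocity=None,
             momentum=0.0):
    """SGD step on a dense layer's W and b.

    ``e_next`` and the cached input must come from the same forward/backward
    pass; ``x_l`` may override the cache (tests).  With ``momentum`` > 0 a
    velocity buffer (same shape as W) accumulates the gradient.
    """
    x = layer.cached_input if x_l is None else np.atleast_2d(np.asarray(x_l, float))
    e = np.atleast_2d(np.asarray(e_next, dtype=float))
    batch = e.shape[0]
    gW = e.T @ x / batch
    gb = e.mean(axis=0)
    _check_finite(gW, "weight")
    if momentum > 0.0 and velocity is not None:
        velocity *= momentum
        velocity += gW
        gW = velocity
    layer.W = (1.0 - decay) * layer.W + lr * gW
    layer.b = layer.b + lr * gb


def update_R(fb: LayerFeedback, x_l, lr, decay, velocity=None, momentum=0.0):
    """SGD step on the plastic feedback of one hidden layer.

    Consumes the ``e_bar`` cached by the most recent backward pass of the
    same minibatch; re-applies the sparsity mask afterwards.
    """
    if fb.mode not in PRODUCT_MODES:
        raise ModeError(f"update_R does not apply to mode {fb.mode!r}")
    if fb.e_bar is None:
        raise ModeError("no cached intermediate error; run the backward pass first")
    x = np.atleast_2d(np.asarray(x_l, dtype=float))
    e_bar = np.atleast_2d(fb.e_bar)
    batch = e_bar.shape[0]
    g = x.T @ e_bar / batch
    _check_finite(g, "feedback")
    if momentum > 0.0 and velocity is not None:
        velocity *= momentum
        velocity += g
        g = velocity
    fb.R = apply_mask((1.0 - decay) * fb.R + lr * g, fb.mask_R)


def update_kp_feedback(fb: LayerFeedback, e_next, x_l, lr, decay):
    """Symmetric feedback update: the transpose of the W step, plus decay.

    KP is the product rule with ``B = I``, so the intermediate error equals
    ``e_{l+1}`` and this is exactly :func:`update_R`.
    """
    if fb.mode != "kp":
        raise ModeError(f"update_kp_feedback does not apply to mode {fb.mode!r}")
    fb.e_bar = np.atleast_2d(np.asarray(e_next, dtype=float))
    update_R(fb, x_l, lr, decay)
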