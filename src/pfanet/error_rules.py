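"""Backward error-propagation rules: BP, FA, DFA, SF, KP, PFA, PFA-o.

Every rule maps the error at layer ``l+1`` (or the output error, for DFA) to
the error at layer ``l``:

* BP      ``e_l = sigma'(z_l) . (W^T e_{l+1})`` -- requires weight transport.
* FA      ``e_l = sigma'(z_l) . (B_fa e_{l+1})`` with fixed random ``B_fa``.
* DFA     ``e_l = sigma'(z_l) . (B_dfa e_L)`` projecting the output error.
* SF      like FA but ``B_sf = sign(W^T) * c_l`` recomputed from the current
          forward weights every backward pass (sign transport).
* PFA     two-factor backward path through an expanded intermediate
          population: ``e_bar = B e_{l+1}``, ``e_l = sigma'(z_l) . (R e_bar)``
          with ``B`` fixed random (entries ~ N(0, 1/n_bar)) and ``R`` plastic.
* PFA-o   PFA with ``B`` semi-orthogonal (``B^T B = I``).
* KP      PFA with ``B = I`` (no expansion); the plastic matrix receives the
          transpose of the forward update, driving it to ``W^T``.

The composed backward path ``R B`` is what aligns with ``W^T`` during
training; no single synapse is ever required to mirror a forward weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import conv_net, randmat
from .core_net import DenseLayer, ErrorStack, Network
from .conv_net import ConvLayer
from .exceptions import DimensionError, ModeError

MODES = ("bp", "fa", "dfa", "sf", "kp", "pfa", "pfa_o")
PRODUCT_MODES = ("kp", "pfa", "pfa_o")
CONV_MODES = ("bp", "fa", "pfa", "pfa_o")


# ---------------------------------------------------------------------------
# dense rule kernels (activation gating applied by the caller via sigma_prime)
# ---------------------------------------------------------------------------

def error_bp(W, sigma_prime, e_next):
    """``sigma' . (W^T e_{l+1})`` -- the chain-rule error."""
    return sigma_prime * (e_next @ W).reshape(sigma_prime.shape)


def error_fa(B_fa, sigma_prime, e_next):
    """Error through a fixed random feedback matrix ``B_fa`` (n_l, n_{l+1})."""
    return sigma_prime * (e_next @ B_fa.T).reshape(sigma_prime.shape)


def error_dfa(B_dfa, sigma_prime, e_output):
    """Project the *output* error straight to layer ``l``."""
    return sigma_prime * (e_output @ B_dfa.T).reshape(sigma_prime.shape)


def sf_feedback(W, mask=None):
    """Sign-concordant feedback ``sign(W^T) * c`` with ``c = mean|W|``.

    A sparsity mask rescales the surviving entries so the feedback norm is
    unchanged in expectation (same convention as the random feedback inits).
    """
    c = float(np.mean(np.abs(W)))
    B = np.sign(W.T) * c
    if mask is not None:
        density = mask.mean()
        B = B * mask / math.sqrt(density) if density > 0 else B * mask
    return B


def error_sf(W, sigma_prime, e_next, mask=None):
    """Sign-transport error; feedback rebuilt from the current W each pass."""
    B = sf_feedback(W, mask)
    return error_fa(B, sigma_prime, e_next), B


def error_pfa(B, R, sigma_prime, e_next):
    """Two-factor error: returns ``(e_bar, e_l)``; ``e_bar`` feeds the R update."""
    e_bar = e_next @ B.T
    e_l = sigma_prime * (e_bar @ R.T).reshape(sigma_prime.shape)
    return e_bar, e_l


# ---------------------------------------------------------------------------
# feedback state
# ---------------------------------------------------------------------------

@dataclass
class LayerFeedback:
    """Feedback structures serving one hidden layer ``l``.

    Which fields are populated depends on the mode; ``e_bar`` is the cached
    intermediate error of the most recent backward pass (product modes only),
    consumed by the R update of the same minibatch.
    """

    mode: str
    conv: bool = False
    B: Optional[np.ndarray] = None        # fixed (n_bar, n_{l+1}); never trained
    R: Optional[np.ndarray] = None        # plastic (n_l, n_bar) / conv kernel
    B_fa: Optional[np.ndarray] = None     # FA fixed feedback
    B_dfa: Optional[np.ndarray] = None    # DFA fixed feedback (n_l, n_L)
    mask_B: Optional[np.ndarray] = None
    mask_R: Optional[np.ndarray] = None
    mask_sf: Optional[np.ndarray] = None
    e_bar: Optional[np.ndarray] = None
    expansion_ratio: float = 1.0


@dataclass
class FeedbackState:
    """Per-hidden-layer feedback structures for a whole network."""

    mode: str
    layers: Dict[int, LayerFeedback] = field(default_factory=dict)

    @classmethod
    def for_network(cls, net: Network, mode: str, expansion_ratio: float = 10.0,
                    sparsity: float = 0.0, rng=None, r_init: str = "random"):
        """Build feedback for every hidden layer of ``net``.

        ``r_init='matched'`` sets ``R_0 = W_0^T B^T`` (dense) or its channel
        analogue (conv), which together with a semi-orthogonal ``B`` makes the
        product path reproduce backprop exactly for the whole run.
        """
        if mode not in MODES:
            raise ModeError(f"unknown algorithm mode {mode!r}")
        if not 0.0 <= sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if expansion_ratio < 1.0:
            raise ValueError("expansion_ratio must be >= 1")
        if r_init not in ("random", "matched"):
            raise ValueError(f"unknown r_init {r_init!r}")
        rng = np.random.default_rng(rng)
        fb = cls(mode=mode)
        if mode == "bp":
            return fb
        L = net.depth
        out_layer = net.layers[-1]
        if not isinstance(out_layer, DenseLayer) and mode == "dfa":
            raise ModeError("dfa requires a dense output layer")
        n_L = out_layer.n_out

        def mask_like(shape):
            if sparsity == 0.0:
                return None
            return (rng.random(shape) >= sparsity).astype(float)

        # Sparse feedback is rescaled so its expected squared norm (and for
        # the product rule E[B^T B] = I, the premise of the alignment
        # mechanism) is unchanged by the mask.
        scale = 1.0 / math.sqrt(1.0 - sparsity)

        for l in range(1, L):
            upper = net.layers[l]
            if isinstance(upper, ConvLayer):
                if mode not in CONV_MODES:
                    raise ModeError(
                        f"mode {mode!r} is not defined for convolutional layers"
                    )
                fb.layers[l] = _conv_layer_feedback(
                    upper, mode, expansion_ratio, mask_like, rng, r_init,
                    scale)
                continue
            n_l, n_next = upper.n_in, upper.n_out
            lf = LayerFeedback(mode=mode)
            if mode in ("fa", "sf"):
                if mode == "fa":
                    lf.B_fa = rng.normal(0.0, 1.0 / math.sqrt(n_next),
                                         size=(n_l, n_next))
                    m = mask_like(lf.B_fa.shape)
                    if m is not None:
                        lf.B_fa *= m * scale
                    lf.mask_B = m
                else:
                    lf.mask_sf = mask_like((n_l, n_next))
            elif mode == "dfa":
                lf.B_dfa = rng.normal(0.0, 1.0 / math.sqrt(n_L),
                                      size=(n_l, n_L))
                m = mask_like(lf.B_dfa.shape)
                if m is not None:
                    lf.B_dfa *= m * scale
                lf.mask_B = m
            else:  # product modes
                if mode == "kp":
                    n_bar = n_next
                    lf.B = np.eye(n_next)
                elif mode == "pfa_o":
                    n_bar = math.ceil(expansion_ratio * n_next)
                    lf.B = randmat.init_semi_orthogonal(n_bar, n_next, rng)
                else:
                    n_bar = math.ceil(expansion_ratio * n_next)
                    lf.B = randmat.init_iid_feedback(n_bar, n_next, rng)
                lf.expansion_ratio = n_bar / n_next
                if mode != "kp":
                    m = mask_like(lf.B.shape)
                    if m is not None:
                        lf.B *= m * scale
                    lf.mask_B = m
                if r_init == "matched":
                    lf.R = upper.W.T @ lf.B.T
                else:
                    # variance 1/n_l gives the composed path R B unit norm
                    # gain at init (norm ratio 1, like BP), matching the
                    # fan-based convention used for the other feedback inits
                    lf.R = rng.normal(0.0, 1.0 / math.sqrt(n_l),
                                      size=(n_l, n_bar))
                lf.mask_R = mask_like(lf.R.shape)
                if lf.mask_R is not None:
                    lf.R *= lf.mask_R * scale
            fb.layers[l] = lf
        return fb


def _conv_layer_feedback(upper: ConvLayer, mode, expansion_ratio, mask_like,
                         rng, r_init, scale=1.0):
    c_out, c_in, kh, kw = upper.W.shape
    lf = LayerFeedback(mode=mode, conv=True)
    if mode == "fa":
        lf.B_fa = rng.normal(0.0, 1.0 / math.sqrt(c_out * kh * kw),
                             size=upper.W.shape)
        m = mask_like(lf.B_fa.shape)
        if m is not None:
            lf.B_fa *= m * scale
        lf.mask_B = m
        return lf
    if mode in ("pfa", "pfa_o"):
        n_bar = math.ceil(expansion_ratio * c_out)
        if mode == "pfa_o":
            lf.B = randmat.init_semi_orthogonal(n_bar, c_out, rng)
        else:
            lf.B = randmat.init_iid_feedback(n_bar, c_out, rng)
        lf.expansion_ratio = n_bar / c_out
        m = mask_like(lf.B.shape)
        if m is not None:
            lf.B *= m * scale
        lf.mask_B = m
        if r_init == "matched":
            lf.R = np.einsum("ki,ichw->kchw", lf.B, upper.W)
        else:
            # unit backward norm gain at init (conv analogue of var 1/n_l)
            lf.R = rng.normal(0.0, 1.0 / math.sqrt(c_in * kh * kw),
                              size=(n_bar, c_in, kh, kw))
        lf.mask_R = mask_like(lf.R.shape)
        if lf.mask_R is not None:
            lf.R *= lf.mask_R * scale
        return lf
    raise ModeError(f"mode {mode!r} is not defined for convolutional layers")


# ---------------------------------------------------------------------------
# backward orchestrator
# ---------------------------------------------------------------------------

def backward(net: Network, feedback: FeedbackState, e_L, loss=float("nan")):
    """Propagate the output error down the network under the configured mode.

    Returns an :class:`ErrorStack` with ``e[l]`` for ``l = 1..L``.  For
    product modes the intermediate errors ``e_bar`` are cached on the
    corresponding :class:`LayerFeedback` for the R update.
    """
    L = net.depth
    e_L = np.asarray(e_L, dtype=float)
    if e_L.ndim == 1:
        e_L = e_L[None, :]
    stack = ErrorStack(e={L: e_L}, loss=loss)
    mode = feedback.mode
    for l in range(L - 1, 0, -1):
        below = net.layers[l - 1]
        upper = net.layers[l]
        sp = below.sigma_prime()
        e_next = stack.e[l + 1]
        if isinstance(upper, ConvLayer):
            if mode == "bp":
                raw = conv_net.error_bp_conv(upper, e_next)
            elif mode == "fa":
                lf = feedback.layers[l]
                raw = conv_net.error_fa_conv(upper, lf.B_fa, e_next)
            elif mode in ("pfa", "pfa_o"):
                lf = feedback.layers[l]
                lf.e_bar, raw = conv_net.error_pfa_conv(upper, lf.B, lf.R,
                                                        e_next)
            else:
                raise ModeError(
                    f"mode {mode!r} is not defined for convolutional layers"
                )
            stack.e[l] = sp * raw
            continue
        if isinstance(below, ConvLayer) and e_next.ndim > 2:
            raise DimensionError("dense error above a conv layer must be 2-d")
        if mode == "bp":
            stack.e[l] = error_bp(upper.W, sp, e_next)
        elif mode == "fa":
            stack.e[l] = error_fa(feedback.layers[l].B_fa, sp, e_next)
        elif mode == "dfa":
            stack.e[l] = error_dfa(feedback.layers[l].B_dfa, sp, e_L)
        elif mode == "sf":
            stack.e[l], _ = error_sf(upper.W, sp, e_next,
                                     feedback.layers[l].mask_sf)
        else:
            lf = feedback.layers[l]
            lf.e_bar, stack.e[l] = error_pfa(lf.B, lf.R, sp, e_next)
    return stack
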