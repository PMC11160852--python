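"""Convolutional layers: forward pass, error propagation, and updates.

Internal layout is ``(batch, channel, height, width)`` for feature maps and
``(out_channels, in_channels, kh, kw)`` for kernels.  The backward rules reuse
one primitive, :func:`conv_input_grad`, which is the transposed convolution
(input-gradient) of the forward operator; the 180-degree kernel flip of the
textbook formulation is implicit in that primitive.

Feedback structure for the product rule (PFA): the fixed matrix ``B`` is a
1x1 channel-mixing kernel, stored as a plain ``(n_bar, out_channels)`` matrix
and applied pixelwise at the upper layer's spatial resolution, so the
intermediate error ``e_bar`` has the same spatial size as ``e_{l+1}``.  The
plastic kernel ``R`` has the forward kernel's spatial extent and carries all
of its stride/padding/dilation, applied through the same transposed-conv
primitive, so the resulting error lands at the lower layer's resolution.
"""

from __future__ import annotations

import numpy as np

from .core_net import ACTIVATIONS
from .exceptions import DimensionError, StateError


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def conv_output_size(size, k, stride, pad, dil):
    eff = dil * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def _im2col(x, kh, kw, stride, pad, dil):
    """Unfold ``x`` (b, c, H, W) into columns (b, c*kh*kw, oh*ow)."""
    b, c, H, W = x.shape
    sh, sw = _pair(stride)
    ph, pw = _pair(pad)
    dh, dw = _pair(dil)
    oh = conv_output_size(H, kh, sh, ph, dh)
    ow = conv_output_size(W, kw, sw, pw, dw)
    if oh < 1 or ow < 1:
        raise DimensionError(
            f"kernel ({kh}x{kw}, stride {stride}, pad {pad}, dilation {dil}) "
            f"does not fit input {H}x{W}"
        )
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dh, j * dw
            cols[:, :, i, j] = xp[:, :, ii:ii + sh * oh:sh, jj:jj + sw * ow:sw]
    return cols.reshape(b, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols, input_hw, kh, kw, stride, pad, dil):
    """Scatter-add inverse of :func:`_im2col`; returns (b, c, H, W)."""
    H, W = input_hw
    sh, sw = _pair(stride)
    ph, pw = _pair(pad)
    dh, dw = _pair(dil)
    oh = conv_output_size(H, kh, sh, ph, dh)
    ow = conv_output_size(W, kw, sw, pw, dw)
    b = cols.shape[0]
    c = cols.shape[1] // (kh * kw)
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    xp = np.zeros((b, c, H + 2 * ph, W + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dh, j * dw
            xp[:, :, ii:ii + sh * oh:sh, jj:jj + sw * ow:sw] += cols[:, :, i, j]
    return xp[:, :, ph:ph + H, pw:pw + W]


def conv_forward_raw(x, W, b=None, stride=1, pad=0, dil=1):
    """Cross-correlation forward pass (deep-learning convention).

    ``x``: (batch, c_in, H, W); ``W``: (c_out, c_in, kh, kw).
    Returns preactivation maps (batch, c_out, oh, ow).
    """
    c_out, c_in, kh, kw = W.shape
    if x.shape[1] != c_in:
        raise DimensionError(
            f"conv expects {c_in} input channels, got {x.shape[1]}"
        )
    cols, (oh, ow) = _im2col(x, kh, kw, stride, pad, dil)
    z = np.einsum("ok,bkl->bol", W.reshape(c_out, -1), cols)
    z = z.reshape(x.shape[0], c_out, oh, ow)
    if b is not None:
        z = z + b[None, :, None, None]
    return z


def conv_input_grad(e_out, K, input_hw, stride=1, pad=0, dil=1):
    """Transposed convolution: propagate ``e_out`` back through kernel ``K``.

    ``e_out``: (batch, c_out, oh, ow); ``K``: (c_out, c_in, kh, kw).
    Returns (batch, c_in, H, W) at the lower layer's resolution ``input_hw``.
    Equivalent to correlating with the 180-degree-flipped, channel-transposed
    kernel.
    """
    c_out, c_in, kh, kw = K.shape
    if e_out.shape[1] != c_out:
        raise DimensionError(
            f"error has {e_out.shape[1]} channels but kernel maps {c_out}"
        )
    b, _, oh, ow = e_out.shape
    cols = np.einsum("ok,bol->bkl", K.reshape(c_out, -1), e_out.reshape(b, c_out, oh * ow))
    return _col2im(cols, input_hw, kh, kw, stride, pad, dil)


def conv_weight_grad(x, e_out, kernel_shape, stride=1, pad=0, dil=1):
    """Kernel gradient: correlate the cached input with the error map.

    Summed over spatial positions, averaged over the batch.  Returns an array
    of ``kernel_shape`` = (c_out, c_in, kh, kw); the bias gradient is the
    per-channel error mean times the number of spatial positions summed --
    returned separately by the update functions.
    """
    c_out, c_in, kh, kw = kernel_shape
    cols, (oh, ow) = _im2col(x, kh, kw, stride, pad, dil)
    b = x.shape[0]
    g = np.einsum("bol,bkl->ok", e_out.reshape(b, c_out, oh * ow), cols) / b
    return g.reshape(kernel_shape)


class ConvLayer:
    """A 2-d convolutional layer ``x -> sigma(W * x + b)``.

    Kernels are stored ``(out_channels, in_channels, kh, kw)``.  ``groups``
    other than 1 are not supported.
    """

    def __init__(self, W, b, activation="relu", stride=1, padding=0,
                 dilation=1, groups=1):
        W = np.asarray(W, dtype=float)
        b = np.asarray(b, dtype=float)
        if W.ndim != 4:
            raise DimensionError(f"conv kernel must be 4-d, got shape {W.shape}")
        if b.shape != (W.shape[0],):
            raise DimensionError(
                f"bias shape {b.shape} does not match out channels {W.shape[0]}"
            )
        if groups != 1:
            raise DimensionError("only groups=1 convolutions are supported")
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.W = W
        self.b = b
        self.activation = activation
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        self.cached_input = None
        self.cached_pre = None

    @property
    def n_in(self) -> int:
        return self.W.shape[1]

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    @property
    def kernel_hw(self):
        return self.W.shape[2], self.W.shape[3]

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim != 4:
            raise DimensionError(
                f"conv input must be (batch, channel, h, w); got shape {x.shape}"
            )
        z = conv_forward_raw(x, self.W, self.b, self.stride, self.padding,
                             self.dilation)
        self.cached_input = x
        self.cached_pre = z
        return ACTIVATIONS[self.activation][0](z)

    def sigma_prime(self):
        if self.cached_pre is None:
            raise StateError("forward pass has not been run; no cached preactivation")
        return ACTIVATIONS[self.activation][1](self.cached_pre)


def _input_hw(layer):
    if layer.cached_input is None:
        raise StateError("conv backward requires a cached forward pass")
    return layer.cached_input.shape[2], layer.cached_input.shape[3]


def error_bp_conv(layer: ConvLayer, e_next):
    """Backprop error through a conv layer (before activation gating)."""
    return conv_input_grad(e_next, layer.W, _input_hw(layer), layer.stride,
                           layer.padding, layer.dilation)


def error_fa_conv(layer: ConvLayer, B_fa, e_next):
    """Fixed-random-kernel error propagation.

    ``B_fa`` has the forward kernel's shape and is applied through the same
    transposed-conv operator, so ``B_fa = W`` reproduces backprop exactly.
    """
    if B_fa.shape != layer.W.shape:
        raise DimensionError(
            f"feedback kernel shape {B_fa.shape} != forward kernel {layer.W.shape}"
        )
    return conv_input_grad(e_next, B_fa, _input_hw(layer), layer.stride,
                           layer.padding, layer.dilation)


def error_pfa_conv(layer: ConvLayer, B, R, e_next):
    """Product-feedback error for a conv layer.

    ``B``: (n_bar, c_out) channel mixer applied pixelwise; ``R``:
    (n_bar, c_in, kh, kw) plastic kernel carrying W's hyperparameters.
    Returns ``(e_bar, raw_e)`` where ``e_bar`` is at the upper layer's
    resolution and ``raw_e`` at the lower layer's (activation gating is
    applied by the caller).
    """
    if B.shape[1] != e_next.shape[1]:
        raise DimensionError(
            f"B mixes {B.shape[1]} channels but error has {e_next.shape[1]}"
        )
    e_bar = np.einsum("ki,bihw->bkhw", B, e_next)
    raw = conv_input_grad(e_bar, R, _input_hw(layer), layer.stride,
                          layer.padding, layer.dilation)
    return e_bar, raw


def update_conv_W(layer: ConvLayer, e_next, lr, decay):
    """SGD step on the conv kernel and bias with multiplicative decay."""
    g = conv_weight_grad(layer.cached_input, e_next, layer.W.shape,
                         layer.stride, layer.padding, layer.dilation)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite conv weight update")
    layer.W = (1.0 - decay) * layer.W + lr * g
    layer.b = layer.b + lr * e_next.sum(axis=(2, 3)).mean(axis=0)


def update_conv_R(layer: ConvLayer, R, e_bar, lr, decay, mask=None):
    """SGD step on the plastic feedback kernel ``R`` (returned, not in place)."""
    g = conv_weight_grad(layer.cached_input, e_bar,
                         (R.shape[0],) + R.shape[1:], layer.stride,
                         layer.padding, layer.dilation)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite conv feedback update")
    R = (1.0 - decay) * R + lr * g
    if mask is not None:
        R = R * mask
    return R
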