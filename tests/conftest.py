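"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized kernels: the
forward oracle is explicit Python loops over matrix entries, convolution is
direct nested-loop correlation, and gradients come from central finite
differences of the loss.  Tests compare the package against these.
"""

import numpy as np
import pytest

from pfanet.core_net import ACTIVATIONS, DenseLayer, Network, output_error


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dense_net(rng, sizes=None, activation="relu", out_activation="identity"):
    """Small random network with LeCun-scaled weights and random biases."""
    if sizes is None:
        depth = int(rng.integers(2, 4))
        sizes = [int(rng.integers(2, 6)) for _ in range(depth + 1)]
    layers = []
    for k in range(len(sizes) - 1):
        W = rng.normal(0, 1.0 / np.sqrt(sizes[k]), size=(sizes[k + 1], sizes[k]))
        b = rng.normal(0, 0.1, size=sizes[k + 1])
        act = activation if k < len(sizes) - 2 else out_activation
        layers.append(DenseLayer(W, b, act))
    return Network(layers)


def loop_forward(net, x0):
    """Forward pass with explicit loops (single sample)."""
    x = np.array(x0, dtype=float)
    for layer in net.layers:
        z = np.zeros(layer.n_out)
        for i in range(layer.n_out):
            acc = layer.b[i]
            for j in range(layer.n_in):
                acc += layer.W[i, j] * x[j]
            z[i] = acc
        x = ACTIVATIONS[layer.activation][0](z)
    return x


def forward_from(net, l, x_l):
    """Forward through layers l..L-1 without touching caches (fresh copies)."""
    x = x_l
    for layer in net.layers[l:]:
        z = x @ layer.W.T + layer.b
        x = ACTIVATIONS[layer.activation][0](z)
    return x


def fd_error_stack(net, x0, y, eps=1e-6):
    """Per-layer errors -dL/dz_l by central finite differences (batched).

    The error recursion e_l = sigma'(z_l) . (feedback of e_{l+1}) carries
    gradients with respect to *preactivations*, so the oracle perturbs z_l
    and re-applies the producing layer's activation before forwarding on.
    """
    stacks = {}
    x = np.atleast_2d(np.asarray(x0, float))
    pres = [None]
    acts = [x]
    for layer in net.layers:
        z = acts[-1] @ layer.W.T + layer.b
        pres.append(z)
        acts.append(ACTIVATIONS[layer.activation][0](z))
    for l in range(1, len(net.layers) + 1):
        act_fn = ACTIVATIONS[net.layers[l - 1].activation][0]
        zl = pres[l]
        g = np.zeros_like(zl)
        for idx in np.ndindex(zl.shape):
            zp = zl.copy()
            zp[idx] += eps
            lp, _ = output_error(forward_from(net, l, act_fn(zp)), y)
            zm = zl.copy()
            zm[idx] -= eps
            lm, _ = output_error(forward_from(net, l, act_fn(zm)), y)
            # output_error returns the batch mean; undo the averaging so the
            # finite difference matches per-sample errors
            g[idx] = -(lp - lm) / (2 * eps) * zl.shape[0]
        stacks[l] = g
    return stacks


def fd_weight_grad(net, x0, y, layer_idx, eps=1e-6):
    """-dL/dW for one layer by central differences (batch-mean loss)."""
    layer = net.layers[layer_idx]
    g = np.zeros_like(layer.W)
    for idx in np.ndindex(layer.W.shape):
        orig = layer.W[idx]
        layer.W[idx] = orig + eps
        lp, _ = output_error(net.forward(x0), y)
        layer.W[idx] = orig - eps
        lm, _ = output_error(net.forward(x0), y)
        layer.W[idx] = orig
        g[idx] = -(lp - lm) / (2 * eps)
    net.forward(x0)  # restore caches
    return g


def loop_conv2d(x, K, stride=1, pad=0, dil=1):
    """Direct nested-loop cross-correlation; x (c_in, H, W), K (c_out, c_in, kh, kw)."""
    c_out, c_in, kh, kw = K.shape
    H, W = x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (H + 2 * pad - dil * (kh - 1) - 1) // stride + 1
    ow = (W + 2 * pad - dil * (kw - 1) - 1) // stride + 1
    out = np.zeros((c_out, oh, ow))
    for o in range(c_out):
        for yy in range(oh):
            for xx in range(ow):
                acc = 0.0
                for c in range(c_in):
                    for i in range(kh):
                        for j in range(kw):
                            acc += K[o, c, i, j] * xp[c, yy * stride + i * dil,
                                                      xx * stride + j * dil]
                out[o, yy, xx] = acc
    return out


def relative_error(a, b):
    denom = max(np.abs(b).max(), 1e-12)
    return np.abs(a - b).max() / denom
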