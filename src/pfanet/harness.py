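"""Training loop and experiment orchestration.

One master seed drives named substreams (weights / feedback / data order),
so e.g. switching algorithm does not perturb the data shuffles.
The per-minibatch schedule is: forward -> output error -> backward under the
configured rule -> W/b updates (plus R for product modes), all from the same
pass's caches; metrics are recorded at epoch end; the test set is touched by
the forward pass only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core_net import DenseLayer, Network, output_error
from .conv_net import ConvLayer, update_conv_W, update_conv_R
from .error_rules import FeedbackState, backward, PRODUCT_MODES
from .exceptions import DivergenceError
from .metrics import layer_metrics
from .tasks import LabeledDataset
from .updates import TrainConfig, update_W, update_R

_STREAMS = {"weights": 0, "feedback": 1, "mask": 2, "data": 3, "shuffle": 4}


def seed_stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random stream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


def build_dense_network(layer_sizes: Sequence[int], activation: str = "relu",
                        rng=None) -> Network:
    """Fully connected net; hidden activations as given, identity read-out.

    Weights are Gaussian with variance ``1/n_in`` (LeCun scaling), biases 0.
    """
    rng = np.random.default_rng(rng)
    layers = []
    for k in range(len(layer_sizes) - 1):
        n_in, n_out = layer_sizes[k], layer_sizes[k + 1]
        W = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_out, n_in))
        act = activation if k < len(layer_sizes) - 2 else "identity"
        layers.append(DenseLayer(W, np.zeros(n_out), act))
    return Network(layers)


def build_conv_network(image_size: int, in_channels: int, n_classes: int,
                       conv_channels: Sequence[int] = (8,), kernel: int = 3,
                       activation: str = "relu", rng=None) -> Network:
    """Small conv stack (same-padding 3x3 convs) with a dense read-out head."""
    rng = np.random.default_rng(rng)
    layers = []
    c_prev = in_channels
    for c in conv_channels:
        W = rng.normal(0.0, 1.0 / math.sqrt(c_prev * kernel * kernel),
                       size=(c, c_prev, kernel, kernel))
        layers.append(ConvLayer(W, np.zeros(c), activation, stride=1,
                                padding=kernel // 2))
        c_prev = c
    flat = c_prev * image_size * image_size
    Wd = rng.normal(0.0, 1.0 / math.sqrt(flat), size=(n_classes, flat))
    layers.append(DenseLayer(Wd, np.zeros(n_classes), "identity"))
    return Network(layers)


@dataclass
class RunResult:
    """Per-epoch record of one training run."""

    train_loss: List[float] = field(default_factory=list)
    test_acc: List[float] = field(default_factory=list)
    metrics: List[dict] = field(default_factory=list)
    config: Optional[TrainConfig] = None
    seed: int = 0

    @property
    def final_test_acc(self) -> float:
        return self.test_acc[-1] if self.test_acc else float("nan")

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics)


def evaluate(net: Network, X, y) -> float:
    """Classification accuracy of the forward pass (NaN on an empty set)."""
    if X.shape[0] == 0:
        return float("nan")
    return float(np.mean(net.forward(X).argmax(axis=1) == np.asarray(y)))


def train(net: Network, feedback: FeedbackState, dataset: LabeledDataset,
          config: TrainConfig) -> RunResult:
    """Run the configured algorithm over the dataset; returns the epoch log.

    Raises :class:`DivergenceError` (reporting the last epoch that finished
    with a finite loss) if the loss or any update goes non-finite.
    """
    rng_shuffle = seed_stream(config.seed, "shuffle")
    result = RunResult(config=config, seed=config.seed)
    n = dataset.n_train
    mode = feedback.mode
    lr_r = config.effective_lr_r
    step = 0
    velocities = {}
    if config.momentum > 0.0:
        for k, layer in enumerate(net.layers):
            velocities[(k, "W")] = np.zeros_like(layer.W)
        for l, lf in feedback.layers.items():
            if lf.R is not None:
                velocities[(l, "R")] = np.zeros_like(lf.R)

    for epoch in range(1, config.epochs + 1):
        gamma = config.decay_at(epoch)
        gamma_r = config.decay_r_at(epoch)
        order = rng_shuffle.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = dataset.X_train[idx], dataset.y_train[idx]
            try:
                logits = net.forward(xb)
                loss, e_L = output_error(logits, yb)
                finite = np.isfinite(loss)
            except ValueError as err:  # overflowed weights or logits
                if "non-finite" not in str(err):
                    raise
                finite = False
            if not finite:
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}, step {step}",
                    step=step, last_good_epoch=epoch - 1)
            stack = backward(net, feedback, e_L, loss)
            try:
                for l in range(1, net.depth + 1):
                    layer = net.layers[l - 1]
                    e_l = stack.e[l]
                    x_l = layer.cached_input
                    if isinstance(layer, ConvLayer):
                        update_conv_W(layer, e_l, config.lr, gamma)
                    else:
                        update_W(layer, e_l.reshape(e_l.shape[0], -1),
                                 config.lr, gamma,
                                 velocity=velocities.get((l - 1, "W")),
                                 momentum=config.momentum)
                    if mode in PRODUCT_MODES and l < net.depth and lr_r > 0:
                        lf = feedback.layers[l]
                        upper = net.layers[l]
                        if lf.conv:
                            lf.R = update_conv_R(upper, lf.R, lf.e_bar, lr_r,
                                                 gamma_r, lf.mask_R)
                        else:
                            update_R(lf, upper.cached_input, lr_r, gamma_r,
                                     velocity=velocities.get((l, "R")),
                                     momentum=config.momentum)
                    elif mode in PRODUCT_MODES and l < net.depth and gamma_r > 0:
                        # frozen-lr feedback still decays if asked to
                        lf = feedback.layers[l]
                        lf.R = (1.0 - gamma_r) * lf.R
            except DivergenceError as err:
                raise DivergenceError(
                    f"{err} (epoch {epoch}, step {step}, layer {l})",
                    layer=l, step=step, last_good_epoch=epoch - 1) from err
            losses.append(loss)
            step += 1
        result.train_loss.append(float(np.mean(losses)))
        acc = evaluate(net, dataset.X_test, dataset.y_test)
        result.test_acc.append(acc)
        for rec in layer_metrics(net, feedback, epoch=epoch):
            rec.update(seed=config.seed, train_loss=result.train_loss[-1],
                       test_acc=acc)
            result.metrics.append(rec)
    return result


def run_experiment(config: TrainConfig, dataset: LabeledDataset,
                   net: Optional[Network] = None,
                   feedback: Optional[FeedbackState] = None):
    """Build a seeded network + feedback for the dataset and train.

    Returns ``(net, feedback, RunResult)``.  Pre-built ``net``/``feedback``
    may be injected (reduction tests and custom architectures).
    """
    if net is None:
        d = dataset.X_train.shape[1:]
        if len(d) == 3:
            net = build_conv_network(d[1], d[0], dataset.n_classes,
                                     rng=seed_stream(config.seed, "weights"),
                                     activation=config.activation)
        else:
            sizes = [d[0], *config.hidden_sizes, dataset.n_classes]
            net = build_dense_network(sizes, config.activation,
                                      seed_stream(config.seed, "weights"))
    if feedback is None:
        fb_rng = seed_stream(config.seed, "feedback")
        feedback = FeedbackState.for_network(
            net, config.algorithm, config.expansion_ratio, config.sparsity,
            fb_rng, r_init=config.r_init)
    result = train(net, feedback, dataset, config)
    return net, feedback, result


def run_sparsity_sweep(config: TrainConfig, dataset: LabeledDataset,
                       sparsity_levels: Sequence[float],
                       algorithms: Sequence[str],
                       seeds: Sequence[int]) -> pd.DataFrame:
    """Final accuracy for each (algorithm, sparsity, seed) full run.

    Columns: algorithm, sparsity, seed, final_test_acc, final_train_loss.
    """
    import dataclasses

    rows = []
    for alg in algorithms:
        for p in sparsity_levels:
            for s in seeds:
                cfg = dataclasses.replace(config, algorithm=alg, sparsity=p,
                                          seed=s)
                _, _, res = run_experiment(cfg, dataset)
                rows.append({"algorithm": alg, "sparsity": p, "seed": s,
                             "final_test_acc": res.final_test_acc,
                             "final_train_loss": res.train_loss[-1]})
    return pd.DataFrame(rows)
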