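"""Canned desk-scale experiments.

These reproduce, on synthetic teacher-network data, the qualitative regimes
of the benchmark protocol: a 784-512-512-10 ReLU network trained by each
algorithm with expansion ratio 10, recording alignment angles and norm
ratios; the sparse-feedback comparison; and the synthetic convolutional
comparison.  Problem sizes are chosen so each experiment completes in
minutes on one CPU; see docs/methods.md for the exact sizes and why.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Sequence

import numpy as np

from .harness import run_experiment, run_sparsity_sweep
from .tasks import gen_conv_task, gen_teacher_task
from .updates import TrainConfig

#: Training protocol mirroring the benchmark study: 784-512-512-10 ReLU,
#: expansion ratio 10, two-phase weight decay (a large initial value that
#: wipes out the feedback initialization, then a small maintenance value).
PROTOCOL = TrainConfig(
    algorithm="pfa",
    hidden_sizes=(512, 512),
    activation="relu",
    lr=0.2,
    wd_initial=0.01,
    wd_initial_epochs=5,
    wd_main=5e-4,
    batch_size=64,
    epochs=15,
    expansion_ratio=10.0,
)


def alignment_protocol(seed: int = 0,
                       algorithms: Sequence[str] = ("pfa", "pfa_o", "fa", "sf"),
                       input_dim: int = 784, n_classes: int = 10,
                       n_samples: int = 6000,
                       config: TrainConfig = PROTOCOL) -> Dict[str, dict]:
    """Train each algorithm on one 784-dim teacher task; return end-of-run
    alignment diagnostics.

    Returns ``{algorithm: {"angle_deg": mean over hidden layers,
    "angles": per-layer list, "norm_ratio": mean, "norm_ratios": list,
    "final_test_acc": float, "final_train_loss": float}}``.
    """
    data = gen_teacher_task(input_dim, n_classes, n_samples, teacher_depth=1,
                            seed=seed)
    out = {}
    for alg in algorithms:
        cfg = dataclasses.replace(config, algorithm=alg, seed=seed + 1)
        _, _, res = run_experiment(cfg, data)
        mf = res.metrics_frame()
        last = mf[mf.epoch == mf.epoch.max()]
        out[alg] = {
            "angle_deg": float(last.angle_deg.mean()),
            "angles": last.angle_deg.tolist(),
            "norm_ratio": float(last.norm_ratio.mean()),
            "norm_ratios": last.norm_ratio.tolist(),
            "final_test_acc": res.final_test_acc,
            "final_train_loss": res.train_loss[-1],
        }
    return out


def sparsity_experiment(seed: int = 0, sparsity: float = 0.9,
                        algorithms: Sequence[str] = ("pfa", "fa"),
                        n_seeds: int = 5):
    """Mean final accuracy of each algorithm at one feedback sparsity level.

    Scaled-down analogue of the sparse-feedback comparison: a two-hidden-
    layer (32-32) network on a 10-class nonlinear (depth-2) teacher task,
    trained to plateau.  The narrow top layer makes sparse per-layer
    feedback lose whole units (a 32 x 10 feedback matrix at 90% sparsity
    leaves ~1/3 of units with no feedback at all), which is the regime in
    which the expanded intermediate population's redundancy pays off.

    Returns the tidy sweep frame plus ``{algorithm: mean final accuracy}``.
    """
    cfg = dataclasses.replace(
        PROTOCOL, hidden_sizes=(32, 32), lr=0.1, epochs=40,
        wd_initial=5e-3, wd_main=5e-4)
    data = gen_teacher_task(32, 10, 6000, teacher_depth=2, seed=seed,
                            teacher_hidden=64)
    frame = run_sparsity_sweep(cfg, data, [sparsity], algorithms,
                               list(range(seed + 1, seed + 1 + n_seeds)))
    means = frame.groupby("algorithm")["final_test_acc"].mean().to_dict()
    return frame, means


def conv_comparison(seed: int = 0, algorithms: Sequence[str] = ("bp", "pfa", "fa"),
                    epochs: int = 4) -> Dict[str, float]:
    """Final training loss of each algorithm on the synthetic conv task."""
    data = gen_conv_task(8, 1, 2, 1200, seed=seed)
    out = {}
    for alg in algorithms:
        cfg = TrainConfig(algorithm=alg, epochs=epochs, seed=seed + 1, lr=0.05,
                          batch_size=32, expansion_ratio=4.0,
                          wd_initial=1e-3, wd_main=1e-4, wd_initial_epochs=2)
        _, _, res = run_experiment(cfg, data)
        out[alg] = res.train_loss[-1]
    return out
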