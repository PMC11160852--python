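"""Dataset generation and I/O.

Synthetic supervised tasks are produced by fixed random *teacher* networks:
inputs are i.i.d. standard Gaussian (hence already standardized to mean 0,
variance 1) and labels are the argmax of the teacher's output, optionally
corrupted by uniform label noise.  Zero teacher biases keep the classes close
to balanced by symmetry.  Everything is bit-reproducible from the seed.

MNIST is read from IDX files on disk (idx3-ubyte images, idx1-ubyte labels,
optionally gzipped); the library never downloads anything -- see the CLI's
fetch helper for obtaining the files.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .conv_net import conv_forward_raw
from .core_net import relu
from .exceptions import FormatError

IDX_MAGIC_IMAGES = 0x00000803
IDX_MAGIC_LABELS = 0x00000801


@dataclass
class LabeledDataset:
    """Supervised classification data with a train/test split.

    ``X_*`` are ``(n, d)`` float arrays for dense tasks or
    ``(n, c, h, w)`` for image tasks; labels are integers in
    ``[0, n_classes)``.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    n_classes: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    @property
    def n_test(self) -> int:
        return self.X_test.shape[0]

    def to_columnar(self, path) -> None:
        """Dump the train split as a plain CSV (label, then features)."""
        X = self.X_train.reshape(self.n_train, -1)
        out = np.column_stack([self.y_train, X])
        header = "label," + ",".join(f"x{i}" for i in range(X.shape[1]))
        np.savetxt(path, out, delimiter=",", header=header, comments="")


def _split(X, y, n_classes, test_fraction, rng, provenance):
    n = X.shape[0]
    n_test = int(round(test_fraction * n))
    perm = rng.permutation(n)
    te, tr = perm[:n_test], perm[n_test:]
    return LabeledDataset(X[tr], y[tr], X[te], y[te], n_classes, provenance)


def gen_teacher_task(input_dim: int, n_classes: int, n_samples: int,
                     teacher_depth: int = 1, noise_rate: float = 0.0,
                     seed: int = 0, test_fraction: float = 0.25,
                     teacher_hidden: Optional[int] = None) -> LabeledDataset:
    """Classification task labeled by a fixed random dense teacher network.

    ``teacher_depth`` counts weight layers; depth 1 is a linear teacher
    (linearly separable classes up to margin), deeper teachers use tanh
    hidden layers.  ``noise_rate`` resamples that fraction of labels
    uniformly at random.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    X = rng.standard_normal((n_samples, input_dim))
    h = teacher_hidden or max(2 * input_dim, 16)
    sizes = [input_dim] + [h] * (teacher_depth - 1) + [n_classes]
    out = X
    for k in range(teacher_depth):
        W = rng.normal(0.0, 1.0 / np.sqrt(sizes[k]), size=(sizes[k + 1], sizes[k]))
        out = out @ W.T
        if k < teacher_depth - 1:
            out = np.tanh(out)
    y = out.argmax(axis=1)
    if noise_rate > 0.0:
        flip = rng.random(n_samples) < noise_rate
        y = np.where(flip, rng.integers(0, n_classes, size=n_samples), y)
    prov = {"kind": "synthetic", "seed": seed, "teacher_depth": teacher_depth,
            "input_dim": input_dim, "noise_rate": noise_rate}
    return _split(X, y, n_classes, test_fraction, rng, prov)


def gen_conv_task(image_size: int = 8, n_channels: int = 1, n_classes: int = 2,
                  n_samples: int = 1000, seed: int = 0,
                  test_fraction: float = 0.25,
                  teacher_channels: int = 4) -> LabeledDataset:
    """Small images labeled by a fixed random convolutional teacher.

    The teacher is conv(3x3, same padding) -> relu -> global average pool ->
    linear read-out; labels are the read-out argmax.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    X = rng.standard_normal((n_samples, n_channels, image_size, image_size))
    K = rng.normal(0.0, 1.0 / np.sqrt(n_channels * 9),
                   size=(teacher_channels, n_channels, 3, 3))
    V = rng.normal(0.0, 1.0 / np.sqrt(teacher_channels),
                   size=(n_classes, teacher_channels))
    maps = relu(conv_forward_raw(X, K, None, stride=1, pad=1))
    pooled = maps.mean(axis=(2, 3))
    y = (pooled @ V.T).argmax(axis=1)
    prov = {"kind": "synthetic_conv", "seed": seed, "image_size": image_size}
    return _split(X, y, n_classes, test_fraction, rng, prov)


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic2 = fh.read(2)
    if magic2 == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_idx(path, expected_magic, n_dims):
    with _open_maybe_gzip(path) as fh:
        head = fh.read(4 + 4 * n_dims)
        if len(head) < 4 + 4 * n_dims:
            raise FormatError(f"{path}: truncated IDX header at byte {len(head)}")
        magic = struct.unpack(">I", head[:4])[0]
        if magic != expected_magic:
            raise FormatError(
                f"{path}: bad magic 0x{magic:08x} at byte 0 "
                f"(expected 0x{expected_magic:08x})"
            )
        dims = struct.unpack(f">{n_dims}I", head[4:])
        count = int(np.prod(dims))
        payload = fh.read(count)
        if len(payload) != count:
            raise FormatError(
                f"{path}: truncated payload at byte {4 + 4 * n_dims + len(payload)} "
                f"(expected {count} bytes)"
            )
        if fh.read(1):
            raise FormatError(f"{path}: trailing bytes after declared payload")
    return np.frombuffer(payload, dtype=np.uint8).reshape(dims)


def read_mnist_idx(images_path, labels_path, flatten: bool = True) -> LabeledDataset:
    """Read one (images, labels) IDX pair into a dataset.

    Images are scaled to [0, 1] and flattened to length ``h*w`` unless
    ``flatten=False`` (then returned as ``(n, 1, h, w)``).  All samples land
    in the train split; see :func:`load_mnist` for the standard two-file
    train/test layout.
    """
    images = _read_idx(images_path, IDX_MAGIC_IMAGES, 3)
    labels = _read_idx(labels_path, IDX_MAGIC_LABELS, 1)
    if images.shape[0] != labels.shape[0]:
        raise FormatError(
            f"count mismatch: {images.shape[0]} images vs {labels.shape[0]} labels"
        )
    X = images.astype(float) / 255.0
    X = X.reshape(X.shape[0], -1) if flatten else X[:, None, :, :]
    y = labels.astype(int)
    empty_X = X[:0]
    return LabeledDataset(X, y, empty_X, y[:0], n_classes=10,
                          provenance={"kind": "mnist", "images": str(images_path),
                                      "labels": str(labels_path)})


MNIST_FILES = {
    "train": ("train-images-idx3-ubyte", "train-labels-idx1-ubyte"),
    "test": ("t10k-images-idx3-ubyte", "t10k-labels-idx1-ubyte"),
}


def load_mnist(directory, flatten: bool = True) -> LabeledDataset:
    """Load the standard four-file MNIST layout (plain or .gz) from a directory."""
    directory = Path(directory)

    def find(stem):
        for cand in (directory / stem, directory / (stem + ".gz")):
            if cand.exists():
                return cand
        raise FileNotFoundError(f"{stem}[.gz] not found under {directory}")

    tr = read_mnist_idx(find(MNIST_FILES["train"][0]),
                        find(MNIST_FILES["train"][1]), flatten)
    te = read_mnist_idx(find(MNIST_FILES["test"][0]),
                        find(MNIST_FILES["test"][1]), flatten)
    return LabeledDataset(tr.X_train, tr.y_train, te.X_train, te.y_train,
                          n_classes=10,
                          provenance={"kind": "mnist", "dir": str(directory)})
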