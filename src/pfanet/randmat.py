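"""Feedback-matrix initializations and Marchenko-Pastur analysis of B^T B.

The product backward path approximates backprop when ``B^T B`` is close to
the identity.  Two constructions are provided:

* i.i.d. Gaussian entries with mean 0 and variance ``1/n_bar`` -- then
  ``B^T B`` is a Wishart-type matrix whose eigenvalue density follows the
  Marchenko-Pastur law with aspect ratio ``lam = n_cols / n_bar``; as the
  expansion ratio ``1/lam`` grows the spectrum concentrates at 1.
* semi-orthogonal ``B`` (QR of a Gaussian matrix), for which ``B^T B = I``
  holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import DimensionError


def init_iid_feedback(n_rows: int, n_cols: int, rng=None) -> np.ndarray:
    """Gaussian feedback matrix, entries i.i.d. ``N(0, 1/n_rows)``.

    ``n_rows`` is the intermediate-population size ``n_bar``; with this
    variance ``E[B^T B] = I``.
    """
    rng = np.random.default_rng(rng)
    return rng.normal(0.0, 1.0 / math.sqrt(n_rows), size=(n_rows, n_cols))


def init_semi_orthogonal(n_rows: int, n_cols: int, rng=None) -> np.ndarray:
    """Semi-orthogonal matrix with ``B^T B = I`` (n_rows >= n_cols).

    Columns are an orthonormal basis of a Haar-random subspace: QR of a
    Gaussian matrix with the sign of R's diagonal folded into Q.
    """
    if n_rows < n_cols:
        raise DimensionError(
            f"semi-orthogonality needs n_rows >= n_cols; got {n_rows} < {n_cols}"
        )
    rng = np.random.default_rng(rng)
    G = rng.normal(size=(n_rows, n_cols))
    Q, R = np.linalg.qr(G)
    return Q * np.sign(np.diag(R))


def mp_support(lam: float) -> Tuple[float, float]:
    """Support edges ``(1 -+ sqrt(lam))**2`` of the Marchenko-Pastur law."""
    if not 0.0 < lam <= 1.0:
        raise ValueError("aspect ratio lam must lie in (0, 1]")
    s = math.sqrt(lam)
    return (1.0 - s) ** 2, (1.0 + s) ** 2


def mp_density(v, lam: float):
    """Marchenko-Pastur density ``sqrt((l+ - v)(v - l-)) / (2 pi lam v)``.

    Zero outside the support; vectorized in ``v``.
    """
    lo, hi = mp_support(lam)
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    inside = (v >= lo) & (v <= hi) & (v > 0)
    vi = v[inside]
    out[inside] = np.sqrt((hi - vi) * (vi - lo)) / (2.0 * math.pi * lam * vi)
    return out if out.ndim else float(out)


@dataclass
class SpectrumResult:
    """Empirical spectrum of ``B^T B`` with its analytic MP envelope."""

    eigenvalues: np.ndarray          # sorted ascending, length n_cols
    lam: float                       # aspect ratio n_cols / n_rows
    support_edges: Tuple[float, float]
    density: Callable[[np.ndarray], np.ndarray]

    def fraction_in_support(self, slack: float = 0.0) -> float:
        lo, hi = self.support_edges
        ev = self.eigenvalues
        return float(np.mean((ev >= lo - slack) & (ev <= hi + slack)))


def empirical_spectrum(B: np.ndarray) -> SpectrumResult:
    """Eigenvalues of ``B^T B`` paired with the MP support for B's aspect ratio."""
    B = np.asarray(B, dtype=float)
    n_rows, n_cols = B.shape
    lam = n_cols / n_rows
    ev = np.sort(np.linalg.eigvalsh(B.T @ B))
    return SpectrumResult(eigenvalues=ev, lam=lam,
                          support_edges=mp_support(lam),
                          density=lambda v: mp_density(v, lam))


def spectrum_sweep(n_cols: int, ratios: Sequence[float], n_seeds: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Eigenvalues of ``B^T B`` across expansion ratios (tidy frame).

    Columns: ratio, seed, eigenvalue.
    """
    rows = []
    for ratio in ratios:
        for s in range(n_seeds):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(ratio * 1000), s)))
            B = init_iid_feedback(math.ceil(ratio * n_cols), n_cols, rng)
            for ev in np.linalg.eigvalsh(B.T @ B):
                rows.append({"ratio": ratio, "seed": s, "eigenvalue": ev})
    return pd.DataFrame(rows)


def path_alignment_vs_ratio(n_out: int = 200, n_in: int = 100,
                            ratios: Sequence[float] = (1, 2, 5, 10, 50),
                            n_seeds: int = 20, seed: int = 0) -> pd.DataFrame:
    """Alignment angle of the construction ``R^T = B W`` across ratios.

    For a random forward matrix ``W`` and i.i.d. feedback ``B``, setting
    ``R = W^T B^T`` (the fixed point the plastic feedback is driven to once
    initial conditions have decayed) gives a backward path
    ``R B = W^T B^T B``; its angle to ``W^T`` shrinks as ``B^T B``
    concentrates at the identity, i.e. as the expansion ratio grows.

    Columns: ratio, seed, angle_deg.
    """
    from .metrics import alignment_angle

    rows = []
    for ratio in ratios:
        n_bar = math.ceil(ratio * n_out)
        for s in range(n_seeds):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(int(ratio * 1000), s)))
            W = rng.normal(size=(n_out, n_in))
            B = init_iid_feedback(n_bar, n_out, rng)
            path = (W.T @ B.T) @ B
            rows.append({"ratio": ratio, "seed": s,
                         "angle_deg": alignment_angle(W.T, path)})
    return pd.DataFrame(rows)
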