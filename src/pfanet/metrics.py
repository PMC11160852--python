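"""Alignment diagnostics: weight/path alignment angles and norm ratios.

*Weight alignment* (FA, SF) is the angle between the vectorized transpose of
the forward weights and the vectorized feedback matrix.  *Path alignment*
(KP, PFA, PFA-o) uses the composed backward path ``R B`` instead; 0 degrees
means a backprop-equivalent pathway.  The *norm ratio*
``||backward||_F / ||W^T||_F`` tracks the risk of exploding or vanishing
error signals; 1 is the backprop-like ideal.
"""

from __future__ import annotations

import math
from typing import List, Optional

import numpy as np

from .core_net import Network
from .conv_net import ConvLayer
from .error_rules import FeedbackState, sf_feedback
from .exceptions import UndefinedAngleError


def alignment_angle(a, b) -> float:
    """Angle in degrees between two arrays, vectorized.

    Symmetric and invariant to positive rescaling of either argument.
    Raises :class:`UndefinedAngleError` for a zero-norm operand rather than
    silently returning 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise UndefinedAngleError(
            f"operands have {a.size} and {b.size} entries; angles are only "
            "defined between same-shaped weight structures"
        )
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedAngleError("alignment angle undefined for zero-norm operand")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return math.degrees(math.acos(c))


def path_matrix(R, B) -> np.ndarray:
    """Composed dense backward path ``R B`` of shape (n_l, n_{l+1})."""
    return R @ B


def compose_path_conv(R, B) -> np.ndarray:
    """Effective conv backward kernel: contract R (n_bar, c_in, kh, kw)
    with the 1x1 channel mixer B (n_bar, c_out) over the intermediate axis.

    The result has the forward kernel's shape (c_out, c_in, kh, kw) and,
    used as a fixed feedback kernel, reproduces the product rule's error
    exactly; compared entrywise with ``W`` it yields the conv path alignment
    (0 degrees for a backprop-equivalent path).
    """
    return np.einsum("ki,kchw->ichw", B, R)


def norm_ratio(backward, forward_T) -> float:
    """Frobenius norm quotient ``||backward|| / ||W^T||``."""
    f = np.linalg.norm(np.asarray(forward_T, dtype=float))
    if f == 0.0:
        raise UndefinedAngleError("norm ratio undefined for zero forward weights")
    return float(np.linalg.norm(np.asarray(backward, dtype=float)) / f)


def layer_metrics(net: Network, feedback: FeedbackState,
                  epoch: Optional[int] = None) -> List[dict]:
    """Per-hidden-layer alignment angle and norm ratio for the current state.

    For DFA the per-layer feedback projects the output error, so it is not
    shape-comparable with ``W^T``; both diagnostics are recorded as NaN.
    A zero-norm feedback (e.g. fully masked) also records NaN rather than
    aborting a run.
    """
    records = []
    mode = feedback.mode
    for l in range(1, net.depth):
        upper = net.layers[l]
        conv = isinstance(upper, ConvLayer)
        if mode == "bp":
            angle, ratio = 0.0, 1.0
        elif mode == "dfa":
            angle, ratio = float("nan"), float("nan")
        elif mode in ("fa", "sf"):
            lf = feedback.layers[l]
            if mode == "fa":
                Bm = lf.B_fa
            else:
                Bm = sf_feedback(upper.W, lf.mask_sf)
                if conv:
                    raise NotImplementedError("sf is dense-only")
            # conv FA kernels live in the forward orientation already
            target = upper.W if conv else upper.W.T
            back = Bm
            try:
                angle = alignment_angle(target, back)
                ratio = norm_ratio(back, target)
            except UndefinedAngleError:
                angle, ratio = float("nan"), float("nan")
        else:
            lf = feedback.layers[l]
            if conv:
                back = compose_path_conv(lf.R, lf.B)
                target = upper.W
            else:
                back = path_matrix(lf.R, lf.B)
                target = upper.W.T
            try:
                angle = alignment_angle(target, back)
                ratio = norm_ratio(back, target)
            except UndefinedAngleError:
                angle, ratio = float("nan"), float("nan")
        rec = {"layer": l, "algorithm": mode, "angle_deg": angle,
               "norm_ratio": ratio}
        if epoch is not None:
            rec["epoch"] = epoch
        records.append(rec)
    return records
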