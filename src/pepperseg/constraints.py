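"""Physical plausibility constraints on the learned transmittance curve.

A fabricable optical filter cannot transmit negative light and should not
oscillate wildly between adjoining wavelengths.  Two mechanisms enforce this
during optimization:

* a smoothness penalty ``L_smooth = ||G W||_2^2`` where ``G`` is the second
  difference matrix on the band index grid, and
* projected gradient descent: after every optimizer update the weights are
  clamped at zero.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["second_difference_matrix", "smoothness_penalty", "project_nonnegative"]


def second_difference_matrix(n_bands: int) -> np.ndarray:
    """(n-2) x n matrix with rows (..., 1, -2, 1, ...); annihilates affine curves."""
    if n_bands < 3:
        raise ValueError("second differences need at least 3 bands")
    g = np.zeros((n_bands - 2, n_bands))
    idx = np.arange(n_bands - 2)
    g[idx, idx] = 1.0
    g[idx, idx + 1] = -2.0
    g[idx, idx + 2] = 1.0
    return g


def smoothness_penalty(weights, g_matrix: np.ndarray | None = None):
    """Squared 2-norm of the second differences of the curve.

    Accepts a plain array, a :class:`~pepperseg.optics.TransmittanceCurve`, or
    an autodiff :class:`Tensor` (in which case the result is a differentiable
    scalar Tensor).  Zero iff the curve is affine on the index grid; no
    normalization by the band count — the loss weight eta absorbs scale.
    """
    w = weights.weights if hasattr(weights, "weights") else weights
    n = w.shape[0] if isinstance(w, Tensor) else np.asarray(w).shape[0]
    if g_matrix is None:
        g_matrix = second_difference_matrix(n)
    if g_matrix.shape[1] != n:
        raise ValueError(f"G is {g_matrix.shape} but the curve has {n} bands")
    if isinstance(w, Tensor):
        d = g_matrix @ w
        return (d * d).sum()
    d = g_matrix @ np.asarray(w, dtype=np.float64)
    return float(d @ d)


def project_nonnegative(weights):
    """Clamp weights at zero (idempotent).  Arrays are returned as a new array;
    Tensors are projected in place on ``.data`` (the projected-gradient step)."""
    if isinstance(weights, Tensor):
        np.maximum(weights.data, 0.0, out=weights.data)
        return weights
    if hasattr(weights, "weights"):  # TransmittanceCurve
        weights.weights = np.maximum(weights.weights, 0.0)
        return weights
    return np.maximum(np.asarray(weights, dtype=np.float64), 0.0)
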