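"""Sliding-window parabola regression engine.

Within a window of ``m = 2w + 1`` samples centered at index ``i``, the
signal fragment ``y(j)``, ``j = i-w ... i+w``, is approximated by a
vertex-centered parabola

    y'(j) = a (i - j)^2 + v

whose opening coefficient ``a`` and vertex value ``v`` are the ordinary
least-squares solution of the simple regression of ``y`` on the single
regressor ``x = (i - j)^2``.  The quadratic-mean fit error

    eps(i) = mean over the window of (y(j) - y'(j))^2

is small where a symmetric extremum sits at the window center: its local
minima are the candidate peak locations, and the sign and magnitude of
``a`` separate maxima (a < 0), minima (a > 0) and near-linear stretches
(|a| ~ 0).

Units: with samples in mV and the regressor in samples^2, ``a`` is in
mV/sample^2, so fixed thresholds on ``a`` are specific to a sampling rate
and gain.  The published defaults hold for mV-scaled 500 Hz signals; for
another rate fs they rescale as ``a_threshold * (fs / 500)^2``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import EcgSignal

__all__ = [
    "WindowFit",
    "FitProfile",
    "fit_parabola_window",
    "error_profile",
    "r_window_halfwidth",
    "pqrst_window_halfwidth",
]


@dataclass(frozen=True)
class WindowFit:
    """Parabola fit at one window center.

    ``a`` opens the parabola (mV/sample^2; negative at a local maximum),
    ``v`` is the vertex amplitude (mV) and ``epsilon`` the quadratic-mean
    residual (mV^2) over the ``2w + 1`` window samples.
    """

    center: int
    a: float
    v: float
    epsilon: float


@dataclass
class FitProfile:
    """Per-center parabola fits for every admissible window center.

    Centers run consecutively over ``w ... N - w - 1`` (length ``N - 2w``);
    fields are stored as parallel arrays for speed, with item access
    returning a :class:`WindowFit`.
    """

    centers: np.ndarray
    a: np.ndarray
    v: np.ndarray
    epsilon: np.ndarray
    w: int

    def __len__(self) -> int:
        return self.centers.size

    def __getitem__(self, k: int) -> WindowFit:
        return WindowFit(
            center=int(self.centers[k]),
            a=float(self.a[k]),
            v=float(self.v[k]),
            epsilon=float(self.epsilon[k]),
        )


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def r_window_halfwidth(fs: float) -> int:
    """Half-width w = round(0.030 * fs) of the R-detection window.

    0.030 s is roughly the half-duration of the R deflection within a
    normal 70-100 ms QRS complex.  At fs = 500 Hz this gives w = 15, a
    31-sample window.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    return max(1, _round_half_away(0.030 * fs))


def pqrst_window_halfwidth(fs: float) -> int:
    """Half-width w = round(0.012 * fs) of the narrow small-wave window.

    Sized to the shortest wave (Q, about 20-30 ms); at fs = 500 Hz this
    gives w = 6, a 13-sample window.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    return max(1, _round_half_away(0.012 * fs))


def _regressor(w: int) -> np.ndarray:
    """x(j) = (i - j)^2 over a window, identical for every center."""
    d = np.arange(-w, w + 1, dtype=np.float64)
    return d * d


def fit_parabola_window(signal: EcgSignal, center: int, w: int) -> WindowFit:
    """Least-squares vertex-centered parabola over one window.

    Closed-form simple-regression solution for ``(a, v)`` with regressor
    ``x = (center - j)^2``; ``epsilon`` is the mean squared residual.

    Raises
    ------
    ValueError
        If ``w < 1``, the window does not fit in the signal, or the
        center is not an admissible index.
    """
    y = signal.samples
    n = y.size
    if w < 1:
        raise ValueError("half-width w must be >= 1")
    if 2 * w + 1 >= n:
        raise ValueError(f"window of {2 * w + 1} samples exceeds signal length {n}")
    if not (w <= center <= n - w - 1):
        raise ValueError(f"center {center} outside admissible range [{w}, {n - w - 1}]")

    x = _regressor(w)
    yw = y[center - w : center + w + 1]
    m = 2 * w + 1
    sx = x.sum()
    sxx = (x * x).sum()
    sy = yw.sum()
    sxy = (x * yw).sum()
    denom = m * sxx - sx * sx
    a = (m * sxy - sx * sy) / denom
    v = (sxx * sy - sxy * sx) / denom
    resid = yw - (a * x + v)
    epsilon = float(np.mean(resid * resid))
    return WindowFit(center=center, a=float(a), v=float(v), epsilon=epsilon)


def error_profile(signal: EcgSignal, w: int) -> FitProfile:
    """Parabola fit and error at every admissible center.

    Vectorized equivalent of calling :func:`fit_parabola_window` at each
    center ``i`` in ``w ... N - w - 1``; the two paths agree to machine
    precision because both evaluate the same closed-form sums.
    """
    y = signal.samples
    n = y.size
    if w < 1:
        raise ValueError("half-width w must be >= 1")
    if 2 * w + 1 >= n:
        raise ValueError(f"signal too short ({n} samples) for window of {2 * w + 1}")

    x = _regressor(w)
    m = 2 * w + 1
    sx = x.sum()
    sxx = (x * x).sum()
    denom = m * sxx - sx * sx

    windows = np.lib.stride_tricks.sliding_window_view(y, m)  # (n - 2w, m)
    sy = windows.sum(axis=1)
    sxy = windows @ x
    a = (m * sxy - sx * sy) / denom
    v = (sxx * sy - sxy * sx) / denom
    resid = windows - a[:, None] * x[None, :] - v[:, None]
    epsilon = np.mean(resid * resid, axis=1)

    centers = np.arange(w, n - w, dtype=np.int64)
    return FitProfile(centers=centers, a=a, v=v, epsilon=epsilon, w=w)
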