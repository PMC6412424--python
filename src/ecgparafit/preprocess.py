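"""Noise filtering and baseline-wander removal.

Two stages: a Butterworth low-pass (default order 10, 100 Hz cutoff — the
upper edge of the diagnostic ECG band) applied zero-phase so peak
positions do not shift, followed by subtraction of a least-squares
polynomial (default order 8) that tracks the slow baseline wander from
respiration and electrode drift.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import EcgSignal

__all__ = [
    "FilterSpec",
    "BaselineModel",
    "lowpass_filter",
    "fit_baseline",
    "remove_baseline",
    "preprocess",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    ``zero_phase`` selects forward-backward application (no group delay);
    the effective attenuation is then that of a filter of twice the order.
    """

    order: int = 10
    cutoff: float = 100.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class BaselineModel:
    """Least-squares polynomial baseline.

    ``coefficients`` are in descending powers of the *normalized* sample
    index ``index / N`` (length ``order + 1``); normalization keeps the
    order-8 Vandermonde system well conditioned on 10^4-sample records.
    """

    coefficients: np.ndarray
    order: int
    n_samples: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order + 1:
            raise ValueError("coefficient length must equal order + 1")

    def evaluate(self) -> np.ndarray:
        """Baseline values at every sample index of the fitted domain."""
        u = np.arange(self.n_samples) / self.n_samples
        return np.polyval(self.coefficients, u)


def lowpass_filter(signal: EcgSignal, spec: FilterSpec | None = None) -> EcgSignal:
    """Apply a Butterworth low-pass filter; same length and fs.

    Zero-phase by default (scipy ``sosfiltfilt`` with even-reflection
    padding to suppress startup transients).  Raises ``ValueError`` if the
    cutoff reaches the Nyquist frequency.
    """
    spec = spec or FilterSpec()
    nyq = signal.fs / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype="lowpass", fs=signal.fs, output="sos")
    if spec.zero_phase:
        padlen = min(signal.samples.size - 1, 3 * (2 * spec.order + 1))
        out = sps.sosfiltfilt(sos, signal.samples, padtype="even", padlen=padlen)
    else:
        out = sps.sosfilt(sos, signal.samples)
    return signal.replace_samples(out)


def fit_baseline(signal: EcgSignal, order: int = 8) -> BaselineModel:
    """Least-squares polynomial of the given order over sample index.

    The fit minimizes the residual sum of squares among all polynomials of
    that order (ordinary polynomial regression on the normalized index).
    """
    n = signal.samples.size
    if order < 0:
        raise ValueError("order must be >= 0")
    if order >= n - 1:
        raise ValueError(f"order {order} too high for {n} samples")
    u = np.arange(n) / n
    coeffs = np.polynomial.polynomial.polyfit(u, signal.samples, deg=order)
    # polyfit returns ascending powers; store descending for np.polyval
    return BaselineModel(coefficients=coeffs[::-1].copy(), order=order, n_samples=n)


def remove_baseline(signal: EcgSignal, model: BaselineModel) -> EcgSignal:
    """Subtract the fitted polynomial baseline from the signal."""
    if model.n_samples != signal.samples.size:
        raise ValueError("baseline model was fitted on a different index domain")
    return signal.replace_samples(signal.samples - model.evaluate())


def preprocess(
    signal: EcgSignal,
    filter_spec: FilterSpec | None = None,
    baseline_order: int | None = 8,
) -> EcgSignal:
    """Standard conditioning chain: low-pass filter, then baseline removal.

    ``baseline_order=None`` skips the baseline stage.
    """
    out = lowpass_filter(signal, filter_spec)
    if baseline_order is not None:
        out = remove_baseline(out, fit_baseline(out, baseline_order))
    return out
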