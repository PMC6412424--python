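"""Core value types shared across the package.

``EcgSignal`` is the uniformly sampled single-lead voltage sequence every
operation consumes; ``FiducialAnnotation`` is one labeled peak (P, Q, R, S
or T) at a sample index.  Indices are 0-based; time in seconds is
``index / fs``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical fiducial labels in within-beat temporal order.
LABELS = ("P", "Q", "R", "S", "T")


@dataclass
class EcgSignal:
    """A uniformly sampled ECG voltage sequence.

    Parameters
    ----------
    samples : array-like of float
        Voltage samples in millivolt.
    fs : float
        Sampling frequency in Hz, strictly positive.
    record_id : str, optional
        Free-text record label carried through I/O and annotations.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (N / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "EcgSignal":
        """Return a copy of this signal with new samples, same fs and id."""
        return EcgSignal(samples=samples, fs=self.fs, record_id=self.record_id)


@dataclass(frozen=True, order=True)
class FiducialAnnotation:
    """One labeled fiducial peak.

    Sorted by ``index`` first so lists of annotations order temporally.
    ``amplitude`` is the fitted vertex value *v* at detection time (mV); for
    synthetic ground truth it is the rendered noiseless sample value.
    """

    index: int
    label: str = field(compare=False)
    amplitude: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown fiducial label {self.label!r}")
        if self.index < 0:
            raise ValueError("annotation index must be non-negative")

    def time_s(self, fs: float) -> float:
        return self.index / fs
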