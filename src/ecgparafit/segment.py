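"""Beat segmentation: fixed-width windows centered on interior R peaks.

The window is sized from the mean R-R interval: half-width
``round(mean_rr / 2)`` samples on each side of R, window length
``2 * half + 1``.  The first and last detected R serve only as references
for the start and end of the segmentation, so a record with K detected R
peaks yields K - 2 beats.
"""
from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np

from .core import _round_half_away
from .types import EcgSignal

__all__ = ["BeatMatrix", "mean_rr", "segmentation_window", "segment_beats"]


@dataclass
class BeatMatrix:
    """Equal-length beat windows stacked row-wise.

    ``beats`` has shape (n_beats, window_length); ``r_offset`` is the
    index of R within every row (== half_width); ``source_r_indices`` are
    the absolute R sample indices each row is centered on; ``padded``
    flags rows that overran the record edge and were zero-padded.
    """

    beats: np.ndarray
    window_length: int
    half_width: int
    r_offset: int
    source_r_indices: np.ndarray
    padded: np.ndarray
    fs: float

    def __len__(self) -> int:
        return self.beats.shape[0]

    def beat_signal(self, k: int, record_id: str = "") -> EcgSignal:
        """Row ``k`` as an :class:`EcgSignal` (for per-beat delineation)."""
        return EcgSignal(samples=self.beats[k], fs=self.fs, record_id=record_id)

    def to_delimited(self, path: str | PathLike) -> None:
        """Write one beat per row, comma-separated, for inspection."""
        np.savetxt(path, self.beats, delimiter=",", fmt="%.9g")


def mean_rr(r_indices) -> float:
    """Arithmetic mean of consecutive R-R distances, in samples."""
    r = np.asarray(r_indices, dtype=np.float64)
    if r.size < 2:
        raise ValueError("need at least 2 R peaks to compute a mean R-R interval")
    d = np.diff(r)
    if np.any(d <= 0):
        raise ValueError("R indices must be strictly increasing")
    return float(np.mean(d))


def segmentation_window(mean_rr_samples: float) -> tuple[int, int]:
    """Half-width and window length from the mean R-R spacing.

    half = round(mean_rr / 2) (halves away from zero), length = 2*half+1;
    e.g. a mean spacing of 384.28 samples gives (192, 385).
    """
    if not mean_rr_samples > 0:
        raise ValueError("mean R-R spacing must be positive")
    half = max(1, _round_half_away(mean_rr_samples / 2.0))
    return half, 2 * half + 1


def segment_beats(
    signal: EcgSignal,
    r_indices,
    half_width: int | None = None,
) -> BeatMatrix:
    """Extract one fixed-width window per interior R peak.

    The first and last R are excluded (segmentation references).  Windows
    that overrun the record edge — possible with irregular rhythm — are
    zero-padded on the overrunning side and flagged in ``padded``.
    """
    r = np.asarray(r_indices, dtype=np.int64)
    if r.size < 3:
        raise ValueError("need at least 3 R peaks to segment beats")
    if half_width is None:
        half_width, _ = segmentation_window(mean_rr(r))
    length = 2 * half_width + 1
    interior = r[1:-1]
    n = len(signal)
    beats = np.zeros((interior.size, length))
    padded = np.zeros(interior.size, dtype=bool)
    for k, ri in enumerate(interior):
        lo, hi = ri - half_width, ri + half_width + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        beats[k, src_lo - lo : src_hi - lo] = signal.samples[src_lo:src_hi]
        padded[k] = lo < 0 or hi > n
    return BeatMatrix(
        beats=beats,
        window_length=length,
        half_width=half_width,
        r_offset=half_width,
        source_r_indices=interior.copy(),
        padded=padded,
        fs=signal.fs,
    )
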