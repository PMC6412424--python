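"""Fiducial-point detection from parabola-fit error profiles.

R peaks are found where the error signal eps(i) of the wide (31-sample at
500 Hz) window has a strict local minimum and the opening coefficient is
strongly negative (|a| above a fixed limit, a < 0 for an upward peak).
The isoelectric level is the mean signal value over centers where the fit
is both flat (|a| small) and good (eps small) — i.e. where the parabola
degenerates to a horizontal line.  Small waves (P, Q, S, T) are found in
per-beat windows with the narrow 13-sample window, gated by amplitude
margins around the isoelectric level, and labeled by their position
relative to R.

Thresholds on ``a`` are in mV/sample^2 and therefore tied to a sampling
rate and gain; defaults hold for mV-scaled 500 Hz signals and rescale as
``(fs / 500)^2`` elsewhere (see :mod:`ecgparafit.core`).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (
    FitProfile,
    error_profile,
    pqrst_window_halfwidth,
    r_window_halfwidth,
)
from .types import EcgSignal, FiducialAnnotation

__all__ = [
    "DetectorConfig",
    "FiducialAnnotation",
    "find_error_minima",
    "detect_r_peaks",
    "estimate_isoelectric_level",
    "detect_pqrst",
]

SignFilter = Literal["max", "min", "either"]


@dataclass
class DetectorConfig:
    """Tunable detector thresholds.

    Attributes
    ----------
    a_min_r : float
        Minimum |a| (mV/sample^2) for an error minimum to count as an R
        candidate; default 5e-4, separating the steep R apex from the
        broader P and T waves at 500 Hz.
    a_max_iso : float
        Maximum |a| for a center to count as isoelectric (flat); 1e-4.
    eps_max_iso : float
        Maximum eps (mV^2) for an isoelectric center; 0.01.
    a_min_small : float
        Minimum |a| for small-wave (P/Q/S/T) candidates with the narrow
        window; default 1e-4, below the fitted curvature of the broad T
        wave (~3e-4 in the default morphology) but above flat stretches.
    upper_margin, lower_margin : float
        Amplitude gates (mV) around the isoelectric level: maxima must
        rise above iso + upper_margin, minima fall below
        iso - lower_margin.  Set slightly inside the smallest rendered
        positive and negative wave excursions (P ~ 0.13 mV up after
        residual baseline variation; Q ~ 0.07 mV down — the dip is
        partially filled by the R upstroke, hence the asymmetry).
        Data-dependent; adjust per recording chain.
    min_peak_distance_ms : float
        Refractory distance between same-polarity small-wave detections;
        40 ms, below the shortest physiologic inter-fiducial gap.
    r_refractory_ms : float
        Minimum R-R distance (200 ms, a 300 bpm ceiling), guarding
        against double detection on notched R waves.
    sensitivity_tolerance_ms : float
        Temporal tolerance used by the evaluation metric; 10 ms.
    """

    a_min_r: float = 5e-4
    a_max_iso: float = 1e-4
    eps_max_iso: float = 0.01
    a_min_small: float = 1e-4
    upper_margin: float = 0.08
    lower_margin: float = 0.04
    min_peak_distance_ms: float = 40.0
    r_refractory_ms: float = 200.0
    sensitivity_tolerance_ms: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "a_min_r",
            "a_max_iso",
            "eps_max_iso",
            "a_min_small",
            "upper_margin",
            "lower_margin",
            "min_peak_distance_ms",
            "r_refractory_ms",
            "sensitivity_tolerance_ms",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.min_peak_distance_ms < self.r_refractory_ms:
            raise ValueError("min_peak_distance_ms must be below r_refractory_ms")


def find_error_minima(
    profile: FitProfile,
    a_magnitude_min: float,
    sign_filter: SignFilter = "either",
) -> np.ndarray:
    """Candidate peak centers: strict local minima of eps, filtered by a.

    A local minimum is the middle of a triplet eps[i-2] > eps[i-1] < eps[i];
    plateaus of equal values flanked by strictly larger neighbours report
    their leftmost index.  Candidates must additionally satisfy
    |a| > a_magnitude_min, and sign(a) must match ``sign_filter``
    ("max" keeps a < 0, i.e. upward peaks; "min" keeps a > 0).

    Returns absolute sample indices (window centers), possibly empty.
    """
    if len(profile) == 0:
        raise ValueError("empty fit profile")
    e = profile.epsilon
    if e.size < 3:
        return np.empty(0, dtype=np.int64)

    # run-length encode so plateaus act as single points (leftmost index)
    change = np.flatnonzero(np.diff(e) != 0) + 1
    starts = np.concatenate(([0], change))
    vals = e[starts]
    if starts.size < 3:
        return np.empty(0, dtype=np.int64)
    interior_min = (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:])
    pos = starts[1:-1][interior_min]

    a = profile.a[pos]
    keep = np.abs(a) > a_magnitude_min
    if sign_filter == "max":
        keep &= a < 0
    elif sign_filter == "min":
        keep &= a > 0
    elif sign_filter != "either":
        raise ValueError(f"unknown sign_filter {sign_filter!r}")
    return profile.centers[pos[keep]]


def _collapse_refractory(
    centers: np.ndarray, strength: np.ndarray, min_gap: int
) -> np.ndarray:
    """Greedy non-maximum suppression: strongest first, drop neighbours."""
    order = np.argsort(strength)[::-1]
    kept: list[int] = []
    for k in order:
        c = centers[k]
        if all(abs(c - centers[j]) >= min_gap for j in kept):
            kept.append(k)
    return np.sort(centers[kept])


def detect_r_peaks(
    signal: EcgSignal,
    config: DetectorConfig | None = None,
    profile: FitProfile | None = None,
) -> list[FiducialAnnotation]:
    """Detect R peaks over the whole (preprocessed) signal.

    Error-minimum candidates from the wide window with a < 0 and
    |a| > ``a_min_r``; candidates closer than ``r_refractory_ms`` are
    collapsed to the one with the largest |a|.  Returns annotations sorted
    by index; an empty list if nothing qualifies.
    """
    config = config or DetectorConfig()
    if profile is None:
        profile = error_profile(signal, r_window_halfwidth(signal.fs))
    cands = find_error_minima(profile, config.a_min_r, sign_filter="max")
    if cands.size == 0:
        return []
    pos = cands - profile.centers[0]
    strength = np.abs(profile.a[pos])
    min_gap = max(1, int(round(config.r_refractory_ms / 1000.0 * signal.fs)))
    kept = _collapse_refractory(cands, strength, min_gap)
    kpos = kept - profile.centers[0]
    return [
        FiducialAnnotation(index=int(c), label="R", amplitude=float(profile.v[p]))
        for c, p in zip(kept, kpos)
    ]


def estimate_isoelectric_level(
    signal: EcgSignal,
    config: DetectorConfig | None = None,
    profile: FitProfile | None = None,
) -> float:
    """Signal level over flat, well-fitted window centers.

    Centers qualify when |a| < ``a_max_iso`` and eps < ``eps_max_iso`` —
    the parabola has degenerated to a horizontal line, i.e. the window
    sits on the isoelectric line.  The level is the *median* of the
    qualifying samples: gentle wave flanks (the slow shoulders of T and
    P) slip through both gates and would bias a mean upward by tens of
    microvolt, while the median stays on the flat-segment majority.  If
    no center qualifies (a signal with no flat region) the overall
    signal median is returned with a warning.
    """
    config = config or DetectorConfig()
    if profile is None:
        profile = error_profile(signal, r_window_halfwidth(signal.fs))
    mask = (np.abs(profile.a) < config.a_max_iso) & (profile.epsilon < config.eps_max_iso)
    if not mask.any():
        warnings.warn(
            "no flat region found; falling back to signal median for the "
            "isoelectric level",
            stacklevel=2,
        )
        return float(np.median(signal.samples))
    return float(np.median(signal.samples[profile.centers[mask]]))


def detect_pqrst(
    beat: EcgSignal,
    r_index_in_beat: int,
    iso_level: float,
    config: DetectorConfig | None = None,
) -> list[FiducialAnnotation]:
    """Delineate P, Q, S and T around a known R within one beat window.

    Candidates come from the narrow-window error profile (both signs) and
    are snapped to the signal extremum within one half-width: against the
    steep QRS slopes the error minimum can sit a few samples off the
    actual apex of a narrow wave.  Maxima are kept when the signal rises
    above iso + ``upper_margin``, minima when it falls below
    iso - ``lower_margin``.  Candidates within one narrow half-width of R
    are discarded (they are the R apex itself), and same-polarity
    candidates closer than ``min_peak_distance_ms`` collapse to the
    larger excursion.  Labels are assigned relative to R:
    Q and S are the nearest minima before/after R, P and T the
    largest-amplitude maxima before Q / after S.  Waves failing the gates
    are simply absent — never mislabeled.

    Returns annotations (indices local to the beat) sorted by index,
    always including R.
    """
    config = config or DetectorConfig()
    n = len(beat)
    if not (0 <= r_index_in_beat < n):
        raise ValueError(f"r_index_in_beat {r_index_in_beat} outside beat of {n}")
    w = pqrst_window_halfwidth(beat.fs)
    out = [
        FiducialAnnotation(
            index=r_index_in_beat,
            label="R",
            amplitude=float(beat.samples[r_index_in_beat]),
        )
    ]
    if n <= 2 * w + 1 + 2:
        return out
    profile = error_profile(beat, w)
    cands = find_error_minima(profile, config.a_min_small, sign_filter="either")
    if cands.size == 0:
        return out
    pos = cands - profile.centers[0]
    a = profile.a[pos]
    is_max = a < 0

    # drop the R apex's own error minimum, then snap each candidate to the
    # signal extremum within +-w samples
    keep0 = np.abs(cands - r_index_in_beat) > w
    cands, a, is_max = cands[keep0], a[keep0], is_max[keep0]
    if cands.size == 0:
        return out
    snapped = np.empty_like(cands)
    for k, (c, mx) in enumerate(zip(cands, is_max)):
        lo, hi = max(0, c - w), min(n, c + w + 1)
        seg = beat.samples[lo:hi]
        snapped[k] = lo + (np.argmax(seg) if mx else np.argmin(seg))
    # two candidates snapping to one extremum collapse to a single one
    _, first = np.unique(snapped, return_index=True)
    cands, a, is_max = snapped[np.sort(first)], a[np.sort(first)], is_max[np.sort(first)]

    in_prof = (cands >= profile.centers[0]) & (cands <= profile.centers[-1])
    v = np.where(in_prof, profile.v[np.clip(cands - profile.centers[0], 0, len(profile) - 1)],
                 beat.samples[cands])
    value = beat.samples[cands]

    # amplitude gates against the rendered sample value at the apex: the
    # narrow-window vertex v underestimates sharp dips on the QRS slopes
    keep = (np.abs(cands - r_index_in_beat) > w) & np.where(
        is_max, value > iso_level + config.upper_margin, value < iso_level - config.lower_margin
    )
    cands, a, v, value, is_max = (
        cands[keep],
        a[keep],
        v[keep],
        value[keep],
        is_max[keep],
    )
    if cands.size == 0:
        return out

    # same-polarity refractory: keep the larger excursion from iso
    min_gap = max(1, int(round(config.min_peak_distance_ms / 1000.0 * beat.fs)))
    sel = np.zeros(cands.size, dtype=bool)
    for polarity in (True, False):
        grp = np.flatnonzero(is_max == polarity)
        if grp.size == 0:
            continue
        kept_centers = _collapse_refractory(
            cands[grp], np.abs(value[grp] - iso_level), min_gap
        )
        sel[grp[np.isin(cands[grp], kept_centers)]] = True
    cands, a, v, value, is_max = (
        cands[sel],
        a[sel],
        v[sel],
        value[sel],
        is_max[sel],
    )

    minima = [(int(c), float(vv)) for c, vv, mx in zip(cands, v, is_max) if not mx]
    maxima = [(int(c), float(vv), float(val)) for c, vv, val, mx in zip(cands, v, value, is_max) if mx]

    q_idx = None
    s_idx = None
    before_r = [m for m in minima if m[0] < r_index_in_beat]
    after_r = [m for m in minima if m[0] > r_index_in_beat]
    if before_r:
        q_idx, q_v = max(before_r, key=lambda m: m[0])
        out.append(FiducialAnnotation(index=q_idx, label="Q", amplitude=q_v))
    if after_r:
        s_idx, s_v = min(after_r, key=lambda m: m[0])
        out.append(FiducialAnnotation(index=s_idx, label="S", amplitude=s_v))

    p_limit = q_idx if q_idx is not None else r_index_in_beat
    t_limit = s_idx if s_idx is not None else r_index_in_beat
    before_q = [m for m in maxima if m[0] < p_limit]
    after_s = [m for m in maxima if m[0] > t_limit]
    if before_q:
        p_idx, p_v, _ = max(before_q, key=lambda m: m[2] - iso_level)
        out.append(FiducialAnnotation(index=p_idx, label="P", amplitude=p_v))
    if after_s:
        t_idx, t_v, _ = max(after_s, key=lambda m: m[2] - iso_level)
        out.append(FiducialAnnotation(index=t_idx, label="T", amplitude=t_v))

    out.sort()
    return out
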