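"""Synthetic single-lead ECG generator with exact ground-truth fiducials.

Each beat is a sum of five Gaussians (P, Q, R, S, T) placed relative to a
jittered R time on a constant baseline; optional noise terms emulate the
usual contaminants: sinusoidal baseline wander, 50/60 Hz powerline
interference, white measurement noise and band-limited EMG-like noise.

Ground-truth annotations are recomputed on the *rendered noiseless*
signal — the local extremum nearest each wave's nominal center — not the
nominal Gaussian center itself, because neighbouring waves shift and can
even swallow a shallow extremum (a Q dip riding the R upstroke).  A wave
whose extremum is absorbed by its neighbours yields no annotation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .types import EcgSignal, FiducialAnnotation

__all__ = [
    "Wave",
    "BeatTemplate",
    "NoiseSpec",
    "default_template",
    "random_template",
    "generate_ecg",
]


@dataclass(frozen=True)
class Wave:
    """One Gaussian wave: center offset from R (s), peak amplitude (mV,
    sign gives polarity), and width (Gaussian sigma, s)."""

    offset: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat: the five waves plus a baseline level."""

    p: Wave
    q: Wave
    r: Wave
    s: Wave
    t: Wave
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        if self.r.offset != 0.0:
            raise ValueError("R wave must sit at offset 0")
        offsets = [self.p.offset, self.q.offset, 0.0, self.s.offset, self.t.offset]
        if not all(x < y for x, y in zip(offsets, offsets[1:])):
            raise ValueError("wave offsets must be ordered P < Q < R < S < T")

    @property
    def waves(self) -> dict:
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}

    @property
    def span(self) -> float:
        """Temporal footprint of one beat (s), tails included at 4 sigma."""
        lo = self.p.offset - 4 * self.p.width
        hi = self.t.offset + 4 * self.t.width
        return hi - lo


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes and frequencies of the four contamination terms.

    All amplitudes in mV (``emg_amp`` and ``white_sigma`` are RMS); zero
    amplitude disables a term.
    """

    wander_amp: float = 0.0
    wander_freq: float = 0.2
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0
    white_sigma: float = 0.0
    emg_band: tuple = (20.0, 150.0)
    emg_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wander_amp", "powerline_amp", "white_sigma", "emg_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls()

    @classmethod
    def typical(cls) -> "NoiseSpec":
        """Moderate contamination for robustness exercises."""
        return cls(wander_amp=0.15, powerline_amp=0.02, white_sigma=0.01, emg_amp=0.01)


def default_template() -> BeatTemplate:
    """Textbook lead-I morphology: modest P, narrow Q/R/S, broad T."""
    return BeatTemplate(
        p=Wave(-0.16, 0.15, 0.025),
        q=Wave(-0.03, -0.10, 0.008),
        r=Wave(0.0, 1.0, 0.012),
        s=Wave(0.03, -0.15, 0.010),
        t=Wave(0.25, 0.30, 0.045),
    )


def random_template(rng: np.random.Generator, rel_scale: float = 0.10) -> BeatTemplate:
    """A morphology near the default: amplitudes and widths perturbed by a
    uniform relative factor, wave offsets left in place so ordering holds."""
    base = default_template()

    def jiggle(wv: Wave) -> Wave:
        fa, fw = 1 + rng.uniform(-rel_scale, rel_scale, size=2)
        return replace(wv, amplitude=wv.amplitude * fa, width=wv.width * fw)

    return BeatTemplate(
        p=jiggle(base.p),
        q=jiggle(base.q),
        r=jiggle(base.r),
        s=jiggle(base.s),
        t=jiggle(base.t),
        baseline_level=base.baseline_level,
    )


def _render_clean(
    template: BeatTemplate, fs: float, r_times: np.ndarray, n: int
) -> np.ndarray:
    t = np.arange(n) / fs
    y = np.full(n, template.baseline_level, dtype=np.float64)
    for wave in template.waves.values():
        if wave.amplitude == 0.0:
            continue
        for rt in r_times:
            c = rt + wave.offset
            lo = max(0, int(np.floor((c - 5 * wave.width) * fs)))
            hi = min(n, int(np.ceil((c + 5 * wave.width) * fs)) + 1)
            if lo >= hi:
                continue
            d = t[lo:hi] - c
            y[lo:hi] += wave.amplitude * np.exp(-(d * d) / (2 * wave.width**2))
    return y


def _annotate_clean(
    template: BeatTemplate, fs: float, r_times: np.ndarray, clean: np.ndarray
) -> list[FiducialAnnotation]:
    """Exact extremum of the rendered noiseless signal, per wave per beat."""
    n = clean.size
    out: list[FiducialAnnotation] = []
    for rt in r_times:
        for label, wave in template.waves.items():
            if wave.amplitude == 0.0:
                continue
            center = int(round((rt + wave.offset) * fs))
            half = max(2, int(round(2.5 * wave.width * fs)))
            lo, hi = max(0, center - half), min(n, center + half + 1)
            if hi - lo < 3:
                continue
            seg = clean[lo:hi]
            k = int(np.argmax(seg) if wave.amplitude > 0 else np.argmin(seg))
            idx = lo + k
            # a wave swallowed by its neighbours has no interior extremum
            if k == 0 or k == seg.size - 1:
                continue
            if not (0 < idx < n - 1):
                continue
            is_max = wave.amplitude > 0
            if is_max and not (clean[idx] >= clean[idx - 1] and clean[idx] >= clean[idx + 1]):
                continue
            if not is_max and not (clean[idx] <= clean[idx - 1] and clean[idx] <= clean[idx + 1]):
                continue
            out.append(
                FiducialAnnotation(index=idx, label=label, amplitude=float(clean[idx]))
            )
    out.sort()
    return out


def generate_ecg(
    template: BeatTemplate | None = None,
    fs: float = 500.0,
    n_beats: int = 20,
    rr_mean: float = 0.8,
    rr_sd: float = 0.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    record_id: str = "synthetic",
) -> tuple[EcgSignal, list[FiducialAnnotation]]:
    """Render a quasi-periodic ECG and its exact ground-truth fiducials.

    R-R intervals are Gaussian with mean ``rr_mean`` and sd ``rr_sd``
    (truncated at 3 sd); the returned annotations mark the exact extrema
    of the rendered noiseless component.  Deterministic given ``seed``;
    with ``rr_sd=0`` the noiseless component is identical across seeds
    while the noise differs.
    """
    template = template or default_template()
    noise = noise or NoiseSpec.none()
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if not rr_mean > template.span:
        raise ValueError(
            f"rr_mean {rr_mean} s must exceed the template span {template.span:.3f} s"
        )
    ss = np.random.SeedSequence(seed)
    rng_rr, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    lead_in = -(template.p.offset - 4 * template.p.width)
    tail = template.t.offset + 4 * template.t.width
    if n_beats > 1:
        rr = rng_rr.normal(rr_mean, rr_sd, size=n_beats - 1) if rr_sd > 0 else np.full(
            n_beats - 1, rr_mean
        )
        rr = np.clip(rr, rr_mean - 3 * rr_sd, rr_mean + 3 * rr_sd)
        r_times = lead_in + np.concatenate(([0.0], np.cumsum(rr)))
    else:
        r_times = np.array([lead_in])
    n = int(round((r_times[-1] + tail) * fs)) + 1

    clean = _render_clean(template, fs, r_times, n)
    annotations = _annotate_clean(template, fs, r_times, clean)

    t = np.arange(n) / fs
    y = clean.copy()
    if noise.wander_amp > 0:
        y += noise.wander_amp * np.sin(
            2 * np.pi * noise.wander_freq * t + rng_noise.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp > 0:
        y += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng_noise.uniform(0, 2 * np.pi)
        )
    if noise.white_sigma > 0:
        y += rng_noise.normal(0.0, noise.white_sigma, size=n)
    if noise.emg_amp > 0:
        lo, hi = noise.emg_band
        hi = min(hi, 0.45 * fs)
        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        raw = sps.sosfiltfilt(sos, rng_noise.normal(0.0, 1.0, size=n))
        sd = raw.std()
        if sd > 0:
            y += noise.emg_amp * raw / sd

    return EcgSignal(samples=y, fs=fs, record_id=record_id), annotations
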