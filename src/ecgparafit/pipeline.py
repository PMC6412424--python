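"""End-to-end delineation: preprocess, detect R, segment, delineate beats.

The full chain mirrors the intended use of the method: condition the
record (low-pass + baseline removal), detect R peaks and the isoelectric
level over the whole record, cut fixed-width beat windows around every
interior R, and run the narrow-window detector inside each beat.  P, Q, S
and T are therefore only defined for interior beats — the first and last
R serve as segmentation references.
"""
from __future__ import annotations

from .detect import (
    DetectorConfig,
    detect_pqrst,
    detect_r_peaks,
    estimate_isoelectric_level,
)
from .core import error_profile, r_window_halfwidth
from .preprocess import FilterSpec, preprocess
from .segment import segment_beats
from .types import EcgSignal, FiducialAnnotation

__all__ = ["delineate"]


def delineate(
    signal: EcgSignal,
    config: DetectorConfig | None = None,
    do_preprocess: bool = True,
    filter_spec: FilterSpec | None = None,
    baseline_order: int | None = 8,
) -> list[FiducialAnnotation]:
    """Detect all five fiducials across a record.

    Returns annotations with absolute sample indices, sorted.  If fewer
    than three R peaks are found, only the R annotations are returned
    (no beat can be delineated).
    """
    config = config or DetectorConfig()
    work = preprocess(signal, filter_spec, baseline_order) if do_preprocess else signal

    profile = error_profile(work, r_window_halfwidth(work.fs))
    r_anns = detect_r_peaks(work, config, profile=profile)
    if len(r_anns) < 3:
        return r_anns
    iso = estimate_isoelectric_level(work, config, profile=profile)

    r_indices = [a.index for a in r_anns]
    beats = segment_beats(work, r_indices)
    out: list[FiducialAnnotation] = list(r_anns)
    for k in range(len(beats)):
        beat = beats.beat_signal(k, record_id=work.record_id)
        local = detect_pqrst(beat, beats.r_offset, iso, config)
        r_abs = int(beats.source_r_indices[k])
        for ann in local:
            if ann.label == "R":
                continue  # already reported from the record-level pass
            out.append(
                FiducialAnnotation(
                    index=r_abs - beats.r_offset + ann.index,
                    label=ann.label,
                    amplitude=ann.amplitude,
                )
            )
    out.sort()
    return out
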