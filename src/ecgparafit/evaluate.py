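"""Detection sensitivity against reference annotations.

A reference fiducial point counts as detected when a same-label detection
lies within a temporal tolerance (default 10 ms, boundary inclusive);
each detection may account for at most one reference point, pairs taken
nearest-first.  Sensitivity is the percentage of reference points matched,
pooled over records per label.  A record-level variant — the fraction of
records in which every reference point of a label was matched — is
available for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .exceptions import ValidationError
from .types import LABELS, FiducialAnnotation

__all__ = ["SensitivityReport", "match_annotations", "sensitivity", "evaluate_detection"]

DEFAULT_TOLERANCE_MS = 10.0


@dataclass
class SensitivityReport:
    """Per-label sensitivity (%) with the underlying matched/total counts.

    Labels with no reference points are reported as ``None`` (undefined),
    never as 0.
    """

    per_label: dict
    tolerance_ms: float
    n_records: int
    counts: dict

    def as_dict(self) -> dict:
        return {
            "tolerance_ms": self.tolerance_ms,
            "n_records": self.n_records,
            "sensitivity_percent": dict(self.per_label),
            "counts": {k: list(v) for k, v in self.counts.items()},
        }


def match_annotations(
    detected: Sequence[FiducialAnnotation],
    reference: Sequence[FiducialAnnotation],
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    fs: float = 500.0,
) -> dict:
    """Per-label (matched, total) counts for one record.

    For each reference point, matched iff a same-label detection exists
    with |delta index| / fs <= tolerance_ms / 1000 (inclusive); greedy
    nearest-first pairing, each detection consuming at most one reference.
    """
    for ann in list(detected) + list(reference):
        if ann.label not in LABELS:
            raise ValidationError(f"unknown fiducial label {ann.label!r}")
    tol_samples = tolerance_ms / 1000.0 * fs
    counts: dict = {}
    for label in LABELS:
        refs = [a.index for a in reference if a.label == label]
        if not refs:
            continue
        dets = [a.index for a in detected if a.label == label]
        pairs = sorted(
            (
                (abs(d - r), ri, di)
                for ri, r in enumerate(refs)
                for di, d in enumerate(dets)
                if abs(d - r) <= tol_samples
            )
        )
        used_r: set = set()
        used_d: set = set()
        matched = 0
        for _, ri, di in pairs:
            if ri in used_r or di in used_d:
                continue
            used_r.add(ri)
            used_d.add(di)
            matched += 1
        counts[label] = (matched, len(refs))
    return counts


def sensitivity(
    record_counts: Iterable[Mapping],
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    record_level: bool = False,
) -> SensitivityReport:
    """Pool per-record (matched, total) counts into a sensitivity report.

    Pooled (default): 100 * sum(matched) / sum(total) per label.  With
    ``record_level=True``, a record scores 1 for a label only if all of
    that label's reference points were matched, and the percentage is
    taken over records containing the label.
    """
    record_counts = list(record_counts)
    if not record_counts:
        raise ValueError("need at least one record")
    per_label: dict = {}
    pooled: dict = {}
    for label in LABELS:
        matched = total = 0
        rec_ok = rec_n = 0
        for rc in record_counts:
            if label not in rc:
                continue
            m, t = rc[label]
            if m > t:
                raise ValidationError("matched count exceeds total")
            matched += m
            total += t
            rec_n += 1
            rec_ok += int(m == t)
        if total == 0:
            continue
        pooled[label] = (matched, total)
        if record_level:
            per_label[label] = 100.0 * rec_ok / rec_n
        else:
            per_label[label] = 100.0 * matched / total
    for label in LABELS:
        per_label.setdefault(label, None)
    return SensitivityReport(
        per_label=per_label,
        tolerance_ms=tolerance_ms,
        n_records=len(record_counts),
        counts=pooled,
    )


def evaluate_detection(
    detected: Sequence[FiducialAnnotation],
    reference: Sequence[FiducialAnnotation],
    fs: float,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    record_level: bool = False,
) -> SensitivityReport:
    """Single-record convenience wrapper around match + pool."""
    counts = match_annotations(detected, reference, tolerance_ms=tolerance_ms, fs=fs)
    return sensitivity([counts], tolerance_ms=tolerance_ms, record_level=record_level)
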