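"""Cleaning, fixed-length segmentation, and per-segment outlier trimming.

The cleaning stage removes, in order, (a) artifact intervals longer than
2 s and (b) intervals whose beat label is not 'N' (ectopic / abnormal
beats), concatenating the survivors in original temporal order. Cleaned
series are then cut into consecutive non-overlapping windows of N = 300
intervals. Immediately before entropy computation each window is trimmed
of values outside its own mean ± 3·SD band (the 99% normal range).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hrvrefine.rr_io import Group, RRRecording

__all__ = [
    "RRSegment",
    "clean_recording",
    "segment_recording",
    "trim_segment_outliers",
    "segments_to_frame",
    "frame_to_segments",
]

DEFAULT_MAX_RR_MS = 2000.0
DEFAULT_SEGMENT_N = 300


@dataclass
class RRSegment:
    """A fixed-nominal-length window of RR values traceable to its recording.

    ``origin_start`` is the 0-based index of the first value in the cleaned
    series it was cut from. ``effective_length`` is the number of values
    remaining after trimming (== nominal_length until trimmed).
    """

    subject_id: str
    group: Group
    origin_start: int
    values: np.ndarray
    nominal_length: int = DEFAULT_SEGMENT_N

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("segment values must be one-dimensional")
        if not 0 < self.values.size <= self.nominal_length:
            raise ValueError(
                f"segment needs 1..{self.nominal_length} values, got {self.values.size}"
            )
        if not np.all(self.values > 0):
            raise ValueError("segment values must be positive")
        if self.origin_start < 0:
            raise ValueError("origin_start must be non-negative")

    @property
    def effective_length(self) -> int:
        return self.values.size


def clean_recording(rec: RRRecording, max_rr_ms: float = DEFAULT_MAX_RR_MS) -> RRRecording:
    """Remove artifact and abnormal intervals from a recording.

    First drops every interval longer than ``max_rr_ms`` (default 2 s),
    then every interval whose label is not 'N'; survivors keep their
    original order. ``stage_counts`` gains ``after_long_removal`` and
    ``after_abnormal_removal``. Idempotent; may return an empty recording.
    """
    keep_long = rec.rr_ms <= max_rr_ms
    rr = rec.rr_ms[keep_long]
    labels = rec.beat_labels[keep_long]
    after_long = int(rr.size)
    keep_normal = labels == "N"
    rr = rr[keep_normal]
    labels = labels[keep_normal]
    counts = dict(rec.stage_counts)
    counts.setdefault("raw", len(rec))
    # setdefault keeps the original audit trail when re-cleaning a clean recording
    counts.setdefault("after_long_removal", after_long)
    counts.setdefault("after_abnormal_removal", int(rr.size))
    return RRRecording(
        subject_id=rec.subject_id,
        group=rec.group,
        rr_ms=rr,
        beat_labels=labels,
        sampling_rate_hz=rec.sampling_rate_hz,
        stage_counts=counts,
    )


def segment_recording(rec: RRRecording, n: int = DEFAULT_SEGMENT_N) -> list[RRSegment]:
    """Cut a cleaned recording into consecutive non-overlapping N-windows.

    Windows start at index 0; the trailing remainder shorter than ``n`` is
    discarded, so exactly ``floor(len/n)`` segments are returned (possibly
    zero — not an error).
    """
    if n < 1:
        raise ValueError("segment length must be >= 1")
    n_segments = len(rec) // n
    return [
        RRSegment(
            subject_id=rec.subject_id,
            group=rec.group,
            origin_start=i * n,
            values=rec.rr_ms[i * n : (i + 1) * n],
            nominal_length=n,
        )
        for i in range(n_segments)
    ]


def trim_segment_outliers(seg: RRSegment) -> RRSegment:
    """Remove values outside the segment's own mean ± 3·SD band.

    A single pass (not iterated): mean and SD (denominator n−1) are
    computed from the segment's current values, and values outside
    [mean − 3·SD, mean + 3·SD] are dropped, order preserved. When SD = 0
    nothing is removed.
    """
    if seg.effective_length < 2:
        raise ValueError(
            f"subject {seg.subject_id} segment @{seg.origin_start}: "
            "need >= 2 values to trim"
        )
    mean = float(np.mean(seg.values))
    sd = float(np.std(seg.values, ddof=1))
    keep = np.abs(seg.values - mean) <= 3.0 * sd
    return replace(seg, values=seg.values[keep])


def segments_to_frame(segments: list[RRSegment]) -> pd.DataFrame:
    """Serialize segments to a long-format DataFrame (one row per interval).

    Columns: subject_id, group, origin_start, beat_index, rr_ms. This is
    the on-disk format used by the CLI between pipeline stages.
    """
    records = []
    for seg in segments:
        records.append(
            pd.DataFrame(
                {
                    "subject_id": seg.subject_id,
                    "group": seg.group.value,
                    "origin_start": seg.origin_start,
                    "beat_index": np.arange(seg.effective_length),
                    "rr_ms": seg.values,
                }
            )
        )
    if not records:
        return pd.DataFrame(
            columns=["subject_id", "group", "origin_start", "beat_index", "rr_ms"]
        )
    return pd.concat(records, ignore_index=True)


def frame_to_segments(frame: pd.DataFrame, nominal_length: int = DEFAULT_SEGMENT_N) -> list[RRSegment]:
    """Inverse of :func:`segments_to_frame`; segment order follows the frame."""
    segments = []
    for (sid, group, origin), part in frame.groupby(
        ["subject_id", "group", "origin_start"], sort=False
    ):
        part = part.sort_values("beat_index")
        segments.append(
            RRSegment(
                subject_id=str(sid),
                group=Group(group),
                origin_start=int(origin),
                values=part["rr_ms"].to_numpy(),
                nominal_length=nominal_length,
            )
        )
    return segments
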