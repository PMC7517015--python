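"""Data refinement: fast-HR segment selection, DTW similarity filtering, typing.

These three stages are the refinement proper. A *fast-HR sequence* is the
300-interval window that immediately follows an RR interval <= 600 ms and
whose median and mode are <= 600 ms with SD < 50 ms — a sustained, stable
period of fast heart rate presumed to expose the subject's intrinsic
cardiac state. Within each subject, segments are then compared pairwise
with dynamic time warping (DTW); a segment whose column median cost
exceeds 10 is morphologically unlike the rest and is discarded. Finally
subjects are typed by how many segments survive: >= 90 segments is type I
(high-quality signal), fewer is type II, none at all is excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numba import njit

from hrvrefine.preprocess import RRSegment
from hrvrefine.rr_io import RRRecording

__all__ = [
    "FastHRParams",
    "DTWFilterResult",
    "SubjectType",
    "SubjectTyping",
    "select_fast_hr_segments",
    "dtw_cost",
    "dtw_filter_subject",
    "assign_subject_types",
]

DEFAULT_DTW_THRESHOLD = 10.0
DEFAULT_TYPE_BOUNDARY = 90


@dataclass(frozen=True)
class FastHRParams:
    """Gates for fast-HR sequence selection (all in ms except seg_n).

    trigger_ms : an RR interval at or below this starts a candidate window.
    seg_n : window length in beats taken strictly after the trigger.
    max_median_ms / max_mode_ms : non-strict upper gates on the window.
    max_sd_ms : strict upper gate on the window SD.
    """

    trigger_ms: float = 600.0
    seg_n: int = 300
    max_median_ms: float = 600.0
    max_mode_ms: float = 600.0
    max_sd_ms: float = 50.0

    def __post_init__(self) -> None:
        if min(self.trigger_ms, self.seg_n, self.max_median_ms,
               self.max_mode_ms, self.max_sd_ms) <= 0:
            raise ValueError("all fast-HR parameters must be positive")


class SubjectType(str, enum.Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    EXCLUDED = "EXCLUDED"


@dataclass
class SubjectTyping:
    """Surviving-segment counts and the type assigned to each subject."""

    counts: dict[str, int]
    boundary: int
    types: dict[str, SubjectType]


@dataclass
class DTWFilterResult:
    """Pairwise DTW costs and keep/discard flags for one subject's segments."""

    subject_id: str
    cost_matrix: np.ndarray
    column_medians: np.ndarray
    threshold: float
    kept: np.ndarray


def _smallest_mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken by the smallest modal value."""
    uniques, counts = np.unique(values, return_counts=True)
    return float(uniques[np.argmax(counts)])  # uniques sorted, argmax takes first


def select_fast_hr_segments(rec: RRRecording, params: FastHRParams | None = None) -> list[RRSegment]:
    """Scan a cleaned recording for fast-HR sequences.

    Left-to-right scan: at index t with rr[t] <= trigger_ms, the candidate
    is the seg_n intervals strictly after t. It is accepted iff
    median <= max_median_ms, mode <= max_mode_ms and SD (denominator n−1)
    < max_sd_ms; on acceptance the scan resumes just past the accepted
    window (segments never overlap), on rejection it advances one beat.
    """
    if params is None:
        params = FastHRParams()
    rr = rec.rr_ms
    n = rr.size
    seg_n = params.seg_n
    segments: list[RRSegment] = []
    t = 0
    while t <= n - seg_n - 1:
        if rr[t] <= params.trigger_ms:
            candidate = rr[t + 1 : t + 1 + seg_n]
            if (
                float(np.median(candidate)) <= params.max_median_ms
                and _smallest_mode(candidate) <= params.max_mode_ms
                and float(np.std(candidate, ddof=1)) < params.max_sd_ms
            ):
                segments.append(
                    RRSegment(
                        subject_id=rec.subject_id,
                        group=rec.group,
                        origin_start=t + 1,
                        values=candidate.copy(),
                        nominal_length=seg_n,
                    )
                )
                t += seg_n + 1
                continue
        t += 1
    return segments


@njit(cache=True)
def _dtw_kernel(x: np.ndarray, y: np.ndarray):  # pragma: no cover - jitted
    """Full DTW dynamic program; returns (cumulative cost, path length).

    Backtracking tie-break: diagonal, then vertical (advance in x), then
    horizontal. The cumulative cost itself is tie-free.
    """
    m = x.shape[0]
    k = y.shape[0]
    cum = np.empty((m, k))
    cum[0, 0] = abs(x[0] - y[0])
    for j in range(1, k):
        cum[0, j] = cum[0, j - 1] + abs(x[0] - y[j])
    for i in range(1, m):
        cum[i, 0] = cum[i - 1, 0] + abs(x[i] - y[0])
        for j in range(1, k):
            best = cum[i - 1, j - 1]
            if cum[i - 1, j] < best:
                best = cum[i - 1, j]
            if cum[i, j - 1] < best:
                best = cum[i, j - 1]
            cum[i, j] = abs(x[i] - y[j]) + best
    i = m - 1
    j = k - 1
    length = 1
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = cum[i - 1, j - 1]
            vert = cum[i - 1, j]
            horiz = cum[i, j - 1]
            if diag <= vert and diag <= horiz:
                i -= 1
                j -= 1
            elif vert <= horiz:
                i -= 1
            else:
                j -= 1
        elif i > 0:
            i -= 1
        else:
            j -= 1
        length += 1
    return cum[m - 1, k - 1], length


def dtw_cost(x, y) -> tuple[float, int]:
    """Path-length-normalized DTW cost between two series.

    Local distance is the absolute difference in ms; the cumulative
    distance of the optimal monotone warping path from corner (1,1) to
    corner (len(x), len(y)) is divided by the path length N, with
    max(len(x), len(y)) <= N <= len(x) + len(y) − 1. Arguments are
    canonically ordered internally so the cost is exactly symmetric even
    when backtracking ties admit paths of different lengths.
    """
    a = np.ascontiguousarray(x, dtype=np.float64)
    b = np.ascontiguousarray(y, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("DTW inputs must be one-dimensional")
    if (a.size, tuple(a)) > (b.size, tuple(b)):
        a, b = b, a
    cumulative, path_len = _dtw_kernel(a, b)
    return float(cumulative) / path_len, int(path_len)


def dtw_filter_subject(
    segments: list[RRSegment], threshold: float = DEFAULT_DTW_THRESHOLD
) -> DTWFilterResult:
    """Keep a subject's segments whose median DTW cost to the rest is <= threshold.

    Builds the symmetric pairwise cost matrix over all segment pairs, takes
    for every column the median of its n−1 off-diagonal entries (the
    diagonal zero carries no information; even counts average the two
    middle values), and keeps a segment iff that median is <= threshold.
    A single segment is trivially kept.
    """
    if not segments:
        raise ValueError("dtw_filter_subject needs at least one segment")
    sids = {seg.subject_id for seg in segments}
    if len(sids) > 1:
        raise ValueError(f"segments must come from a single subject, got {sorted(sids)}")
    n = len(segments)
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cost[i, j], _ = dtw_cost(segments[i].values, segments[j].values)
            cost[j, i] = cost[i, j]
    if n == 1:
        medians = np.zeros(1)
    else:
        off = ~np.eye(n, dtype=bool)
        medians = np.array([np.median(cost[:, j][off[:, j]]) for j in range(n)])
    kept = medians <= threshold
    return DTWFilterResult(
        subject_id=segments[0].subject_id,
        cost_matrix=cost,
        column_medians=medians,
        threshold=threshold,
        kept=kept,
    )


def assign_subject_types(
    counts: dict[str, int], boundary: int = DEFAULT_TYPE_BOUNDARY
) -> SubjectTyping:
    """Type subjects by surviving-segment count.

    count == 0 -> EXCLUDED (no usable fast-HR sequence at all);
    count >= boundary -> TYPE_I; otherwise TYPE_II.
    """
    types: dict[str, SubjectType] = {}
    for sid, count in counts.items():
        if count < 0:
            raise ValueError(f"subject {sid}: negative segment count {count}")
        if count == 0:
            types[sid] = SubjectType.EXCLUDED
        elif count >= boundary:
            types[sid] = SubjectType.TYPE_I
        else:
            types[sid] = SubjectType.TYPE_II
    return SubjectTyping(counts=dict(counts), boundary=boundary, types=types)
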