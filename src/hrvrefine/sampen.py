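"""Sample entropy with a physical (ms) or traditional (fraction-of-SD) tolerance.

Sample entropy of a series x(1..n) with embedding dimension m and tolerance
r is

    SampEn(m, r, n) = -ln( A / B )

where B counts ordered template pairs (i, j), i != j, whose m-point
templates are within r of each other in Chebyshev (maximum absolute
difference) distance, and A counts the same pairs whose (m+1)-point
extensions also match. Both counts run over template indices
1 <= i, j <= n - m, so the (m+1)-templates use points up to x(n) and the
last m-window (starting at n - m + 1) is excluded; self-matches are
excluded per the standard definition.

The physical tolerance fixes r in milliseconds (default 12 ms = 1.5x the
nominal 8 ms sampling period of a 128 Hz ECG) so that the same absolute
similarity scale applies to every subject; the traditional tolerance
scales r to 0.10x the segment's own SD.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hrvrefine.preprocess import RRSegment

__all__ = [
    "ToleranceMode",
    "SampEnParams",
    "SampEnResult",
    "resolve_tolerance",
    "sample_entropy",
    "entropy_table",
    "subject_mean_entropy",
]

logger = logging.getLogger(__name__)


class ToleranceMode(str, enum.Enum):
    PHYSICAL = "physical"
    TRADITIONAL = "traditional"


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    m : embedding dimension (>= 1).
    r_mode : PHYSICAL (fixed ms tolerance) or TRADITIONAL (fraction of SD).
    r_physical_ms : tolerance in ms for PHYSICAL mode (default 12).
    r_fraction : SD multiplier for TRADITIONAL mode (default 0.10).
    n : nominal segment length the analysis is designed for (default 300).
    """

    m: int = 1
    r_mode: ToleranceMode = ToleranceMode.PHYSICAL
    r_physical_ms: float = 12.0
    r_fraction: float = 0.10
    n: int = 300

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_physical_ms <= 0:
            raise ValueError("r_physical_ms must be positive")
        if not 0 < self.r_fraction < 1:
            raise ValueError("r_fraction must be in (0, 1)")


@dataclass(frozen=True)
class SampEnResult:
    """Sample entropy of one series; ``value`` is NaN when undefined.

    The entropy is undefined (no exception) when no template pair matches
    at length m or at length m+1, i.e. the log ratio has an empty count.
    """

    value: float
    m: int
    r_used_ms: float
    n_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def resolve_tolerance(seg: RRSegment, params: SampEnParams) -> float:
    """Tolerance in ms for one segment under the configured mode.

    PHYSICAL returns ``r_physical_ms`` unchanged; TRADITIONAL returns
    ``r_fraction`` times the SD (denominator n−1) of the segment's current
    (post-trim) values, and raises on a constant segment.
    """
    if params.r_mode is ToleranceMode.PHYSICAL:
        return params.r_physical_ms
    sd = float(np.std(seg.values, ddof=1))
    if sd == 0.0:
        raise ValueError(
            f"subject {seg.subject_id} segment @{seg.origin_start}: "
            "degenerate tolerance (SD = 0) in traditional mode"
        )
    return params.r_fraction * sd


def sample_entropy(values, m: int, r: float) -> SampEnResult:
    """Sample entropy of a series (vectorized template counting).

    Distances are Chebyshev; matches use ``d <= r``; self-matches are
    excluded; A and B run over the shared template range 1..n−m. Returns
    NaN (``defined == False``) when either count is zero.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if n < m + 2:
        raise ValueError(f"series length {n} too short for m={m} (need >= {m + 2})")
    d0 = np.abs(x[:, None] - x[None, :])
    nt = n - m
    dm = d0[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, d0[k : k + nt, k : k + nt], out=dm)
    dm1 = np.maximum(dm, d0[m : m + nt, m : m + nt])
    off_diagonal = ~np.eye(nt, dtype=bool)
    b = int(np.count_nonzero((dm <= r) & off_diagonal))
    a = int(np.count_nonzero((dm1 <= r) & off_diagonal))
    value = -math.log(a / b) if a > 0 and b > 0 else math.nan
    return SampEnResult(value=value, m=m, r_used_ms=float(r), n_used=n)


def entropy_table(segments: list[RRSegment], params: SampEnParams) -> pd.DataFrame:
    """Per-segment sample entropy, one row per segment.

    Columns: subject_id, group, origin_start, n_used, r_used_ms, sampen,
    defined. Undefined entropies keep their row (``defined == False``) but
    are excluded from downstream aggregates; their count is logged.
    """
    rows = []
    for seg in segments:
        r = resolve_tolerance(seg, params)
        result = sample_entropy(seg.values, m=params.m, r=r)
        rows.append(
            {
                "subject_id": seg.subject_id,
                "group": seg.group.value,
                "origin_start": seg.origin_start,
                "n_used": result.n_used,
                "r_used_ms": result.r_used_ms,
                "sampen": result.value,
                "defined": result.defined,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "origin_start", "n_used", "r_used_ms", "sampen", "defined"],
    )
    n_undefined = int((~table["defined"]).sum()) if len(table) else 0
    if n_undefined:
        logger.info("entropy_table: %d of %d segments have undefined SampEn",
                    n_undefined, len(table))
    return table


def subject_mean_entropy(table: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean of defined per-segment entropies per subject.

    Subjects with no defined value are excluded with a warning.
    """
    if table.empty:
        raise ValueError("entropy table is empty")
    means: dict[str, float] = {}
    for sid, part in table.groupby("subject_id", sort=False):
        defined = part.loc[part["defined"], "sampen"]
        if defined.empty:
            warnings.warn(f"subject {sid}: no defined SampEn values; excluded from means",
                          stacklevel=2)
            continue
        means[str(sid)] = float(defined.mean())
    return means
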