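"""Reading and writing RR-interval recordings and cohort manifests.

On-disk RR format: UTF-8 text, one interval per line, whitespace-separated
``rr_ms label``; ``#`` starts a comment line. The unit is milliseconds, and
fractional values are accepted so that intervals quantized to the 128 Hz
sampling grid (multiples of 7.8125 ms) round-trip exactly.

Beat-label convention: the single-character annotation is attached to the
interval it *terminates* (the usual convention for RR lists derived from
beat annotations, e.g. WFDB ``ann2rr`` output). ``'N'`` marks a normal
sinus interval; anything else (``'V'``, ``'S'``, ...) is treated as
abnormal by :func:`hrvrefine.preprocess.clean_recording`.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Group",
    "STAGE_ORDER",
    "RRRecording",
    "CohortManifest",
    "read_rr_file",
    "write_rr_file",
    "read_manifest",
    "write_manifest",
    "load_cohort",
]


class Group(str, enum.Enum):
    """Cohort arm: normal sinus rhythm, congestive heart failure, or unknown."""

    NSR = "NSR"
    CHF = "CHF"
    UNKNOWN = "UNKNOWN"


#: Declared order of cleaning stages; stage_counts must be non-increasing along it.
STAGE_ORDER = ("raw", "after_long_removal", "after_abnormal_removal")


@dataclass
class RRRecording:
    """One subject's RR-interval series with per-beat annotation labels.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : Group
        Cohort arm the subject belongs to.
    rr_ms : ndarray of float
        RR interval durations in milliseconds, in temporal order.
    beat_labels : ndarray of str
        One single-character annotation per interval ('N' = normal).
    sampling_rate_hz : float
        Sampling rate of the underlying ECG (default 128 Hz).
    stage_counts : dict
        Number of intervals surviving each cleaning stage, keyed by stage
        name; used for audit reports.
    """

    subject_id: str
    group: Group
    rr_ms: np.ndarray
    beat_labels: np.ndarray
    sampling_rate_hz: float = 128.0
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.rr_ms = np.asarray(self.rr_ms, dtype=np.float64)
        self.beat_labels = np.asarray(self.beat_labels, dtype="U1")
        if self.rr_ms.ndim != 1:
            raise ValueError("rr_ms must be one-dimensional")
        if self.rr_ms.shape != self.beat_labels.shape:
            raise ValueError(
                f"subject {self.subject_id}: rr_ms has {self.rr_ms.size} values "
                f"but beat_labels has {self.beat_labels.size}"
            )
        if self.rr_ms.size and not np.all(self.rr_ms > 0):
            raise ValueError(f"subject {self.subject_id}: RR intervals must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self._check_stage_counts()

    def _check_stage_counts(self) -> None:
        ordered = [self.stage_counts[s] for s in STAGE_ORDER if s in self.stage_counts]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError(
                f"subject {self.subject_id}: stage_counts must be non-increasing "
                f"along {STAGE_ORDER}"
            )

    def __len__(self) -> int:
        return self.rr_ms.size


@dataclass
class CohortManifest:
    """List of (subject_id, group, file_path) entries; subject ids unique."""

    entries: list[tuple[str, Group, Path]]

    def __post_init__(self) -> None:
        self.entries = [(sid, Group(g), Path(p)) for sid, g, p in self.entries]
        ids = [sid for sid, _, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate subject_id in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)


def read_rr_file(path: str | Path, subject_id: str, group: Group | str) -> RRRecording:
    """Parse an RR text file into an :class:`RRRecording`.

    Lines are ``rr_ms label``; ``#`` comments and blank lines are skipped.
    Columns beyond the first two are ignored with a warning (tolerates
    ``ann2rr``-style extra columns).
    """
    path = Path(path)
    rr: list[float] = []
    labels: list[str] = []
    extra_warned = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected '<rr_ms> <label>', got {line!r}")
            if len(fields) > 2 and not extra_warned:
                warnings.warn(
                    f"{path}:{lineno}: ignoring extra columns after 'rr_ms label'",
                    stacklevel=2,
                )
                extra_warned = True
            try:
                value = float(fields[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable RR value {fields[0]!r}") from exc
            if not value > 0:
                raise ValueError(f"{path}:{lineno}: RR value must be positive, got {value}")
            if len(fields[1]) != 1:
                raise ValueError(f"{path}:{lineno}: label must be one character, got {fields[1]!r}")
            rr.append(value)
            labels.append(fields[1])
    if not rr:
        raise ValueError(f"{path}: no RR intervals found")
    return RRRecording(
        subject_id=subject_id,
        group=group,
        rr_ms=np.array(rr),
        beat_labels=np.array(labels),
        stage_counts={"raw": len(rr)},
    )


def write_rr_file(rec: RRRecording, path: str | Path) -> None:
    """Write a recording in the RR text format read by :func:`read_rr_file`.

    Values are serialized with ``repr`` so any float (in particular exact
    1/128 s multiples such as 507.8125) round-trips bit-for-bit.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# subject_id={rec.subject_id} group={rec.group.value} "
                 f"fs_hz={rec.sampling_rate_hz:g}\n")
        for value, label in zip(rec.rr_ms, rec.beat_labels):
            fh.write(f"{float(value)!r} {label}\n")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (header ``subject_id,group,path``).

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    entries: list[tuple[str, Group, Path]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "group", "path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: manifest must have columns {sorted(required)}")
        for row in reader:
            rr_path = Path(row["path"])
            if not rr_path.is_absolute():
                rr_path = path.parent / rr_path
            entries.append((row["subject_id"], Group(row["group"]), rr_path))
    return CohortManifest(entries=entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a cohort manifest CSV with header ``subject_id,group,path``.

    RR-file paths are stored relative to the manifest's directory when
    possible (so a cohort directory can be moved as a unit), absolute
    otherwise; :func:`read_manifest` resolves them back.
    """
    path = Path(path)
    base = path.parent.resolve()
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "path"])
        for sid, group, rr_path in manifest.entries:
            resolved = Path(rr_path).resolve()
            try:
                stored = resolved.relative_to(base)
            except ValueError:
                stored = resolved
            writer.writerow([sid, group.value, str(stored)])


def load_cohort(manifest: CohortManifest) -> list[RRRecording]:
    """Load every recording referenced by the manifest, order preserved."""
    recordings = []
    for sid, group, rr_path in manifest.entries:
        if not Path(rr_path).exists():
            raise FileNotFoundError(f"subject {sid}: RR file not found: {rr_path}")
        recordings.append(read_rr_file(rr_path, subject_id=sid, group=group))
    return recordings
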