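"""Full refinement pipeline: clean -> select -> DTW filter -> type -> evaluate.

Dataset0 is the cleaned, exhaustively segmented cohort; Dataset1 keeps
only fast-HR sequences; Dataset2 additionally drops DTW-dissimilar
segments. Entropy tables are computed for all three (segments are trimmed
of ±3·SD outliers immediately before entropy), subjects are typed by their
Dataset2 segment count, and classification reports are produced for the
ALL, TYPE_I and TYPE_II scopes. All run artifacts are plain CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from hrvrefine.evaluation import RunSummary, summarize_run
from hrvrefine.preprocess import clean_recording, segment_recording, trim_segment_outliers
from hrvrefine.refine import (
    FastHRParams,
    SubjectTyping,
    assign_subject_types,
    dtw_filter_subject,
    select_fast_hr_segments,
)
from hrvrefine.rr_io import CohortManifest, load_cohort
from hrvrefine.sampen import SampEnParams, ToleranceMode, entropy_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters; the defaults are the reference settings."""

    max_rr_ms: float = 2000.0
    segment_n: int = 300
    trigger_ms: float = 600.0
    max_median_ms: float = 600.0
    max_mode_ms: float = 600.0
    max_sd_ms: float = 50.0
    dtw_threshold: float = 10.0
    type_boundary: int = 90
    m: int = 1
    r_mode: ToleranceMode = ToleranceMode.PHYSICAL
    r_physical_ms: float = 12.0
    r_fraction: float = 0.10

    def fast_hr_params(self) -> FastHRParams:
        return FastHRParams(
            trigger_ms=self.trigger_ms,
            seg_n=self.segment_n,
            max_median_ms=self.max_median_ms,
            max_mode_ms=self.max_mode_ms,
            max_sd_ms=self.max_sd_ms,
        )

    def sampen_params(self) -> SampEnParams:
        return SampEnParams(
            m=self.m,
            r_mode=ToleranceMode(self.r_mode),
            r_physical_ms=self.r_physical_ms,
            r_fraction=self.r_fraction,
            n=self.segment_n,
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    counts: pd.DataFrame
    group_counts: pd.DataFrame
    entropy_dataset0: pd.DataFrame
    entropy_dataset1: pd.DataFrame
    entropy_dataset2: pd.DataFrame
    typing: SubjectTyping
    summaries: dict[str, RunSummary | None]


def _trimmed(segments):
    return [trim_segment_outliers(seg) for seg in segments]


def run_pipeline(
    manifest: CohortManifest,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage on a cohort; optionally write artifacts to out_dir.

    Artifacts: per-subject counts.csv, group-level group_counts.csv,
    entropy_dataset{0,1,2}.csv, typing.csv, report_{all,type_i,type_ii}.json
    and run.log. Any stage error aborts with subject context (exceptions
    propagate, annotated by the failing stage's own message).
    """
    if config is None:
        config = PipelineConfig()
    out_path = None
    log_handler = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out_path / "run.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logging.getLogger("hrvrefine").addHandler(log_handler)

    try:
        recordings = load_cohort(manifest)
        sampen_params = config.sampen_params()
        fast_params = config.fast_hr_params()

        count_rows = []
        dataset0_segments = []
        dataset1_segments = []
        dataset2_segments = []
        dtw_counts: dict[str, int] = {}

        for rec in recordings:
            cleaned = clean_recording(rec, max_rr_ms=config.max_rr_ms)
            all_segments = segment_recording(cleaned, n=config.segment_n)
            dataset0_segments.extend(all_segments)

            selected = select_fast_hr_segments(cleaned, fast_params)
            dataset1_segments.extend(selected)
            if selected:
                filter_result = dtw_filter_subject(selected, threshold=config.dtw_threshold)
                kept = [seg for seg, keep in zip(selected, filter_result.kept) if keep]
            else:
                kept = []
                logger.info("subject %s: no fast-HR sequence found; excluded", rec.subject_id)
            dataset2_segments.extend(kept)
            dtw_counts[rec.subject_id] = len(kept)
            if selected and len(kept) < len(selected):
                logger.info(
                    "subject %s: DTW filter discarded %d of %d segments",
                    rec.subject_id, len(selected) - len(kept), len(selected),
                )

            count_rows.append(
                {
                    "subject_id": cleaned.subject_id,
                    "group": cleaned.group.value,
                    "raw": cleaned.stage_counts["raw"],
                    "after_long_removal": cleaned.stage_counts["after_long_removal"],
                    "after_abnormal_removal": cleaned.stage_counts["after_abnormal_removal"],
                    "n_segments_dataset0": len(all_segments),
                    "n_segments_dataset1": len(selected),
                    "n_segments_dataset2": len(kept),
                }
            )

        counts = pd.DataFrame(count_rows)
        typing = assign_subject_types(dtw_counts, boundary=config.type_boundary)
        counts["subject_type"] = counts["subject_id"].map(
            lambda s: typing.types[s].value
        )

        table0 = entropy_table(_trimmed(dataset0_segments), sampen_params)
        table1 = entropy_table(_trimmed(dataset1_segments), sampen_params)
        table2 = entropy_table(_trimmed(dataset2_segments), sampen_params)

        group_counts = _group_counts(counts, typing, config.segment_n)

        summaries: dict[str, RunSummary | None] = {}
        for scope in ("ALL", "TYPE_I", "TYPE_II"):
            try:
                summaries[scope] = summarize_run(table2, typing, scope=scope)
            except ValueError as exc:
                logger.warning("scope %s not evaluable: %s", scope, exc)
                summaries[scope] = None

        result = PipelineResult(
            counts=counts,
            group_counts=group_counts,
            entropy_dataset0=table0,
            entropy_dataset1=table1,
            entropy_dataset2=table2,
            typing=typing,
            summaries=summaries,
        )
        if out_path is not None:
            _write_artifacts(result, out_path)
        return result
    finally:
        if log_handler is not None:
            logging.getLogger("hrvrefine").removeHandler(log_handler)
            log_handler.close()


def _group_counts(counts: pd.DataFrame, typing: SubjectTyping, segment_n: int) -> pd.DataFrame:
    """Group-level audit table (one column per group, one row per stage)."""
    rows = {}
    for group, part in counts.groupby("group", sort=True):
        type_i = part[part["subject_type"] == "TYPE_I"]
        type_ii = part[part["subject_type"] == "TYPE_II"]
        rows[group] = {
            "n_recordings": len(part),
            "n_intervals_raw": int(part["raw"].sum()),
            "n_intervals_after_long_removal": int(part["after_long_removal"].sum()),
            "n_intervals_after_abnormal_removal": int(part["after_abnormal_removal"].sum()),
            "n_segments_dataset0": int(part["n_segments_dataset0"].sum()),
            "n_intervals_dataset1": int(part["n_segments_dataset1"].sum()) * segment_n,
            "n_segments_dataset1": int(part["n_segments_dataset1"].sum()),
            "n_segments_dataset2": int(part["n_segments_dataset2"].sum()),
            "n_segments_type_i": int(type_i["n_segments_dataset2"].sum()),
            "n_segments_type_ii": int(type_ii["n_segments_dataset2"].sum()),
        }
    return pd.DataFrame(rows)


def _write_artifacts(result: PipelineResult, out_path: Path) -> None:
    result.counts.to_csv(out_path / "counts.csv", index=False)
    result.group_counts.to_csv(out_path / "group_counts.csv")
    result.entropy_dataset0.to_csv(out_path / "entropy_dataset0.csv", index=False)
    result.entropy_dataset1.to_csv(out_path / "entropy_dataset1.csv", index=False)
    result.entropy_dataset2.to_csv(out_path / "entropy_dataset2.csv", index=False)
    typing_frame = pd.DataFrame(
        {
            "subject_id": list(result.typing.types),
            "n_segments": [result.typing.counts[s] for s in result.typing.types],
            "subject_type": [result.typing.types[s].value for s in result.typing.types],
        }
    )
    typing_frame.to_csv(out_path / "typing.csv", index=False)
    for scope, summary in result.summaries.items():
        name = f"report_{scope.lower()}.json"
        if summary is None:
            payload = {"scope": scope, "error": "scope not evaluable (missing group or empty)"}
        else:
            payload = {
                "scope": scope,
                "n_segments": summary.n_segments,
                "mean_sampen": summary.mean_sampen,
                "sd_sampen": summary.sd_sampen,
                "t_statistic": summary.t_statistic,
                "p_value": summary.p_value,
                "report": summary.report.to_dict(),
            }
        with (out_path / name).open("w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
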