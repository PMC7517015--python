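"""Group statistics and threshold classification: t-test, ROC, Youden index.

Classification is segment-level: every RR segment contributes one entropy
value, CHF is the positive class, and the decision rule is
"SampEn <= c -> CHF" (heart-failure segments have the lower entropy; the
direction can be flipped for other statistics). The threshold sweep runs
from the minimum to the maximum entropy in steps of 1% of the range (101
thresholds); the optimal cut-point c* maximizes the Youden index
J = Se + Sp − 1, and constrained cut-points report the best Sp subject to
Se > 99% and the best Se subject to Sp > 99%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from hrvrefine.refine import SubjectType, SubjectTyping
from hrvrefine.rr_io import Group

__all__ = [
    "ConfusionMetrics",
    "ClassificationReport",
    "RunSummary",
    "confusion_metrics",
    "roc_sweep",
    "group_ttest",
    "summarize_run",
]


class ConfusionMetrics(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int
    se: float
    sp: float
    acc: float
    j: float


@dataclass
class ClassificationReport:
    """Threshold sweep with Se/Sp/Acc/J per threshold, AUC and cut-points.

    ``c_se99``/``c_sp99`` (and their metric rows) are None when no swept
    threshold satisfies the constraint.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    acc: np.ndarray
    j: np.ndarray
    auc: float
    c_star: float
    metrics_at_c_star: ConfusionMetrics
    c_se99: float | None
    metrics_at_c_se99: ConfusionMetrics | None
    c_sp99: float | None
    metrics_at_c_sp99: ConfusionMetrics | None
    positive_class: str = "CHF"
    decision_rule: str = "sampen <= c -> CHF"

    def to_dict(self) -> dict:
        def row(metrics: ConfusionMetrics | None) -> dict | None:
            return None if metrics is None else metrics._asdict()

        return {
            "positive_class": self.positive_class,
            "decision_rule": self.decision_rule,
            "auc": self.auc,
            "c_star": self.c_star,
            "metrics_at_c_star": row(self.metrics_at_c_star),
            "c_se99": self.c_se99,
            "metrics_at_c_se99": row(self.metrics_at_c_se99),
            "c_sp99": self.c_sp99,
            "metrics_at_c_sp99": row(self.metrics_at_c_sp99),
            "thresholds": self.thresholds.tolist(),
            "se": self.se.tolist(),
            "sp": self.sp.tolist(),
            "acc": self.acc.tolist(),
            "j": self.j.tolist(),
        }


def _to_label_array(labels) -> np.ndarray:
    arr = np.array([Group(l).value for l in labels])
    present = set(arr)
    if not {"NSR", "CHF"}.issubset(present):
        raise ValueError(f"both NSR and CHF must be present, got {sorted(present)}")
    if present - {"NSR", "CHF"}:
        raise ValueError(f"labels must be NSR or CHF, got {sorted(present)}")
    return arr


def confusion_metrics(values, labels, c: float, positive_low: bool = True) -> ConfusionMetrics:
    """2x2 confusion metrics at threshold c with CHF as positive class.

    ``positive_low=True`` predicts CHF iff value <= c (the entropy
    direction); set False for statistics where the diseased class is high.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = _to_label_array(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    predicted_chf = values <= c if positive_low else values >= c
    actual_chf = labels == "CHF"
    tp = int(np.count_nonzero(predicted_chf & actual_chf))
    tn = int(np.count_nonzero(~predicted_chf & ~actual_chf))
    fp = int(np.count_nonzero(predicted_chf & ~actual_chf))
    fn = int(np.count_nonzero(~predicted_chf & actual_chf))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / values.size
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn, se=se, sp=sp, acc=acc, j=se + sp - 1.0)


def roc_sweep(values, labels, positive_low: bool = True) -> ClassificationReport:
    """Threshold sweep, ROC/AUC, optimal and constrained cut-points.

    Thresholds are c_k = min + k*(max−min)/100 for k = 0..100 (a single
    threshold when the values are constant). The ROC points (1−Sp, Se) are
    augmented with the (0,0) and (1,1) anchors and integrated by the
    trapezoid rule; c* is the smallest threshold maximizing J.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = _to_label_array(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        thresholds = np.array([vmin])
    else:
        thresholds = vmin + (vmax - vmin) * np.arange(101) / 100.0

    actual_chf = labels == "CHF"
    n_pos = int(actual_chf.sum())
    n_neg = actual_chf.size - n_pos
    if positive_low:
        predicted = values[None, :] <= thresholds[:, None]
    else:
        predicted = values[None, :] >= thresholds[:, None]
    tp = (predicted & actual_chf).sum(axis=1)
    fp = (predicted & ~actual_chf).sum(axis=1)
    se = tp / n_pos
    sp = (n_neg - fp) / n_neg
    acc = (tp + (n_neg - fp)) / actual_chf.size
    j = se + sp - 1.0

    points = np.column_stack([1.0 - sp, se])
    points = np.vstack([points, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((points[:, 1], points[:, 0]))
    points = points[order]
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))

    i_star = int(np.argmax(j))  # first maximum -> smallest c
    c_star = float(thresholds[i_star])

    def constrained(mask: np.ndarray, maximize: np.ndarray):
        if not mask.any():
            return None, None
        idx = np.flatnonzero(mask)
        best = idx[int(np.argmax(maximize[idx]))]
        return float(thresholds[best]), confusion_metrics(
            values, labels, float(thresholds[best]), positive_low=positive_low
        )

    c_se99, m_se99 = constrained(se > 0.99, sp)
    c_sp99, m_sp99 = constrained(sp > 0.99, se)

    rule = "sampen <= c -> CHF" if positive_low else "value >= c -> CHF"
    return ClassificationReport(
        thresholds=thresholds,
        se=se,
        sp=sp,
        acc=acc,
        j=j,
        auc=auc,
        c_star=c_star,
        metrics_at_c_star=confusion_metrics(values, labels, c_star, positive_low=positive_low),
        c_se99=c_se99,
        metrics_at_c_se99=m_se99,
        c_sp99=c_sp99,
        metrics_at_c_sp99=m_sp99,
        decision_rule=rule,
    )


def group_ttest(values_nsr, values_chf, welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance; Welch behind a flag).

    Returns (t, two-sided p) for NSR minus CHF. p-values below the double
    floor are reported as 0.0. Raises on degenerate (zero pooled) variance
    or groups smaller than two.
    """
    a = np.asarray(values_nsr, dtype=np.float64)
    b = np.asarray(values_chf, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("degenerate variance: both groups are constant")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


@dataclass
class RunSummary:
    """Scope-restricted evaluation: report plus per-group mean ± SD and p."""

    scope: str
    report: ClassificationReport
    n_segments: dict[str, int]
    mean_sampen: dict[str, float]
    sd_sampen: dict[str, float]
    t_statistic: float
    p_value: float


def summarize_run(
    entropy_table: pd.DataFrame,
    typing: SubjectTyping | None,
    scope: str = "ALL",
) -> RunSummary:
    """Restrict segments to subjects in scope, then evaluate.

    ``scope`` is ALL, TYPE_I or TYPE_II (EXCLUDED subjects never enter any
    scope when a typing is given). Means/SDs use defined entropies only.
    """
    scope = scope.upper()
    if scope not in {"ALL", "TYPE_I", "TYPE_II"}:
        raise ValueError(f"unknown scope {scope!r}")
    table = entropy_table[entropy_table["defined"]].copy()
    if typing is not None:
        if scope == "ALL":
            allowed = {s for s, t in typing.types.items() if t is not SubjectType.EXCLUDED}
        else:
            allowed = {s for s, t in typing.types.items() if t is SubjectType(scope)}
        table = table[table["subject_id"].isin(allowed)]
    if table.empty:
        raise ValueError(f"scope {scope}: no defined entropy values")
    values = table["sampen"].to_numpy()
    labels = table["group"].to_numpy()
    report = roc_sweep(values, labels)
    nsr = values[labels == "NSR"]
    chf = values[labels == "CHF"]
    t, p = group_ttest(nsr, chf)
    return RunSummary(
        scope=scope,
        report=report,
        n_segments={"NSR": int(nsr.size), "CHF": int(chf.size)},
        mean_sampen={"NSR": float(nsr.mean()), "CHF": float(chf.mean())},
        sd_sampen={"NSR": float(nsr.std(ddof=1)), "CHF": float(chf.std(ddof=1))},
        t_statistic=t,
        p_value=p,
    )
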