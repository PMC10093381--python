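"""Cohort-level evaluation: confusion matrix, averaged metrics, chi-square
distribution comparison, Kaplan-Meier curves with 36-month rates, and
log-rank tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .io import SUBTYPES


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # rows = reference, columns = predicted
    n_total: int

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def confusion_matrix(reference, predicted, labels=SUBTYPES) -> ConfusionMatrix:
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted):
        raise ValueError("reference and predicted must have equal length")
    bad = sorted((set(reference) | set(predicted)) - set(labels))
    if bad:
        raise ValueError(f"labels outside the class universe: {bad}")
    counts = _sk_confusion(reference, predicted, labels=list(labels))
    return ConfusionMatrix(tuple(labels), counts.astype(int), len(reference))


def per_class_prf(m: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall, f1; zero-denominator cases report 0."""
    diag = np.diag(m.counts).astype(float)
    col = m.col_sums().astype(float)
    row = m.row_sums().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1}, index=list(m.labels)
    )


def row_percentages(m: ConfusionMatrix, rounded: bool = True) -> np.ndarray:
    """Each row as percentages of its reference-class size (whole percents,
    half-up, when rounded)."""
    row = m.row_sums().astype(float)
    pct = 100.0 * m.counts / np.where(row[:, None] > 0, row[:, None], 1)
    if rounded:
        return np.vectorize(round_half_up)(pct)
    return pct


def column_percentages(m: ConfusionMatrix, rounded: bool = True) -> np.ndarray:
    """Predicted-class share of the cohort (the predicted distribution)."""
    pct = 100.0 * m.col_sums() / m.n_total
    if rounded:
        return np.vectorize(round_half_up)(pct)
    return pct


@dataclass(frozen=True)
class MetricReport:
    per_class: pd.DataFrame
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]


def aggregate_metrics(m: ConfusionMatrix) -> MetricReport:
    """Accuracy plus macro- and weighted-averaged precision/recall/f1.

    Weighted averaging uses reference-class sizes, so weighted recall over a
    complete matrix equals accuracy.
    """
    # expand the matrix back to label vectors so sklearn computes the averages
    ref, pred = [], []
    for i, li in enumerate(m.labels):
        for j, lj in enumerate(m.labels):
            ref += [li] * int(m.counts[i, j])
            pred += [lj] * int(m.counts[i, j])
    out = {}
    for avg in ("macro", "weighted"):
        p, r, f, _ = precision_recall_fscore_support(
            ref, pred, labels=list(m.labels), average=avg, zero_division=0
        )
        out[avg] = {"precision": float(p), "recall": float(r), "f1": float(f)}
    accuracy = float(np.trace(m.counts) / m.n_total) if m.n_total else 0.0
    return MetricReport(
        per_class=per_class_prf(m),
        accuracy=accuracy,
        macro=out["macro"],
        weighted=out["weighted"],
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def chi_square_homogeneity(counts_a, counts_b) -> ChiSquareResult:
    """Pearson chi-square on the 2 x k table of two class-count vectors
    (no continuity correction), df = k - 1."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the class universe")
    table = np.vstack([a, b])
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected count: class absent from both vectors")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    group: str = ""


def km_estimator(times, events, group: str = "") -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in grid])
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, group=group)


def survival_at(curve: KMCurve, t: float) -> float:
    """Step value of the KM curve at the largest event time <= t (1.0 before
    the first step)."""
    mask = curve.times <= t
    if not mask.any():
        return 1.0
    return float(curve.survival[mask][-1])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


def logrank_test(groups: dict[str, tuple]) -> LogRankResult:
    """k-group log-rank test; groups maps label -> (times, events)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    all_times, all_events, all_labels = [], [], []
    for label, (times, events) in groups.items():
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        all_times.append(times)
        all_events.append(events)
        all_labels += [label] * len(times)
    times = np.concatenate(all_times)
    events = np.concatenate(all_events)
    if not events.any():
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, np.asarray(all_labels), events)
    return LogRankResult(
        float(res.test_statistic), len(groups) - 1, float(res.p_value)
    )


@dataclass(frozen=True)
class CohortEvaluation:
    confusion: ConfusionMatrix
    metrics: MetricReport
    chi_square: ChiSquareResult
    km_curves: dict[str, dict[str, KMCurve]]  # method -> subtype -> curve
    survival_36m: pd.DataFrame
    logrank: dict[str, LogRankResult]  # method -> omnibus test


def evaluate_cohort(calls, clinical, horizon_months: float = 36.0) -> CohortEvaluation:
    """Full evaluation of predicted calls against reference clinical records.

    Records without a reference subtype are excluded from the confusion
    matrix; records without follow-up are excluded from survival analyses
    (per endpoint). KM curves and omnibus log-rank tests are computed under
    both groupings (reference subtype and predicted subtype).
    """
    by_id = {c.sample_id: c for c in calls}
    paired = [
        (clinical[sid].tcga_subtype, by_id[sid].subtype)
        for sid in by_id
        if sid in clinical and clinical[sid].tcga_subtype is not None
    ]
    if not paired:
        raise ValueError("no samples with reference subtype labels")
    ref, pred = zip(*paired)
    cm = confusion_matrix(ref, pred)
    metrics = aggregate_metrics(cm)
    ref_counts = [ref.count(s) for s in SUBTYPES]
    pred_counts = [pred.count(s) for s in SUBTYPES]
    chi2 = chi_square_homogeneity(ref_counts, pred_counts)

    km_curves: dict[str, dict[str, KMCurve]] = {}
    logrank: dict[str, LogRankResult] = {}
    rows = []
    groupers = {
        "reference": lambda sid: clinical[sid].tcga_subtype,
        "predicted": lambda sid: by_id[sid].subtype,
    }
    for method, get_label in groupers.items():
        groups = {}
        for sid in by_id:
            rec = clinical.get(sid)
            if rec is None or rec.followup_months is None or rec.event is None:
                continue
            label = get_label(sid)
            if label is None:
                continue
            groups.setdefault(label, ([], []))
            groups[label][0].append(rec.followup_months)
            groups[label][1].append(rec.event)
        km_curves[method] = {}
        for label in SUBTYPES:
            if label not in groups:
                continue
            t, e = groups[label]
            curve = km_estimator(t, e, group=label)
            km_curves[method][label] = curve
            rows.append(
                {
                    "method": method,
                    "subtype": label,
                    "n": len(t),
                    f"survival_{int(horizon_months)}m": survival_at(curve, horizon_months),
                }
            )
        if len(groups) >= 2 and any(any(e) for _, e in groups.values()):
            logrank[method] = logrank_test(groups)
    return CohortEvaluation(
        confusion=cm,
        metrics=metrics,
        chi_square=chi2,
        km_curves=km_curves,
        survival_36m=pd.DataFrame(rows),
        logrank=logrank,
    )
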