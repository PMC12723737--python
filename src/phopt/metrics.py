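"""Regression metrics, stratified evaluation and pH-preference classification.

Metrics: RMSE = sqrt(mean((t-p)^2)); MAE = mean(|t-p|); R^2 is the coefficient
of determination 1 - SS_res/SS_tot (undefined when the labels have zero
variance; ``None`` is returned in that case, never a number).

Stratified slices follow the evaluation protocol: label ranges pH_opt < 6 and
pH_opt > 8, EC classes 1-6 (EC7 excluded by default because it is too rare in
practice), and train-set identity bins [0, 0.30), [0.30, 0.60), [0.60, 1.0].
Slices are defined on experimental labels, never on predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .exceptions import ContractError, ValidationError
from .io import LabeledRecord

ACIDOPHILIC = "acidophilic"
ALKALIPHILIC = "alkaliphilic"

#: Identity-score bins: half-open [low, high), upper bin closed at 1.0.
IDENTITY_BINS = (("<30%", 0.0, 0.30), ("30-60%", 0.30, 0.60),
                 (">60%", 0.60, 1.0 + 1e-12))


def _check(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ContractError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ContractError("empty metric input")
    return t, p


def rmse(y_true, y_pred) -> float:
    t, p = _check(y_true, y_pred)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def mae(y_true, y_pred) -> float:
    t, p = _check(y_true, y_pred)
    return float(np.mean(np.abs(t - p)))


def r_squared(y_true, y_pred) -> float | None:
    """Coefficient of determination; ``None`` when y_true has zero variance."""
    t, p = _check(y_true, y_pred)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    return float(1.0 - np.sum((t - p) ** 2) / ss_tot)


@dataclass(frozen=True)
class MetricSet:
    rmse: float
    mae: float
    r2: float | None
    n: int

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2, "n": self.n}


def _metric_set(t: np.ndarray, p: np.ndarray) -> MetricSet:
    return MetricSet(rmse(t, p), mae(t, p), r_squared(t, p), len(t))


@dataclass
class EvalReport:
    """Overall metrics plus the stratified slices.

    Slices with no members appear with ``n=0`` and no metrics. Missing EC or
    identity columns skip those stratifications entirely (``notices`` says so).
    """

    overall: MetricSet
    by_ph_range: dict[str, MetricSet | dict] = field(default_factory=dict)
    by_ec: dict[int, MetricSet | dict] = field(default_factory=dict)
    by_identity_bin: dict[str, MetricSet | dict] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        def conv(d):
            return {str(k): (v.as_dict() if isinstance(v, MetricSet) else v)
                    for k, v in d.items()}
        return {
            "overall": self.overall.as_dict(),
            "by_ph_range": conv(self.by_ph_range),
            "by_ec": conv(self.by_ec),
            "by_identity_bin": conv(self.by_identity_bin),
            "notices": list(self.notices),
        }


def _slice_metrics(mask: np.ndarray, t: np.ndarray, p: np.ndarray):
    if not mask.any():
        return {"n": 0}
    return _metric_set(t[mask], p[mask])


def stratified_report(records: Sequence[LabeledRecord],
                      predictions: Sequence[float],
                      include_ec7: bool = False) -> EvalReport:
    """Compute overall and per-slice metrics for labeled records."""
    if len(records) != len(predictions):
        raise ContractError(
            f"{len(records)} records but {len(predictions)} predictions")
    t = np.array([r.ph_opt for r in records])
    p = np.asarray(predictions, dtype=float)
    report = EvalReport(overall=_metric_set(t, p))

    report.by_ph_range["ph_lt_6"] = _slice_metrics(t < 6.0, t, p)
    report.by_ph_range["ph_gt_8"] = _slice_metrics(t > 8.0, t, p)

    ec = np.array([r.ec_class if r.ec_class is not None else -1
                   for r in records])
    if (ec >= 0).any():
        classes = range(1, 8) if include_ec7 else range(1, 7)
        for c in classes:
            report.by_ec[c] = _slice_metrics(ec == c, t, p)
    else:
        report.notices.append("no EC classes present; EC slices skipped")

    ident = np.array([r.identity_score if r.identity_score is not None
                      else np.nan for r in records])
    if np.isfinite(ident).any():
        for name, lo, hi in IDENTITY_BINS:
            mask = np.isfinite(ident) & (ident >= lo) & (ident < hi)
            report.by_identity_bin[name] = _slice_metrics(mask, t, p)
    else:
        report.notices.append("no identity scores present; identity slices "
                              "skipped")
    return report


@dataclass
class ClassificationResult:
    """Acidophilic/alkaliphilic classification at a pH cutoff.

    A prediction below the cutoff is called acidophilic; a prediction at or
    above it is called alkaliphilic (the boundary value goes to alkaliphilic).
    """

    cutoff: float
    counts: dict[str, tuple[int, int]]  # class -> (correct, total)
    accuracy: float
    misclassified: list[str]


def classify_preference(ids: Sequence[str], predictions: Sequence[float],
                        true_classes: Sequence[str],
                        cutoff: float = 7.0) -> ClassificationResult:
    """Threshold classification of pH preference against known classes."""
    if not (len(ids) == len(predictions) == len(true_classes)):
        raise ContractError("ids, predictions and true_classes must align")
    preds = np.asarray(predictions, dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ContractError("predictions must be finite")
    counts = {ACIDOPHILIC: [0, 0], ALKALIPHILIC: [0, 0]}
    misclassified: list[str] = []
    for id_, pred, truth in zip(ids, preds, true_classes):
        if truth not in counts:
            raise ValidationError(
                f"unknown true class {truth!r} for {id_!r}; expected "
                f"{ACIDOPHILIC!r} or {ALKALIPHILIC!r}")
        called = ACIDOPHILIC if pred < cutoff else ALKALIPHILIC
        counts[truth][1] += 1
        if called == truth:
            counts[truth][0] += 1
        else:
            misclassified.append(id_)
    total = sum(c[1] for c in counts.values())
    correct = sum(c[0] for c in counts.values())
    return ClassificationResult(
        cutoff=cutoff,
        counts={k: (v[0], v[1]) for k, v in counts.items()},
        accuracy=correct / total,
        misclassified=misclassified,
    )


class DistributionComparison(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def distribution_compare(group_a: Sequence[float], group_b: Sequence[float],
                         ) -> DistributionComparison:
    """Two-sided Mann-Whitney U test between two prediction distributions.

    The rank-based test makes no normality assumption about predicted pH
    values. Groups in which every value is tied are flagged as degenerate.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ContractError("each group needs at least 3 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        return DistributionComparison(len(a) * len(b) / 2.0, 1.0, True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return DistributionComparison(float(res.statistic), float(res.pvalue),
                                  False)
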