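"""Confusion matrices and diagnostic-accuracy metrics against surveillance.

Surveillance-confirmed SSI status is the reference standard. Each model row
reports sensitivity, specificity, positive and negative predictive value,
and accuracy, both as count fractions and in the conventional
"percent (numerator/denominator)" style, with percents rounded half-up to
two decimals. Metrics with a zero denominator (e.g. PPV when a model flags
nobody) are reported as undefined and printed as an em dash, never as 0 or
100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

from .rule_classifiers import ClassifierResult

__all__ = [
    "ConfusionMatrix",
    "MetricValue",
    "PerformanceRow",
    "confusion",
    "confusion_from_results",
    "compute_metrics",
    "report_tables",
    "MODEL_ORDER",
]

#: Row order of the published comparison tables.
MODEL_ORDER = ["icd9", "strict", "moderate", "loose", "logistic", "cart"]

_MODEL_LABELS = {
    "icd9": "ICD-9-CM-based model",
    "strict": "Model 1 (strict)",
    "moderate": "Model 2 (moderate)",
    "loose": "Model 3 (loose)",
    "logistic": "Model 4 (logistic)",
    "cart": "Model 5 (decision tree)",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricValue:
    """One metric as numerator/denominator with a rounded percent."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> float | None:
        """100 * fraction, rounded half-up to 2 decimals."""
        if not self.defined:
            return None
        q = Decimal(100 * self.numerator) / Decimal(self.denominator)
        return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def formatted(self) -> str:
        if not self.defined:
            return "—"
        return f"{self.percent:.2f}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class PerformanceRow:
    model_name: str
    cm: ConfusionMatrix
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue

    def as_dict(self) -> dict:
        d: dict = {"model": self.model_name}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricValue = getattr(self, name)
            d[name] = {
                "numerator": m.numerator,
                "denominator": m.denominator,
                "percent": m.percent,
            }
        d["counts"] = {"tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn}
        return d


def confusion(predictions: Sequence[int], labels: Sequence[int],
              ids: Sequence[str] | None = None) -> ConfusionMatrix:
    """Exact confusion counts for aligned binary predictions and labels."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must have equal length")
    if ids is not None and len(ids) != len(labels):
        raise ValueError("ids must align with predictions and labels")
    tp = fp = fn = tn = 0
    for p, t in zip(predictions, labels):
        if p not in (0, 1) or t not in (0, 1):
            raise ValueError("predictions and labels must be binary 0/1")
        if t == 1:
            tp, fn = (tp + 1, fn) if p == 1 else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if p == 1 else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_results(results: Sequence[ClassifierResult],
                           labels: Mapping[str, int]) -> ConfusionMatrix:
    """Join per-patient results with surveillance labels by patient_id."""
    missing = [r.patient_id for r in results if r.patient_id not in labels]
    if missing:
        raise ValueError(f"no surveillance label for patient ids: {missing[:10]}")
    preds = [r.prediction for r in results]
    truth = [labels[r.patient_id] for r in results]
    return confusion(preds, truth)


def compute_metrics(cm: ConfusionMatrix, model_name: str = "") -> PerformanceRow:
    """The five diagnostic-accuracy metrics from one confusion matrix."""
    return PerformanceRow(
        model_name=model_name,
        cm=cm,
        sensitivity=MetricValue(cm.tp, cm.n_positive),
        specificity=MetricValue(cm.tn, cm.n_negative),
        ppv=MetricValue(cm.tp, cm.n_flagged),
        npv=MetricValue(cm.tn, cm.tn + cm.fn),
        accuracy=MetricValue(cm.tp + cm.tn, cm.total),
    )


def _rows_to_frame(rows: Sequence[PerformanceRow]) -> pd.DataFrame:
    ordered = sorted(
        rows,
        key=lambda r: MODEL_ORDER.index(r.model_name)
        if r.model_name in MODEL_ORDER
        else len(MODEL_ORDER),
    )
    data = {
        "Model": [_MODEL_LABELS.get(r.model_name, r.model_name) for r in ordered],
        "Sensitivity": [r.sensitivity.formatted() for r in ordered],
        "Specificity": [r.specificity.formatted() for r in ordered],
        "PPV": [r.ppv.formatted() for r in ordered],
        "NPV": [r.npv.formatted() for r in ordered],
        "Accuracy": [r.accuracy.formatted() for r in ordered],
    }
    return pd.DataFrame(data)


def report_tables(
    training_rows: Sequence[PerformanceRow],
    verification_rows: Sequence[PerformanceRow] | None = None,
) -> dict[str, pd.DataFrame | None]:
    """Training/verification performance tables in the published layout.

    Returns ``{"training": DataFrame, "verification": DataFrame | None}``;
    an empty verification input yields None rather than an empty table.
    """
    if not training_rows:
        raise ValueError("at least one evaluated model is required")
    return {
        "training": _rows_to_frame(training_rows),
        "verification": _rows_to_frame(verification_rows) if verification_rows else None,
    }


def format_report_text(tables: Mapping[str, pd.DataFrame | None]) -> str:
    parts = []
    titles = {"training": "Training cohort", "verification": "Verification cohort"}
    for key in ("training", "verification"):
        table = tables.get(key)
        parts.append(f"== {titles[key]} ==")
        parts.append(table.to_string(index=False) if table is not None else "(absent)")
        parts.append("")
    return "\n".join(parts)
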