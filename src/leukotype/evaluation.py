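"""Per-subtype one-vs-rest diagnostic metrics.

Each subtype is evaluated as its own binary problem: samples of that subtype
are positives, everything else negatives.  From the resulting TP/FP/TN/FN
counts the standard screening metrics follow:

    Accuracy    = (TP + TN) / (TP + FN + TN + FP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

Report values are percentages rounded half-up to two decimals (so 98.125 ->
98.13, never banker's 98.12); the exact fractions are retained alongside.
A metric whose denominator is zero is reported as undefined (rendered "—"),
never coerced to 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import multilabel_confusion_matrix

from .errors import ValidationError
from .io import SUBTYPES, SampleLabels


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed diagnostic tables use."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Metrics:
    """Accuracy / Sensitivity / Specificity as rounded percentages.

    ``None`` marks an undefined metric (zero denominator).  ``*_exact``
    carry the unrounded fractions in [0, 1].
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy_exact: float | None
    sensitivity_exact: float | None
    specificity_exact: float | None


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    for name, c in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if c < 0 or int(c) != c:
            raise ValidationError(f"{name} must be a non-negative integer, got {c!r}")

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    acc = frac(tp + tn, tp + fn + tn + fp)
    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    pct = lambda f: None if f is None else round_half_up(100.0 * f)
    return Metrics(pct(acc), pct(sens), pct(spec), acc, sens, spec)


def confusion_counts(true: SampleLabels, predicted: SampleLabels) -> pd.DataFrame:
    """One-vs-rest (TP, FP, TN, FN) per subtype over a shared sample set."""
    t, p = set(true.labels), set(predicted.labels)
    if t != p:
        raise ValidationError(
            f"sample sets differ; only in true: {sorted(t - p)}, "
            f"only in predicted: {sorted(p - t)}"
        )
    order = sorted(t)
    y_true = [true[s] for s in order]
    y_pred = [predicted[s] for s in order]
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=list(SUBTYPES))
    rows = {
        sub: {
            "TP": int(m[1, 1]),
            "FP": int(m[0, 1]),
            "TN": int(m[0, 0]),
            "FN": int(m[1, 0]),
        }
        for sub, m in zip(SUBTYPES, mcm)
    }
    return pd.DataFrame.from_dict(rows, orient="index")[["TP", "FP", "TN", "FN"]]


def table_from_counts(counts: pd.DataFrame | Mapping[str, tuple]) -> pd.DataFrame:
    """Build the per-subtype report table from (TP, FP, TN, FN) rows."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame.from_dict(
            {k: dict(zip(("TP", "FP", "TN", "FN"), v)) for k, v in counts.items()},
            orient="index",
        )
    rows = []
    for sub, r in counts.iterrows():
        m = metrics_from_counts(r["TP"], r["FP"], r["TN"], r["FN"])
        rows.append(
            {
                "Subtype": sub,
                "TP": int(r["TP"]),
                "FP": int(r["FP"]),
                "TN": int(r["TN"]),
                "FN": int(r["FN"]),
                "Accuracy": m.accuracy,
                "Sensitivity": m.sensitivity,
                "Specificity": m.specificity,
            }
        )
    return pd.DataFrame(rows)


def evaluate_table(true: SampleLabels, predicted: SampleLabels) -> pd.DataFrame:
    """Seven-row per-subtype report (counts + rounded percentage metrics)."""
    return table_from_counts(confusion_counts(true, predicted))


def overall_accuracy(true: SampleLabels, predicted: SampleLabels) -> float:
    """Micro (plain multiclass) accuracy — an extension beyond the
    per-subtype rows; fraction in [0, 1]."""
    t, p = set(true.labels), set(predicted.labels)
    if t != p:
        raise ValidationError("sample sets differ")
    return float(np.mean([true[s] == predicted[s] for s in sorted(t)]))


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in ("Accuracy", "Sensitivity", "Specificity"):
        out[col] = out[col].map(lambda v: "—" if v is None or pd.isna(v) else f"{v:.2f}%")
    out.to_csv(path, index=False)
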