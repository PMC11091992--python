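"""In-sample evaluation of the pattern -> injury-class predictor.

The saturated model predicts, for each moment-curve pattern, the injury
class with the largest fitted conditional probability — equivalently the
modal class of that pattern's row in the contingency table.  Evaluation
is in-sample (the same observations that built the table), producing a
5 x 5 confusion matrix (rows actual, columns predicted) and per-class
recall (sensitivity), precision (positive predictive value) and F1, the
macro-averaged F1 (simple mean over all five classes) and overall
accuracy.  Metrics with 0/0 denominators are scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import MultinomialFit
from .errors import ValidationError
from .labels import CLASS_ORDER, PATTERN_ORDER, validate_class, validate_pattern


@dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    f1: float


@dataclass
class EvaluationReport:
    per_class: dict[str, ClassMetrics]
    macro_f1: float
    accuracy: float
    n: int


def predict_class(pattern: str, model: pd.DataFrame | MultinomialFit) -> str:
    """Predict the injury class for a pattern.

    ``model`` may be the fitted model (argmax of fitted probabilities)
    or the contingency table itself (argmax of the pattern's row counts)
    — identical for the saturated model.  Exact ties break toward the
    earlier class in ``CLASS_ORDER``.
    """
    validate_pattern(pattern)
    if isinstance(model, MultinomialFit):
        row = model.fitted_probs.loc[pattern]
    else:
        row = model.reindex(index=list(PATTERN_ORDER), columns=list(CLASS_ORDER)).loc[pattern]
    values = row[list(CLASS_ORDER)].to_numpy(dtype=float)
    best = values.max()
    for cls, v in zip(CLASS_ORDER, values):
        if v >= best - 1e-12 * max(abs(best), 1.0):
            return cls
    return CLASS_ORDER[int(np.argmax(values))]  # pragma: no cover


def confusion_from_predictions(
    pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Confusion matrix from ``(actual, predicted)`` class pairs."""
    if len(pairs) == 0:
        raise ValidationError("cannot evaluate an empty label sequence")
    mat = pd.DataFrame(0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    for actual, predicted in pairs:
        validate_class(actual)
        validate_class(predicted)
        mat.at[actual, predicted] += 1
    return mat


def report_from_confusion(confusion: pd.DataFrame) -> EvaluationReport:
    """Per-class and macro metrics from a 5 x 5 confusion matrix.

    Recall = diagonal / row sum, precision = diagonal / column sum, each
    0 when its denominator is 0; F1 is the harmonic mean (0 when
    precision + recall = 0); macro-F1 averages all five classes.
    """
    mat = confusion.reindex(index=list(CLASS_ORDER), columns=list(CLASS_ORDER))
    arr = mat.to_numpy(dtype=float)
    per_class: dict[str, ClassMetrics] = {}
    f1s = []
    for i, cls in enumerate(CLASS_ORDER):
        tp = arr[i, i]
        row = arr[i, :].sum()
        col = arr[:, i].sum()
        recall = tp / row if row > 0 else 0.0
        precision = tp / col if col > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class[cls] = ClassMetrics(recall=recall, precision=precision, f1=f1)
        f1s.append(f1)
    total = arr.sum()
    return EvaluationReport(
        per_class=per_class,
        macro_f1=float(np.mean(f1s)),
        accuracy=float(np.trace(arr) / total),
        n=int(round(total)),
    )


def evaluate_predictions(
    pairs: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Evaluate explicit ``(actual, predicted)`` class pairs."""
    confusion = confusion_from_predictions(pairs)
    return confusion, report_from_confusion(confusion)


def evaluate(
    labels: Sequence[tuple[str, str]],
    model: pd.DataFrame | MultinomialFit,
) -> tuple[pd.DataFrame, EvaluationReport]:
    """Score the pattern -> class predictor on ``(pattern, actual_class)`` pairs.

    Returns the confusion matrix (rows actual, columns predicted) and
    the metrics report.
    """
    if len(labels) == 0:
        raise ValidationError("cannot evaluate an empty label sequence")
    prediction_of = {p: predict_class(p, model) for p in PATTERN_ORDER}
    pairs = [(cls, prediction_of[validate_pattern(pattern)]) for pattern, cls in labels]
    return evaluate_predictions(pairs)
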