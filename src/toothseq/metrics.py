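"""Classification metrics: accuracy, per-class precision/recall/F1, confusion.

Thin wrapper over scikit-learn that packages the numbers into an
EvaluationReport with the invariants the rest of the pipeline relies on:
confusion rows sum to per-class test counts, accuracy = trace/n × 100, and
F1 is the harmonic mean of precision and recall (0 when both are 0).
Percentages are rounded to two decimals only at serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

__all__ = ["EvaluationReport", "compute_metrics"]


@dataclass
class EvaluationReport:
    accuracy: float  # percent
    per_class: pd.DataFrame  # columns: label, precision, recall, f1, support (%)
    confusion: np.ndarray  # (k, k) counts, rows = truth
    n_test: int
    labels: List = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "n_test": self.n_test,
            "labels": [str(l) for l in self.labels],
            "per_class": [
                {
                    "label": str(r.label),
                    "precision": round(float(r.precision), 2),
                    "recall": round(float(r.recall), 2),
                    "f1": round(float(r.f1), 2),
                    "support": int(r.support),
                }
                for r in self.per_class.itertuples(index=False)
            ],
            "confusion": self.confusion.tolist(),
        }

    def write(self, directory, stem: str = "report") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import json

        (directory / f"{stem}.json").write_text(
            json.dumps(self.to_json_dict(), indent=2)
        )
        self.per_class.round(2).to_csv(directory / f"{stem}.csv", index=False)
        pd.DataFrame(
            self.confusion,
            index=[str(l) for l in self.labels],
            columns=[str(l) for l in self.labels],
        ).to_csv(directory / "confusion.csv")


def compute_metrics(
    truth: Sequence, predicted: Sequence, labels: Optional[Sequence] = None
) -> EvaluationReport:
    """Build an EvaluationReport from true and predicted labels.

    ``labels`` fixes the class order of the confusion matrix and per-class
    table; by default it is the sorted union of both label sets. Classes with
    no predicted positives get precision 0 (not NaN).
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) lengths differ"
        )
    if not truth:
        raise ValueError("cannot compute metrics on an empty label list")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    labels = list(labels)
    cm = confusion_matrix(truth, predicted, labels=labels)
    precision, recall, f1, support = precision_recall_fscore_support(
        truth, predicted, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "label": labels,
            "precision": precision * 100.0,
            "recall": recall * 100.0,
            "f1": f1 * 100.0,
            "support": support,
        }
    )
    n = len(truth)
    accuracy = float(np.trace(cm)) / n * 100.0
    return EvaluationReport(
        accuracy=accuracy,
        per_class=per_class,
        confusion=cm,
        n_test=n,
        labels=labels,
    )
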