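"""Held-out evaluation: confusion counts, derived metrics, and AUC.

Metrics follow the standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AUC is the rank-based (Mann-Whitney) estimator: the probability that a
random case is scored above a random control, ties counting one half.
A metric with a zero denominator is reported as ``None`` together with
an explicit reason, never as a silent NaN.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .genotype_io import GenotypeDataset
from .mlp_classifier import TrainedModel, predict_proba

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "LeakageError",
    "confusion",
    "metrics",
    "auc",
    "evaluate_report",
]


class LeakageError(RuntimeError):
    """Raised when evaluation data took part in selection or training."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None
    mcc: float | None
    auc: float | None
    decision_threshold: float = 0.5
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp, "fp": self.counts.fp,
                "fn": self.counts.fn, "tn": self.counts.tn,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
            "decision_threshold": self.decision_threshold,
            "undefined": self.undefined,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_tsv_row(self) -> str:
        fields = [
            self.accuracy, self.sensitivity, self.precision,
            self.f1, self.mcc, self.auc,
        ]
        return "\t".join("NA" if v is None else f"{v:.6f}" for v in fields)


def confusion(
    labels: np.ndarray, probabilities: np.ndarray, decision_threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold probabilities at ``decision_threshold`` (predict case when
    probability >= threshold) and tally the four outcomes."""
    y = np.asarray(labels)
    p = np.asarray(probabilities)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    pred = p >= decision_threshold
    case = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & case)),
        fp=int(np.sum(pred & ~case)),
        fn=int(np.sum(~pred & case)),
        tn=int(np.sum(~pred & ~case)),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, precision, F1 and MCC from one confusion table.

    Returns a dict with the five metrics (``None`` where undefined) and an
    ``"undefined"`` sub-dict naming the zero denominator responsible.
    """
    if counts.total < 1:
        raise ValueError("need at least one evaluated sample")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    out: dict = {"undefined": {}}
    out["accuracy"] = (tp + tn) / counts.total

    if tp + fn == 0:
        out["sensitivity"] = None
        out["undefined"]["sensitivity"] = "no positive samples (TP+FN=0)"
    else:
        out["sensitivity"] = tp / (tp + fn)
    if tp + fp == 0:
        out["precision"] = None
        out["undefined"]["precision"] = "no positive predictions (TP+FP=0)"
    else:
        out["precision"] = tp / (tp + fp)

    s, p = out["sensitivity"], out["precision"]
    if s is None or p is None or (s + p) == 0:
        out["f1"] = None
        out["undefined"]["f1"] = "precision + sensitivity is zero or undefined"
    else:
        out["f1"] = 2 * p * s / (p + s)

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        out["mcc"] = None
        out["undefined"]["mcc"] = "a confusion-margin product is zero"
    else:
        out["mcc"] = (tp * tn - fp * fn) / math.sqrt(denom)
    return out


def auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mann-Whitney AUC: mean rank of case scores, ties contributing 1/2."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    n_case = int(np.sum(y == 1))
    n_ctrl = int(np.sum(y == 0))
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(p)  # average ranks handle ties as half-wins
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n_case * (n_case + 1) / 2.0) / (n_case * n_ctrl)


def evaluate_report(
    model: TrainedModel,
    test: GenotypeDataset,
    panel: np.ndarray,
    decision_threshold: float = 0.5,
) -> MetricReport:
    """Full metric report of a trained model on a held-out test set.

    Refuses to run when the dataset's provenance shows it passed through
    selection or training stages — held-out means held out.
    """
    leaked = {"selection", "training"} & set(test.provenance)
    if leaked:
        raise LeakageError(
            f"test dataset provenance {test.provenance} includes {sorted(leaked)}"
        )
    features = test.genotypes[:, np.asarray(panel, dtype=int)].astype(float)
    probs = predict_proba(model, features)
    counts = confusion(test.labels, probs, decision_threshold)
    m = metrics(counts)
    return MetricReport(
        counts=counts,
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        precision=m["precision"],
        f1=m["f1"],
        mcc=m["mcc"],
        auc=auc(test.labels, probs),
        decision_threshold=decision_threshold,
        undefined=m["undefined"],
    )
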