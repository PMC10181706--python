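"""Cross-validation stability selection over JMI feature rankings.

The training data are split into F stratified folds (F = 5 by default).
For each fold, JMI greedy selection is run on the other F-1 groups and
the chosen SNPs are marked 1 in a q x F indicator matrix.  Each SNP's
stability weight is the fraction of folds in which it was selected,
W_j = (sum_t d_j^t) / F, so with five folds weights lie on the grid
{0, 0.2, 0.4, 0.6, 0.8, 1.0}.  The final panel keeps SNPs with
W_j >= a; the threshold a defaults to 0.6 (selected in at least three
of five folds), and a weak inequality is used so a = 1 still keeps the
SNPs selected in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .genotype_io import GenotypeDataset
from .info_theory import greedy_select

__all__ = [
    "StabilityConfig",
    "stratified_kfold",
    "run_fold_selection",
    "accumulate_weights",
    "threshold_select",
    "threshold_sweep",
]


@dataclass(frozen=True)
class StabilityConfig:
    folds: int = 5
    per_fold_k: int = 2000
    threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def stratified_kfold(labels: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffled label-stratified partition of 0..n-1 into ``folds`` groups."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if (counts < folds).any():
        raise ValueError(f"every class needs >= {folds} members, got {counts.tolist()}")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros_like(labels), labels)]


def run_fold_selection(
    train: GenotypeDataset, config: StabilityConfig
) -> np.ndarray:
    """Build the q x F binary indicator matrix of per-fold JMI selections.

    Fold t's selection runs on the union of the other F-1 groups; the
    held-out group takes no part, so each column is independent of its
    own held-out samples.
    """
    groups = stratified_kfold(train.labels, config.folds, config.seed)
    q = train.n_snps
    indicators = np.zeros((q, config.folds), dtype=np.int8)
    all_idx = np.arange(train.n_samples)
    for t, held_out in enumerate(groups):
        train_idx = np.setdiff1d(all_idx, held_out)
        sub = train.take_samples(train_idx)
        chosen = greedy_select(sub.genotypes, sub.labels, config.per_fold_k)
        indicators[list(chosen), t] = 1
    return indicators


def accumulate_weights(indicators: np.ndarray) -> np.ndarray:
    """W_j = (number of folds selecting SNP j) / F."""
    indicators = np.asarray(indicators)
    if not np.isin(indicators, (0, 1)).all():
        raise ValueError("indicator matrix must be binary")
    return indicators.sum(axis=1) / indicators.shape[1]


def threshold_select(weights: np.ndarray, a: float) -> np.ndarray:
    """Indices with stability weight >= a, ascending."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return np.flatnonzero(np.asarray(weights) >= a)


def threshold_sweep(
    weights: np.ndarray,
    thresholds: list[float],
    evaluator=None,
) -> list[dict]:
    """Panel size (and optional downstream score) for each threshold.

    ``evaluator``, if given, is called with the panel index array and may
    return any scalar/summary to attach under ``"score"``.
    """
    rows = []
    for a in thresholds:
        panel = threshold_select(weights, a)
        row = {"threshold": a, "panel_size": int(panel.size), "panel": panel}
        if evaluator is not None:
            row["score"] = evaluator(panel)
        rows.append(row)
    return rows
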