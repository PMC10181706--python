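"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal sums over value combinations or
exhaustive pair enumeration, deliberately sharing no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def mi_naive(y, z) -> float:
    """I(Y;Z) in bits by direct summation over the observed joint table."""
    y, z = list(y), list(z)
    n = len(y)
    total = 0.0
    for yv in set(y):
        py = sum(1 for v in y if v == yv) / n
        for zv in set(z):
            pz = sum(1 for v in z if v == zv) / n
            pyz = sum(1 for a, b in zip(y, z) if a == yv and b == zv) / n
            if pyz > 0:
                total += pyz * math.log2(pyz / (py * pz))
    return total


def cmi_naive(x, z, given) -> float:
    """I(X;Z|Y) in bits by an exhaustive triple loop over strata."""
    x, z, y = list(x), list(z), list(given)
    n = len(x)
    total = 0.0
    for yv in set(y):
        stratum = [i for i in range(n) if y[i] == yv]
        py = len(stratum) / n
        m = len(stratum)
        for xv in set(x):
            px = sum(1 for i in stratum if x[i] == xv) / m
            for zv in set(z):
                pz = sum(1 for i in stratum if z[i] == zv) / m
                pxz = sum(1 for i in stratum if x[i] == xv and z[i] == zv) / m
                if pxz > 0:
                    total += py * pxz * math.log2(pxz / (px * pz))
    return total


def joint_relevance_naive(x, y, z) -> float:
    """I(X,Y;Z) via pair-encoding: MI of the paired symbol (x_i, y_i) with z."""
    pairs = [f"{a}|{b}" for a, b in zip(x, y)]
    return mi_naive(pairs, z)


def greedy_jmi_naive(genotypes: np.ndarray, labels: np.ndarray, k: int) -> list[int]:
    """Greedy JMI selection with full re-scoring from scratch every round."""
    q = genotypes.shape[1]
    labels = list(labels)
    selected: list[int] = []
    for _ in range(k):
        best_j, best_score = None, None
        for j in range(q):
            if j in selected:
                continue
            col = list(genotypes[:, j])
            if not selected:
                score = mi_naive(col, labels)
            else:
                score = sum(
                    joint_relevance_naive(col, list(genotypes[:, s]), labels)
                    for s in selected
                )
            if best_score is None or score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def auc_pairs(labels, scores) -> float:
    """AUC as the fraction of correctly ordered case-control pairs (+ half ties)."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    ctrls = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(ctrls))


def metrics_naive(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Spreadsheet-style recomputation of the five confusion metrics."""
    out = {}
    out["accuracy"] = (tp + tn) / (tp + fn + fp + tn)
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    s, p = out["sensitivity"], out["precision"]
    out["f1"] = 2 * p * s / (p + s) if s is not None and p is not None and s + p else None
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(d) if d else None
    return out
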