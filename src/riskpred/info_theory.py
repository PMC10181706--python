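"""Plug-in information estimators on discrete variables and JMI selection.

All quantities are in bits (log base 2).  Probabilities are empirical
(maximum-likelihood) cell frequencies; with genotype/label alphabets of
size 3 and 2 and sample sizes in the thousands, plug-in bias is
negligible for ranking purposes.

The joint-mutual-information (JMI) criterion scores a candidate feature
``s_i`` against the already-selected set ``D`` as

    JMI(s_i) = sum_{s_j in D} I(s_i, s_j; Y)

where ``I(X, S; Y) = I(X; Y | S) + I(S; Y)`` is the joint relevance of
the pair to the class label.  Selection is greedy-forward: the first
feature maximizes marginal I(s; Y); each later pick maximizes the JMI
score over the remaining candidates, ties broken by lowest column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "SelectedSet",
    "mutual_information",
    "conditional_mutual_information",
    "joint_relevance",
    "jmi_score",
    "greedy_select",
]

_LN2 = float(np.log(2.0))


@dataclass
class SelectedSet:
    """Ordered record of admitted feature indices and their admission scores."""

    indices: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def add(self, index: int, score: float) -> None:
        if index in self.indices:
            raise ValueError(f"feature {index} already selected")
        self.indices.append(index)
        self.scores.append(score)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


def _as_codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map an arbitrary discrete vector to contiguous codes 0..m-1."""
    _, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1 if codes.size else 1


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(-xlogy(p, p).sum() / _LN2)


def mutual_information(y: np.ndarray, z: np.ndarray) -> float:
    """I(Y;Z) = sum_{y,z} p(y,z) log2 p(y,z) / (p(y) p(z)), plug-in."""
    y = np.asarray(y)
    z = np.asarray(z)
    if y.shape != z.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {z.shape}")
    yc, my = _as_codes(y)
    zc, mz = _as_codes(z)
    joint = np.bincount(yc * mz + zc, minlength=my * mz).astype(float)
    hy = _entropy_from_counts(np.bincount(yc, minlength=my).astype(float))
    hz = _entropy_from_counts(np.bincount(zc, minlength=mz).astype(float))
    hyz = _entropy_from_counts(joint)
    return max(hy + hz - hyz, 0.0)


def conditional_mutual_information(
    x: np.ndarray, z: np.ndarray, given: np.ndarray
) -> float:
    """I(X;Z | given) = sum_y p(y) I(X;Z | Y=y), plug-in, in bits."""
    x = np.asarray(x)
    z = np.asarray(z)
    y = np.asarray(given)
    if not (x.shape == z.shape == y.shape):
        raise ValueError("all three vectors must have equal length")
    xc, mx = _as_codes(x)
    zc, mz = _as_codes(z)
    yc, my = _as_codes(y)
    # I(X;Z|Y) = H(X,Y) + H(Z,Y) - H(X,Z,Y) - H(Y)
    hxy = _entropy_from_counts(
        np.bincount(xc * my + yc, minlength=mx * my).astype(float)
    )
    hzy = _entropy_from_counts(
        np.bincount(zc * my + yc, minlength=mz * my).astype(float)
    )
    hxzy = _entropy_from_counts(
        np.bincount((xc * mz + zc) * my + yc, minlength=mx * mz * my).astype(float)
    )
    hy = _entropy_from_counts(np.bincount(yc, minlength=my).astype(float))
    return max(hxy + hzy - hxzy - hy, 0.0)


def joint_relevance(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """I(X,Y;Z): information the pair (x, y) carries about the target z.

    Computed through the chain decomposition I(X;Z|Y) + I(Y;Z); equal to
    the mutual information between the pair-encoded variable and z.
    """
    return conditional_mutual_information(x, z, y) + mutual_information(y, z)


def jmi_score(
    candidate: np.ndarray, selected_columns: np.ndarray, labels: np.ndarray
) -> float:
    """Sum of joint relevances of (candidate, s_j) with the label over s_j."""
    selected_columns = np.atleast_2d(np.asarray(selected_columns))
    if selected_columns.shape[1] == len(candidate) and selected_columns.shape[0] != len(
        candidate
    ):
        selected_columns = selected_columns.T
    if selected_columns.shape[1] == 0:
        raise ValueError("selected set must be non-empty for a JMI score")
    return float(
        sum(
            joint_relevance(candidate, selected_columns[:, j], labels)
            for j in range(selected_columns.shape[1])
        )
    )


# ---------------------------------------------------------------------------
# vectorized batch kernels over a genotype matrix (codes 0/1/2, labels 0/1)


def _marginal_mi_all(x_matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """I(x_j; Y) in bits for every column j, in one pass."""
    n, q = x_matrix.shape
    cell = x_matrix.astype(np.int64) * 2 + y[:, None]
    offset = np.arange(q, dtype=np.int64) * 6
    counts = (
        np.bincount((cell + offset[None, :]).ravel(), minlength=6 * q)
        .reshape(q, 3, 2)
        .astype(float)
    )
    return _mi_from_joint_counts(counts)


def _mi_from_joint_counts(counts: np.ndarray) -> np.ndarray:
    """Batch MI (bits) from a (q, a, b) array of joint counts."""
    n = counts.sum(axis=(1, 2), keepdims=True)
    p = counts / n
    pa = p.sum(axis=2, keepdims=True)
    pb = p.sum(axis=1, keepdims=True)
    h_a = -xlogy(pa, pa).sum(axis=(1, 2))
    h_b = -xlogy(pb, pb).sum(axis=(1, 2))
    h_ab = -xlogy(p, p).sum(axis=(1, 2))
    return np.maximum(h_a + h_b - h_ab, 0.0) / _LN2


def _joint_relevance_all(
    x_matrix: np.ndarray,
    s: np.ndarray,
    y: np.ndarray,
    _precomputed: np.ndarray | None = None,
) -> np.ndarray:
    """I((x_j, s); Y) in bits for every column j against one anchor s.

    ``_precomputed`` may carry ``x*6 + 18*column_index`` (int64) so the
    greedy loop avoids rebuilding the large cell-index matrix per step.
    """
    n, q = x_matrix.shape
    if _precomputed is None:
        offset = np.arange(q, dtype=np.int64) * 18
        _precomputed = x_matrix.astype(np.int64) * 6 + offset[None, :]
    base = (s.astype(np.int64) * 2 + y)[:, None]  # 6 states of (s, y)
    counts = (
        np.bincount((_precomputed + base).ravel(), minlength=18 * q)
        .reshape(q, 9, 2)
        .astype(float)
    )
    return _mi_from_joint_counts(counts)


def greedy_select(
    genotypes: np.ndarray, labels: np.ndarray, k: int
) -> SelectedSet:
    """Greedy-forward JMI selection of ``k`` SNP columns.

    ``genotypes`` must be complete (missing codes imputed beforehand).
    The accumulated JMI score of each remaining candidate is updated
    incrementally: admitting feature s adds I((x_j, s); Y) to every
    candidate j's running sum, so the whole trajectory costs O(k) batch
    passes over the matrix.
    """
    x = np.ascontiguousarray(genotypes)
    y = np.asarray(labels, dtype=np.int64)
    n, q = x.shape
    if k > q:
        raise ValueError(f"cannot select k={k} from q={q} columns")
    if (x < 0).any():
        raise ValueError("genotype matrix contains missing codes; impute first")

    selected = SelectedSet()
    mi = _marginal_mi_all(x, y)
    first = int(np.argmax(mi))
    selected.add(first, float(mi[first]))

    cum = np.zeros(q)
    mask = np.zeros(q, dtype=bool)
    mask[first] = True
    last = first
    cells = x.astype(np.int64) * 6 + (np.arange(q, dtype=np.int64) * 18)[None, :]
    for _ in range(1, k):
        cum += _joint_relevance_all(x, x[:, last], y, _precomputed=cells)
        scores = np.where(mask, -np.inf, cum)
        pick = int(np.argmax(scores))  # argmax takes the lowest index on ties
        selected.add(pick, float(cum[pick]))
        mask[pick] = True
        last = pick
    return selected
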