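"""Partition-agreement metrics: ARI, NMI, and the mean silhouette score.

All three are computed from first principles (contingency-table pair counts
and entropies; per-sample silhouette widths) rather than delegated, since
they are the package's internal model-selection and evaluation currency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "contingency",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "silhouette_mean",
    "silhouette_samples_",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Co-occurrence counts between two labelings of the same n samples."""

    counts: np.ndarray  # r×c integer matrix n_ij
    a: np.ndarray  # row sums a_i
    b: np.ndarray  # column sums b_j
    n: int


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(labels_a, labels_b) -> ContingencyTable:
    """Exact integer contingency table n_ij between two labelings."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValidationError(
            f"labelings have different lengths: {labels_a.shape} vs {labels_b.shape}"
        )
    if labels_a.size == 0:
        raise ValidationError("empty labelings")
    ca, cb = _as_codes(labels_a), _as_codes(labels_b)
    r, c = ca.max() + 1, cb.max() + 1
    counts = np.zeros((r, c), dtype=np.int64)
    np.add.at(counts, (ca, cb), 1)
    return ContingencyTable(
        counts=counts, a=counts.sum(axis=1), b=counts.sum(axis=0), n=int(counts.sum())
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index between two partitions.

    ARI = (Σ_ij C(n_ij,2) − E) / (½[Σ_i C(a_i,2) + Σ_j C(b_j,2)] − E)
    with E = Σ_i C(a_i,2)·Σ_j C(b_j,2) / C(n,2).  Equals 1 iff the
    partitions are identical; ~0 under random labelings.  Invariant to
    label renaming and to swapping the two arguments.
    """
    t = contingency(labels_a, labels_b)
    if t.n < 2:
        raise ValidationError("ARI needs at least 2 samples")
    sum_ij = sum(comb(int(x), 2) for x in t.counts.ravel())
    sum_a = sum(comb(int(x), 2) for x in t.a)
    sum_b = sum(comb(int(x), 2) for x in t.b)
    expected = sum_a * sum_b / comb(t.n, 2)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        # both labelings are trivial (identical partitions); perfect overlap
        return 1.0
    return float((sum_ij - expected) / denom)


def normalized_mutual_information(labels_a, labels_b) -> float:
    """NMI(C, K) = 2·I(C, K) / (H(C) + H(K)), natural-log entropies.

    Ranges from 0 (independent labelings) to 1 (identical partitions).  The
    2I/(H+H) form makes the value independent of the log base.
    """
    t = contingency(labels_a, labels_b)
    n = t.n
    pa = t.a / n
    pb = t.b / n
    ha = float(-np.sum(pa[pa > 0] * np.log(pa[pa > 0])))
    hb = float(-np.sum(pb[pb > 0] * np.log(pb[pb > 0])))
    if ha + hb == 0:
        # both labelings constant: the two trivial partitions are identical
        logger.info("NMI degenerate case: both labelings constant; returning 1.0")
        return 1.0
    pij = t.counts / n
    mask = t.counts > 0
    outer = pa[:, None] * pb[None, :]
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    return float(np.clip(2.0 * mi / (ha + hb), 0.0, 1.0))


def silhouette_samples_(distances: np.ndarray, labels) -> np.ndarray:
    """Per-sample silhouette widths s_i = (b_i − a_i)/max(a_i, b_i).

    a_i is the mean distance from sample i to the other members of its own
    cluster; b_i is the smallest mean distance to the members of any other
    cluster.  Singleton clusters get s_i = 0 by convention.
    """
    D = np.asarray(distances, dtype=float)
    m = D.shape[0]
    if D.shape != (m, m):
        raise ValidationError("distance matrix must be square")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise ValidationError("distance matrix diagonal must be 0")
    if np.abs(D - D.T).max() > 1e-8 * max(1.0, np.abs(D).max()):
        raise ValidationError("distance matrix must be symmetric")
    codes = _as_codes(labels)
    if len(codes) != m:
        raise ValidationError("labels length does not match distance matrix")
    k = codes.max() + 1
    if k < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    sizes = np.bincount(codes, minlength=k)
    # mean distance from each sample to each cluster
    sums = np.zeros((m, k))
    for c in range(k):
        sums[:, c] = D[:, codes == c].sum(axis=1)
    s = np.zeros(m)
    for i in range(m):
        ci = codes[i]
        if sizes[ci] == 1:
            continue  # singleton convention: s_i = 0
        a_i = sums[i, ci] / (sizes[ci] - 1)
        other = [sums[i, c] / sizes[c] for c in range(k) if c != ci]
        b_i = min(other)
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return s


def silhouette_mean(distances: np.ndarray, labels) -> float:
    """Mean silhouette width over all samples; in [−1, 1]."""
    return float(silhouette_samples_(distances, labels).mean())
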