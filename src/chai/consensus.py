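"""Spectral readout of a fused similarity matrix and the consensus drivers.

The fused matrix is clustered with normalised-Laplacian spectral clustering
(symmetric normalisation, k leading eigenvectors, row-normalised embedding,
seeded k-means readout).  When the number of clusters is unknown, k is
chosen by scanning a range and keeping the k whose partition maximises the
mean silhouette on the similarity-derived distance d = 1 − S/max(S).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .assignments import AlignedEnsemble, to_binary_similarity
from .errors import ValidationError
from .fusion import (
    FusedSimilarityMatrix,
    SNFParams,
    average_similarity,
    snf_fuse,
)
from .metrics import silhouette_mean

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "spectral_cluster",
    "select_k_by_silhouette",
    "chai_avgsim",
    "chai_snf",
    "DEFAULT_K_SCAN",
]

#: Default scan range for automatic k selection.
DEFAULT_K_SCAN = (2, 15)


@dataclass(frozen=True)
class ConsensusResult:
    """Final consensus labels with full provenance.

    labels are integers 1..k, re-coded in order of first appearance so a
    rerun with the same inputs and seed is byte-identical.
    """

    cell_ids: tuple[str, ...]
    labels: tuple[int, ...]
    method: str
    k: int
    k_mode: str  # "user" or "silhouette"
    seed: int
    silhouette_trace: tuple[tuple[int, float], ...] = ()
    params: SNFParams | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError("labels length does not match cell ids")
        if len(set(self.labels)) != self.k:
            raise ValidationError(
                f"labels take {len(set(self.labels))} values but k={self.k}"
            )

    def provenance(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "k_mode": self.k_mode,
            "seed": self.seed,
            "silhouette_trace": [[k, s] for k, s in self.silhouette_trace],
            "params": asdict(self.params) if self.params is not None else None,
        }


def _canonical_labels(raw: np.ndarray) -> tuple[int, ...]:
    """Re-code arbitrary integer labels to 1..k by order of first appearance."""
    mapping: dict[int, int] = {}
    out = []
    for v in raw:
        v = int(v)
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out.append(mapping[v])
    return tuple(out)


def spectral_cluster(S: FusedSimilarityMatrix, k: int, seed: int = 0) -> tuple[int, ...]:
    """Normalised-Laplacian spectral clustering of a similarity matrix.

    Builds the symmetrically normalised affinity D^{-1/2} A D^{-1/2} (self-
    affinities removed), embeds cells in its k leading eigenvectors, row-
    normalises the embedding, and reads out clusters with k-means (fixed
    seed, 10 restarts).  Deterministic given (S, k, seed).
    """
    A = np.asarray(S.values, dtype=float).copy()
    m = A.shape[0]
    if not (2 <= k <= m):
        raise ValidationError(f"k must be in [2, {m}], got {k}")
    if k == m:
        # degenerate: every cell its own cluster; the embedding carries no
        # usable geometry at k=m
        return tuple(range(1, m + 1))
    np.fill_diagonal(A, 0.0)
    n_comp, _ = connected_components((A > 0).astype(np.int8), directed=False)
    if n_comp > k:
        logger.warning(
            "similarity graph has %d components but k=%d; eigen-solver proceeds", n_comp, k
        )
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    M = dinv[:, None] * A * dinv[None, :]
    # k largest eigenvalues of the normalised affinity = k smallest of L_sym
    _, vecs = eigh(M, subset_by_index=(m - k, m - 1))
    norms = np.linalg.norm(vecs, axis=1)
    emb = vecs / np.where(norms > 0, norms, 1.0)[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(emb)
    raw = _top_up_clusters(raw, k)
    return _canonical_labels(raw)


def _top_up_clusters(raw: np.ndarray, k: int) -> np.ndarray:
    """Guarantee k non-empty clusters.

    With fewer distinct structures than k the embedding contains duplicate
    points and k-means can return < k clusters; deterministically split the
    largest cluster (lowest cell indices first) until k are occupied.  The
    silhouette scan then penalises these forced singletons, so an inflated
    k never wins the scan on perfectly blocked input.
    """
    present = len(set(raw.tolist()))
    if present == k:
        return raw
    logger.warning("k-means found %d < k=%d clusters; splitting to top up", present, k)
    raw = raw.copy()
    next_label = raw.max() + 1
    while len(set(raw.tolist())) < k:
        counts = np.bincount(raw)
        largest = int(np.argmax(counts))
        idx = int(np.flatnonzero(raw == largest)[0])
        raw[idx] = next_label
        next_label += 1
    return raw


def _similarity_to_distance(S: FusedSimilarityMatrix) -> np.ndarray:
    """d = 1 − S/max(S): the distance used for silhouette-based k selection."""
    v = np.asarray(S.values, dtype=float)
    top = v.max()
    if top <= 0:
        raise ValidationError("similarity matrix has no positive entries")
    d = 1.0 - v / top
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def select_k_by_silhouette(
    S: FusedSimilarityMatrix,
    k_min: int = DEFAULT_K_SCAN[0],
    k_max: int = DEFAULT_K_SCAN[1],
    seed: int = 0,
) -> tuple[int, tuple[tuple[int, float], ...]]:
    """Scan k in [k_min, k_max]; return the silhouette-maximising k.

    Each candidate partition comes from :func:`spectral_cluster`; its mean
    silhouette is computed on d = 1 − S/max(S).  Ties go to the smallest k
    (parsimony).  Returns (k, trace) with the full (k, score) trace in
    ascending k.
    """
    m = len(S.cell_ids)
    if k_max < k_min:
        raise ValidationError(f"k_max={k_max} < k_min={k_min}")
    if not (2 <= k_min and k_max <= m - 1):
        raise ValidationError(f"scan range [{k_min}, {k_max}] outside [2, {m - 1}]")
    D = _similarity_to_distance(S)
    trace = []
    for k in range(k_min, k_max + 1):
        labels = spectral_cluster(S, k, seed=seed)
        trace.append((k, silhouette_mean(D, labels)))
    best_k = max(trace, key=lambda ks: (ks[1], -ks[0]))[0]
    return best_k, tuple(trace)


def _readout(
    S: FusedSimilarityMatrix,
    method: str,
    k: int | None,
    seed: int,
    k_scan: tuple[int, int] | None,
    params: SNFParams | None,
) -> ConsensusResult:
    if k is None:
        lo, hi = k_scan if k_scan is not None else DEFAULT_K_SCAN
        hi = min(hi, len(S.cell_ids) - 1)
        k_sel, trace = select_k_by_silhouette(S, lo, hi, seed=seed)
        k_mode = "silhouette"
    else:
        k_sel, trace, k_mode = k, (), "user"
    labels = spectral_cluster(S, k_sel, seed=seed)
    return ConsensusResult(
        cell_ids=S.cell_ids,
        labels=labels,
        method=method,
        k=k_sel,
        k_mode=k_mode,
        seed=seed,
        silhouette_trace=trace,
        params=params,
    )


def chai_avgsim(
    ensemble: AlignedEnsemble,
    k: int | None = None,
    seed: int = 0,
    k_scan: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Consensus by average similarity: encode, average, spectral readout.

    ``k=None`` triggers silhouette-guided selection over ``k_scan``
    (default 2..15, clamped to m−1).
    """
    mats = [to_binary_similarity(a) for a in ensemble.assignments]
    fused = average_similarity(mats)
    return _readout(fused, "avgsim", k, seed, k_scan, None)


def chai_snf(
    ensemble: AlignedEnsemble,
    params: SNFParams = SNFParams(),
    k: int | None = None,
    seed: int = 0,
    k_scan: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Consensus by SNF: encode, cross-diffuse the views, spectral readout."""
    if ensemble.n < 2:
        raise ValidationError("SNF consensus needs at least 2 assignments")
    m = ensemble.n_cells
    eff = params
    if params.K > m - 1:
        eff = SNFParams(K=m - 1, t=params.t)
    mats = [to_binary_similarity(a) for a in ensemble.assignments]
    fused = snf_fuse(mats, eff)
    result = _readout(fused, "snf", k, seed, k_scan, eff)
    return result
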