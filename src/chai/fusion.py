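"""Fusion of binary similarity matrices: element-wise averaging and SNF.

Two routes combine the per-algorithm co-membership matrices into one fused
cell×cell similarity:

* **AvgSim** — the entry-wise arithmetic mean, M̄_ij = (1/n) Σ_k M^(k)_ij.
* **SNF** — similarity network fusion (Wang et al. cross-diffusion): each
  view is row-normalised, a sparse local kernel keeps only each cell's K
  strongest neighbours (suppressing weak edges), and the views are
  iteratively diffused through each other until they agree.  The binary
  matrices are fed to SNF directly as affinities — no distance kernel is
  involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assignments import BinarySimilarityMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SNFParams",
    "FusedSimilarityMatrix",
    "average_similarity",
    "snf_row_normalize",
    "snf_local_kernel",
    "snf_fuse",
]

#: Symmetry tolerance used on fused outputs.
SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class SNFParams:
    """SNF hyperparameters.

    K is the local-kernel neighbourhood size (clamped to m−1 for small
    inputs); t is the number of cross-diffusion iterations.  Defaults match
    the reference implementation's documented defaults (K=20, t=20).
    """

    K: int = 20
    t: int = 20

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"SNF K must be >= 1, got {self.K}")
        if self.t < 1:
            raise ValidationError(f"SNF t must be >= 1, got {self.t}")


@dataclass(frozen=True)
class FusedSimilarityMatrix:
    """Non-negative symmetric m×m similarity produced by a fusion method."""

    cell_ids: tuple[str, ...]
    values: np.ndarray
    method: str  # "avgsim" or "snf"
    params: SNFParams | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = len(self.cell_ids)
        if v.shape != (m, m):
            raise ValidationError(f"matrix shape {v.shape} does not match {m} cells")
        if not np.isfinite(v).all():
            raise ValidationError("fused matrix has non-finite entries")
        if (v < 0).any():
            raise ValidationError("fused matrix has negative entries")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > SYMMETRY_RTOL * scale:
            raise ValidationError("fused matrix is not symmetric within tolerance")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))


def _check_aligned(matrices) -> tuple[str, ...]:
    if len(matrices) == 0:
        raise ValidationError("no matrices to fuse")
    ids = matrices[0].cell_ids
    for mat in matrices[1:]:
        if mat.cell_ids != ids:
            raise ValidationError(
                f"matrix {mat.source!r} has a different cell order; align the ensemble first"
            )
    return ids


def average_similarity(
    matrices: list[BinarySimilarityMatrix] | tuple[BinarySimilarityMatrix, ...],
) -> FusedSimilarityMatrix:
    """Entry-wise arithmetic mean of n binary matrices over the same cells.

    The result is symmetric with unit diagonal and entries in [0, 1]; entry
    (i, j) is the fraction of views in which cells i and j co-cluster.
    """
    ids = _check_aligned(matrices)
    stack = np.stack([m.values.astype(float) for m in matrices])
    return FusedSimilarityMatrix(cell_ids=ids, values=stack.mean(axis=0), method="avgsim")


def snf_row_normalize(W: np.ndarray) -> np.ndarray:
    """Row-normalise a similarity matrix to the SNF transition form.

    Off-diagonal entries of row i become W[i, j] / (2·Σ_{j≠i} W[i, j]) and
    the diagonal is fixed at 1/2, so every row sums to 1 while half the
    probability mass stays on the cell itself.  A degenerate row whose
    off-diagonal sum is 0 gets uniform off-diagonal mass (logged) instead of
    dividing by zero.
    """
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    if m < 2:
        raise ValidationError("row normalisation needs at least 2 cells")
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    degenerate = rowsum == 0
    if degenerate.any():
        logger.warning(
            "%d row(s) share no similarity with any other cell; using uniform mass",
            int(degenerate.sum()),
        )
        off[degenerate, :] = 1.0
        off[degenerate, np.arange(m)[degenerate]] = 0.0
        rowsum[degenerate] = float(m - 1)
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def snf_local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Sparse local kernel: keep each row's K strongest neighbours.

    Row i of the result is supported on the K largest off-diagonal entries
    of row i of W (ties at the cutoff broken toward the smallest cell
    index), renormalised to sum to 1.  Entries outside the top K — the
    "weak edges" — are zeroed.  K > m−1 is clamped with a warning.
    """
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if K > m - 1:
        logger.warning("K=%d exceeds m-1=%d; clamping", K, m - 1)
        K = m - 1
    S = np.zeros_like(W)
    idx = np.arange(m)
    for i in range(m):
        row = W[i].copy()
        row[i] = -np.inf  # exclude self from neighbour candidates
        # stable sort on (-value, index): largest values first, smallest
        # index first among ties
        order = np.lexsort((idx, -row))
        keep = order[:K]
        kept = W[i, keep]
        total = kept.sum()
        if total == 0:
            S[i, keep] = 1.0 / K  # all-tied degenerate row: uniform over candidates
        else:
            S[i, keep] = kept / total
    return S


def snf_fuse_arrays(
    values_list, cell_ids, params: SNFParams = SNFParams()
) -> FusedSimilarityMatrix:
    """SNF cross-diffusion over raw non-negative similarity arrays.

    Each view v is row-normalised to P_v and reduced to a local kernel S_v.
    For t iterations every view is updated as

        P_v ← S_v · mean_{w≠v}(P_w) · S_vᵀ

    followed by re-normalisation and symmetrisation, which pulls the
    networks toward each other; strong edges supported by several views
    survive, weak idiosyncratic ones decay.  The output is the average of
    the final P_v, re-normalised, symmetrised and diagonally regularised as
    in the reference method: W = (W + Wᵀ + I)/2.
    """
    if len(values_list) < 2:
        raise ValidationError("SNF needs at least 2 views to fuse")
    m = len(cell_ids)
    if m < 3:
        raise ValidationError("SNF needs at least 3 cells")

    P = []
    S = []
    for W in values_list:
        Pv = snf_row_normalize(np.asarray(W, dtype=float))
        Pv = (Pv + Pv.T) / 2.0
        P.append(Pv)
        S.append(snf_local_kernel(Pv, params.K))

    n = len(P)
    for _ in range(params.t):
        new = []
        for v in range(n):
            others = sum(P[w] for w in range(n) if w != v) / (n - 1)
            new.append(S[v] @ others @ S[v].T)
        for v in range(n):
            Pv = snf_row_normalize(new[v])
            P[v] = (Pv + Pv.T) / 2.0

    W = sum(P) / n
    W = snf_row_normalize(W)
    W = (W + W.T + np.eye(m)) / 2.0
    return FusedSimilarityMatrix(
        cell_ids=tuple(cell_ids), values=W, method="snf", params=params
    )


def snf_fuse(
    matrices: list[BinarySimilarityMatrix] | tuple[BinarySimilarityMatrix, ...],
    params: SNFParams = SNFParams(),
) -> FusedSimilarityMatrix:
    """Fuse n ≥ 2 aligned binary similarity views by SNF (see
    :func:`snf_fuse_arrays` for the update equations)."""
    if len(matrices) < 2:
        raise ValidationError("SNF needs at least 2 views to fuse")
    ids = _check_aligned(matrices)
    return snf_fuse_arrays([m.values.astype(float) for m in matrices], ids, params)
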