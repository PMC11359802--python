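"""Spatial-transcriptomics integration via a binary KNN adjacency.

Spot coordinates are turned into a cell×cell binary matrix: entry (i, j) is
1 when j is among the K spatially nearest neighbours of i (or vice versa —
the graph is symmetrised by union).  That matrix is then just another view:
averaged in alongside the assignment matrices (AvgSim-ST), fused with them
in one SNF pass (first level), or fused in a second SNF pass against the
already-fused assignment matrix, which upweights the spatial modality
(second level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .assignments import (
    AlignedEnsemble,
    BinarySimilarityMatrix,
    to_binary_similarity,
)
from .consensus import ConsensusResult, _readout
from .errors import ValidationError
from .fusion import SNFParams, average_similarity, snf_fuse, snf_fuse_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialCoordinates",
    "read_coordinates",
    "write_coordinates",
    "spatial_binary_adjacency",
    "chai_avgsim_st",
    "chai_snf_first_level",
    "chai_snf_second_level",
    "DEFAULT_SPATIAL_K",
]

#: Neighbourhood size of the spatial KNN graph.
DEFAULT_SPATIAL_K = 3


@dataclass(frozen=True)
class SpatialCoordinates:
    """Per-cell spatial positions (d-dimensional, typically 2-D)."""

    cell_ids: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[0] != len(self.cell_ids):
            raise ValidationError(
                f"coords shape {c.shape} does not match {len(self.cell_ids)} cells"
            )
        if not np.isfinite(c).all():
            raise ValidationError("coordinates must be finite")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "cell_ids", tuple(str(i) for i in self.cell_ids))

    def reindex(self, cell_ids) -> "SpatialCoordinates":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            order = [pos[c] for c in cell_ids]
        except KeyError as exc:
            raise ValidationError(f"cell id missing from coordinates: {exc.args[0]!r}") from exc
        return SpatialCoordinates(cell_ids=tuple(cell_ids), coords=self.coords[order])


def read_coordinates(
    path,
    id_column: str = "cell_id",
    coord_columns: tuple[str, ...] = ("x", "y"),
    delimiter: str = ",",
) -> SpatialCoordinates:
    """Read a delimited coordinate table (cell_id, x, y[, ...])."""
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in (id_column, *coord_columns) if c not in df.columns]
    if missing:
        from .errors import FormatError

        raise FormatError(f"columns {missing} not found in {path}")
    return SpatialCoordinates(
        cell_ids=tuple(str(c) for c in df[id_column]),
        coords=df[list(coord_columns)].to_numpy(dtype=float),
    )


def write_coordinates(
    coords: SpatialCoordinates,
    path,
    id_column: str = "cell_id",
    delimiter: str = ",",
) -> None:
    import pandas as pd

    d = coords.coords.shape[1]
    names = ["x", "y", "z"][:d] if d <= 3 else [f"x{i}" for i in range(d)]
    df = pd.DataFrame(coords.coords, columns=names)
    df.insert(0, id_column, list(coords.cell_ids))
    df.to_csv(path, sep=delimiter, index=False)


def spatial_binary_adjacency(
    coords: SpatialCoordinates, K: int = DEFAULT_SPATIAL_K
) -> BinarySimilarityMatrix:
    """Binary KNN adjacency of the spots, symmetrised by union.

    Pairwise Euclidean distances on the raw coordinates; (i, j) = 1 iff j is
    among the K nearest neighbours of i OR i among the K nearest of j.  Self
    is excluded from the neighbour candidates and the diagonal fixed to 1.
    Distance ties at the K-th neighbour break toward the smallest index.
    Scale-invariant: rescaling all coordinates leaves the graph unchanged.
    """
    m = len(coords.cell_ids)
    if K >= m:
        raise ValidationError(f"K={K} must be < number of cells ({m})")
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    D = squareform(pdist(coords.coords))
    idx = np.arange(m)
    A = np.zeros((m, m), dtype=np.uint8)
    for i in range(m):
        d = D[i].copy()
        d[i] = np.inf
        order = np.lexsort((idx, d))  # nearest first; ties to smallest index
        A[i, order[:K]] = 1
    A = np.maximum(A, A.T)  # union symmetrisation
    np.fill_diagonal(A, 1)
    return BinarySimilarityMatrix(cell_ids=coords.cell_ids, values=A, source="spatial")


def _aligned_spatial(
    ensemble: AlignedEnsemble, coords: SpatialCoordinates, spatial_K: int
) -> BinarySimilarityMatrix:
    if set(coords.cell_ids) != set(ensemble.cell_ids):
        raise ValidationError("coordinate cell ids do not match the ensemble's cells")
    return spatial_binary_adjacency(coords.reindex(ensemble.cell_ids), K=spatial_K)


def chai_avgsim_st(
    ensemble: AlignedEnsemble,
    coords: SpatialCoordinates,
    k: int | None = None,
    seed: int = 0,
    spatial_K: int = DEFAULT_SPATIAL_K,
    k_scan: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Average similarity over the n assignment views plus the spatial view."""
    spatial = _aligned_spatial(ensemble, coords, spatial_K)
    mats = [to_binary_similarity(a) for a in ensemble.assignments] + [spatial]
    fused = average_similarity(mats)
    return _readout(fused, "avgsim-st", k, seed, k_scan, None)


def chai_snf_first_level(
    ensemble: AlignedEnsemble,
    coords: SpatialCoordinates,
    params: SNFParams = SNFParams(),
    k: int | None = None,
    seed: int = 0,
    spatial_K: int = DEFAULT_SPATIAL_K,
    k_scan: tuple[int, int] | None = None,
) -> ConsensusResult:
    """One SNF pass over the assignment views and the spatial view together."""
    spatial = _aligned_spatial(ensemble, coords, spatial_K)
    mats = [to_binary_similarity(a) for a in ensemble.assignments] + [spatial]
    eff = _clamp(params, ensemble.n_cells)
    fused = snf_fuse(mats, eff)
    return _readout(fused, "snf-first-level", k, seed, k_scan, eff)


def chai_snf_second_level(
    ensemble: AlignedEnsemble,
    coords: SpatialCoordinates,
    params: SNFParams = SNFParams(),
    k: int | None = None,
    seed: int = 0,
    spatial_K: int = DEFAULT_SPATIAL_K,
    k_scan: tuple[int, int] | None = None,
) -> ConsensusResult:
    """Two-pass SNF: fuse the assignment views first, then fuse that result
    with the spatial view.

    Entering the spatial matrix as one of only two views in the second pass
    gives it more weight than first-level fusion, where it is one view among
    n+1.
    """
    if ensemble.n < 2:
        raise ValidationError("second-level SNF needs at least 2 assignments")
    spatial = _aligned_spatial(ensemble, coords, spatial_K)
    eff = _clamp(params, ensemble.n_cells)
    mats = [to_binary_similarity(a) for a in ensemble.assignments]
    level1 = snf_fuse(mats, eff)
    fused = snf_fuse_arrays(
        [level1.values, spatial.values.astype(float)], level1.cell_ids, eff
    )
    return _readout(fused, "snf-second-level", k, seed, k_scan, eff)


def _clamp(params: SNFParams, m: int) -> SNFParams:
    if params.K > m - 1:
        return SNFParams(K=m - 1, t=params.t)
    return params
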