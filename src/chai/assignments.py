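"""Cluster-assignment tables and their binary similarity-matrix encoding.

A clustering algorithm's output is a two-column table: a cell identifier and
an opaque cluster label.  Each such partition is encoded as an m×m binary
co-membership matrix with entry 1 where two cells share a cluster.  Several
partitions over the same cells are aligned to a canonical cell order before
fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "AlignedEnsemble",
    "BinarySimilarityMatrix",
    "read_assignment_table",
    "write_assignment_table",
    "align_ensemble",
    "to_binary_similarity",
    "write_similarity_csv",
    "read_similarity_csv",
    "write_similarity_mtx",
    "read_similarity_mtx",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """One algorithm's partition of the cells.

    Parameters
    ----------
    algorithm_name
        Free-text tag identifying the producing algorithm.
    cell_ids
        Unique cell identifiers, in table row order.
    labels
        Cluster label per cell.  Labels are opaque categories: numeric
        labels carry no ordering.
    """

    algorithm_name: str
    cell_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(self.cell_ids) == 0:
            raise ValidationError("assignment has no cells")
        if len(self.labels) != len(self.cell_ids):
            raise ValidationError(
                f"labels length {len(self.labels)} != cell_ids length {len(self.cell_ids)}"
            )
        seen: set[str] = set()
        for c in self.cell_ids:
            if c in seen:
                raise ValidationError(f"duplicate cell id: {c!r}")
            seen.add(c)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def reindex(self, cell_ids: tuple[str, ...]) -> "ClusterAssignment":
        """Return a copy reordered to the given cell-id order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            order = [pos[c] for c in cell_ids]
        except KeyError as exc:
            raise ValidationError(f"cell id missing from assignment: {exc.args[0]!r}") from exc
        return ClusterAssignment(
            algorithm_name=self.algorithm_name,
            cell_ids=tuple(cell_ids),
            labels=tuple(self.labels[i] for i in order),
        )


@dataclass(frozen=True)
class AlignedEnsemble:
    """Several assignments re-indexed to one canonical cell order."""

    cell_ids: tuple[str, ...]
    assignments: tuple[ClusterAssignment, ...]

    def __post_init__(self) -> None:
        if len(self.assignments) < 1:
            raise ValidationError("ensemble needs at least one assignment")
        for a in self.assignments:
            if a.cell_ids != self.cell_ids:
                raise ValidationError(
                    f"assignment {a.algorithm_name!r} is not aligned to the canonical order"
                )

    @property
    def n(self) -> int:
        return len(self.assignments)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class BinarySimilarityMatrix:
    """Symmetric m×m co-membership matrix with unit diagonal.

    ``values[i, j] == 1`` iff cells i and j share a cluster (or are spatial
    neighbours, for ``source='spatial'``).
    """

    cell_ids: tuple[str, ...]
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        m = len(self.cell_ids)
        if v.shape != (m, m):
            raise ValidationError(f"matrix shape {v.shape} does not match {m} cells")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("binary similarity matrix entries must be 0 or 1")
        if not np.array_equal(v, v.T):
            raise ValidationError("binary similarity matrix must be symmetric")
        if not (np.diag(v) == 1).all():
            raise ValidationError("binary similarity matrix diagonal must be 1")
        object.__setattr__(self, "values", v.astype(np.uint8))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))


def read_assignment_table(
    path: str | Path,
    id_column: str = "cell_id",
    label_column: str = "cluster",
    delimiter: str = ",",
    algorithm_name: str | None = None,
) -> ClusterAssignment:
    """Read a delimited cell-id/cluster table into a :class:`ClusterAssignment`.

    The file must have a header row containing ``id_column`` and
    ``label_column``.  Row order is preserved; labels are read as opaque
    strings.  Defaults to the stem of ``path`` as the algorithm name.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty assignment table: {path}") from exc
    for col in (id_column, label_column):
        if col not in df.columns:
            raise FormatError(
                f"column {col!r} not found in {path} (columns: {list(df.columns)})"
            )
    if len(df) == 0:
        raise ValidationError(f"assignment table has no rows: {path}")
    dup = df[id_column][df[id_column].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell id in {path}: {dup.iloc[0]!r}")
    return ClusterAssignment(
        algorithm_name=algorithm_name if algorithm_name is not None else path.stem,
        cell_ids=tuple(df[id_column]),
        labels=tuple(df[label_column]),
    )


def write_assignment_table(
    assignment: ClusterAssignment,
    path: str | Path,
    id_column: str = "cell_id",
    label_column: str = "cluster",
    delimiter: str = ",",
) -> None:
    """Write an assignment as a delimited two-column table with header."""
    df = pd.DataFrame(
        {id_column: list(assignment.cell_ids), label_column: list(assignment.labels)}
    )
    df.to_csv(path, sep=delimiter, index=False)


def align_ensemble(
    assignments: list[ClusterAssignment] | tuple[ClusterAssignment, ...],
    intersect: bool = False,
) -> AlignedEnsemble:
    """Re-index assignments to the cell order of the first one.

    All assignments must cover the same cell-id set; order may differ.  A
    mismatch raises :class:`ValidationError` naming the symmetric-difference
    ids unless ``intersect=True``, which drops to the common cells (logging
    the dropped count) — an explicit opt-in, because silent intersection
    hides upstream failures.
    """
    assignments = tuple(assignments)
    if len(assignments) < 1:
        raise ValidationError("align_ensemble needs at least one assignment")
    sets = [set(a.cell_ids) for a in assignments]
    common = set.intersection(*sets)
    union = set.union(*sets)
    if common != union:
        diff = sorted(union - common)
        if not intersect:
            raise ValidationError(
                "assignments do not cover the same cells; "
                f"ids missing from some assignment: {diff}"
            )
        dropped = len(union) - len(common)
        logger.warning("intersection mode: dropped %d cell ids not shared by all views", dropped)
        if not common:
            raise ValidationError("no cells shared by all assignments")
        canonical = tuple(c for c in assignments[0].cell_ids if c in common)
    else:
        canonical = assignments[0].cell_ids
    return AlignedEnsemble(
        cell_ids=canonical,
        assignments=tuple(a.reindex(canonical) for a in assignments),
    )


def to_binary_similarity(assignment: ClusterAssignment) -> BinarySimilarityMatrix:
    """Encode a partition as its binary co-membership matrix.

    Entry (i, j) is 1 exactly when cells i and j carry the same cluster
    label; the diagonal is 1 (a cell trivially co-clusters with itself).
    """
    codes = pd.Categorical(list(assignment.labels)).codes
    eq = (codes[:, None] == codes[None, :]).astype(np.uint8)
    return BinarySimilarityMatrix(
        cell_ids=assignment.cell_ids, values=eq, source=assignment.algorithm_name
    )


# ---------------------------------------------------------------------------
# Matrix IO: dense CSV with cell ids as header/rownames, or matrix-market
# triplets with a sidecar id list (one id per line).


def write_similarity_csv(cell_ids, values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(values), index=list(cell_ids), columns=list(cell_ids)).to_csv(path)


def read_similarity_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    ids = tuple(str(c) for c in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise FormatError(f"row and column ids disagree in {path}")
    return ids, df.to_numpy(dtype=float)


def write_similarity_mtx(cell_ids, values: np.ndarray, path: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    path = Path(path)
    mmwrite(str(path), coo_matrix(np.asarray(values)))
    sidecar = path.with_suffix(path.suffix + ".ids.txt")
    sidecar.write_text("\n".join(str(c) for c in cell_ids) + "\n")


def read_similarity_mtx(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    from scipy.io import mmread

    path = Path(path)
    values = np.asarray(mmread(str(path)).todense(), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".ids.txt")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar id list: {sidecar}")
    ids = tuple(sidecar.read_text().split())
    if len(ids) != values.shape[0]:
        raise FormatError(f"sidecar id count {len(ids)} != matrix dimension {values.shape[0]}")
    return ids, values
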