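"""Expression input: dense tables, sparse single-cell triplets, annotations.

All readers produce an :class:`ExpressionMatrix`: a non-negative
gene-by-sample pandas frame plus an optional per-sample annotation
(condition, cell type, or cluster label).  Single cells are collapsed to
cluster-mean profiles with :func:`cluster_average` before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

if TYPE_CHECKING:  # pragma: no cover
    from .lr_database import InteractionDatabase

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Non-negative gene-by-sample expression values with annotations."""

    values: pd.DataFrame  # genes x samples
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene symbols must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            gene, sample = np.unravel_index(np.nanargmin(vals), vals.shape)
            raise ValueError(
                f"negative expression for gene {self.values.index[gene]!r} "
                f"in sample {self.values.columns[sample]!r}"
            )
        unknown = set(self.annotation) - set(self.values.columns)
        if unknown:
            raise ValueError(f"annotation refers to unknown samples: {sorted(unknown)}")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s, lab in self.annotation.items() if lab == label]


@dataclass
class MissingGeneReport:
    """Database genes not present in an expression matrix."""

    missing: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.missing)


def _dedupe_genes(frame: pd.DataFrame) -> pd.DataFrame:
    # Keep the duplicate row with the largest total signal; deterministic
    # and order-independent.
    if frame.index.is_unique:
        return frame
    totals = frame.sum(axis=1)
    order = np.argsort(-totals.to_numpy(), kind="stable")
    best = frame.iloc[order]
    dropped = best.index.duplicated(keep="first")
    logger.warning(
        "duplicate gene rows resolved by max total signal: %s",
        sorted(set(best.index[dropped])),
    )
    best = best[~dropped]
    return best.loc[[g for g in dict.fromkeys(frame.index) if g in best.index]]


def read_expression_table(
    path: str | Path, annotation: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table.

    First column holds gene symbols, header row holds sample ids.  Separator
    is inferred from the extension (``.csv`` -> comma, otherwise tab).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = None
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    frame = _dedupe_genes(frame)
    return ExpressionMatrix(values=frame, annotation=dict(annotation or {}))


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    m.values.to_csv(path, sep=sep, index_label="gene")


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, label) delimited file, no header."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    return dict(zip(frame[0], frame[1]))


def read_sparse_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> ExpressionMatrix:
    """Read an MTX coordinate triplet (genes x cells) with label files.

    ``genes_path`` and ``cells_path`` are line-per-entry plain-text files;
    entries absent from the triplet are zero.
    """
    mat = spio.mmread(str(matrix_path))
    mat = sparse.csr_matrix(mat)
    genes = Path(genes_path).read_text().split()
    cells = Path(cells_path).read_text().split()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape}, labels are "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    frame = pd.DataFrame(mat.toarray(), index=genes, columns=cells, dtype=float)
    frame = _dedupe_genes(frame)
    return ExpressionMatrix(values=frame)


def write_sparse_counts(
    m: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write the matrix as an MTX coordinate triplet plus label files."""
    coo = sparse.coo_matrix(m.values.to_numpy())
    spio.mmwrite(str(matrix_path), coo)
    Path(genes_path).write_text("\n".join(m.gene_symbols) + "\n")
    Path(cells_path).write_text("\n".join(m.sample_ids) + "\n")


def cluster_average(
    m: ExpressionMatrix, assignment: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse cells to per-cluster arithmetic-mean profiles.

    ``assignment`` maps cell id -> cluster label.  Cells in the matrix but
    absent from the assignment are ignored with a warning; assigned cells
    missing from the matrix are an error.
    """
    missing = set(assignment) - set(m.values.columns)
    if missing:
        raise ValueError(f"assigned cells not in matrix: {sorted(missing)}")
    unassigned = set(m.values.columns) - set(assignment)
    if unassigned:
        logger.warning("ignoring %d unassigned cells", len(unassigned))

    clusters: dict[str, list[str]] = {}
    for cell, label in assignment.items():
        clusters.setdefault(label, []).append(cell)
    if not clusters:
        raise ValueError("assignment is empty")

    means = {}
    annotation = {}
    for label in sorted(clusters):
        cells = clusters[label]
        means[label] = m.values[cells].mean(axis=1)
        annotation[label] = f"{label} (n={len(cells)})"
    return ExpressionMatrix(values=pd.DataFrame(means), annotation=annotation)


def restrict_to_database_genes(
    m: ExpressionMatrix, db: "InteractionDatabase"
) -> tuple[ExpressionMatrix, MissingGeneReport]:
    """Keep only rows for genes in the database universe.

    Returns the restricted matrix plus a report of database genes the
    platform did not capture.  An empty intersection is an error: nothing
    could be scored.
    """
    universe = db.gene_universe
    present = [g for g in m.values.index if g in universe]
    if not present:
        raise ValueError("no database genes found in the expression matrix")
    report = MissingGeneReport(missing=sorted(universe - set(present)))
    restricted = ExpressionMatrix(
        values=m.values.loc[present], annotation=dict(m.annotation)
    )
    return restricted, report
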