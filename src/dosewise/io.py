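"""Readers and writers for the on-disk formats the pipeline touches.

On disk, count matrices follow the 10x convention (genes as MTX rows,
1-based coordinates); internally everything is cells x genes. All
identifiers at the API surface are string labels, never positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse non-negative integer cells x genes matrix with string labels."""

    matrix: sp.csr_matrix
    cells: pd.Index
    genes: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.cells = pd.Index(self.cells, name="cell")
        self.genes = pd.Index(self.genes, name="gene")
        if self.matrix.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        for name, idx in (("cell", self.cells), ("gene", self.genes)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()[:5]
                raise ValueError(f"duplicate {name} identifiers: {dups}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=1)).ravel()

    def subset_cells(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.cells.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5].tolist()
                raise KeyError(f"unknown cells: {missing}")
        return CountMatrix(self.matrix[idx], self.cells[idx], self.genes)

    def subset_genes(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.genes.get_indexer(keep)
            if (idx < 0).any():
                missing = np.asarray(keep)[idx < 0][:5].tolist()
                raise KeyError(f"unknown genes: {missing}")
        return CountMatrix(self.matrix[:, idx], self.cells, self.genes[idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


@dataclass
class GeneSetCollection:
    """Ordered named gene sets (GMT dialect)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add(self, name: str, genes: list[str], description: str = "") -> None:
        seen: set[str] = set()
        unique = [g for g in genes if not (g in seen or seen.add(g))]
        if len(unique) < len(genes):
            logger.warning(
                "gene set %r: dropped %d duplicate genes", name, len(genes) - len(unique)
            )
        if not unique:
            raise ValueError(f"gene set {name!r} is empty")
        self.sets[name] = unique
        self.descriptions[name] = description


# ---------------------------------------------------------------------------
# Matrix Market round trip
# ---------------------------------------------------------------------------


def read_counts_mtx(path, genes_path=None, cells_path=None, genes_as_rows: bool = True) -> CountMatrix:
    """Read an MTX count matrix plus sidecar label files.

    Parameters
    ----------
    path
        The ``.mtx`` file. Sidecars default to ``genes.tsv`` and
        ``cells.tsv`` next to it.
    genes_as_rows
        On-disk orientation flag (10x convention). The returned matrix is
        always cells x genes.
    """
    path = Path(path)
    genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
    cells_path = Path(cells_path) if cells_path else path.parent / "cells.tsv"
    mat = scipy.io.mmread(path)
    data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: matrix contains non-integer values")
    mat = sp.csr_matrix(mat, dtype=np.int64)
    genes = pd.Index(pd.read_csv(genes_path, sep="\t", header=None)[0], name="gene")
    cells = pd.Index(pd.read_csv(cells_path, sep="\t", header=None)[0], name="cell")
    if genes_as_rows:
        mat = sp.csr_matrix(mat.T)
    n_cells, n_genes = mat.shape
    if n_genes != len(genes):
        raise ValueError(
            f"{path}: matrix has {n_genes} genes but {len(genes)} gene labels"
        )
    if n_cells != len(cells):
        raise ValueError(
            f"{path}: matrix has {n_cells} cells but {len(cells)} cell labels"
        )
    if (mat.data < 0).any():
        raise ValueError(f"{path}: negative counts")
    return CountMatrix(mat, cells, genes)


def write_counts_mtx(counts: CountMatrix, outdir, genes_as_rows: bool = True) -> Path:
    """Write counts as MTX (genes x cells on disk) with label sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = counts.matrix.T if genes_as_rows else counts.matrix
    mtx_path = outdir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(mat), field="integer")
    counts.genes.to_series().to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    counts.cells.to_series().to_csv(outdir / "cells.tsv", sep="\t", header=False, index=False)
    return mtx_path


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name description gene1 gene2 ...``."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            coll.add(fields[0], fields[2:], description=fields[1])
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="cell")
    return table


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index_label="cell")
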