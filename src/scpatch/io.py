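"""Expression-matrix I/O, per-cell log-normalisation, gene alignment, splits.

Conventions
-----------
* CSV/TSV: cells in rows, genes in columns; header row holds gene ids and the
  first column holds cell barcodes.
* Matrix Market (.mtx): genes x cells on disk (the common 10x layout) with
  ``genes.tsv`` / ``barcodes.tsv`` sidecars, transposed to cells x genes on read.
* Labels: two-column CSV ``cell_id,cell_type``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with ids and optional labels.

    ``values`` holds raw counts when ``normalized`` is False, log-normalised
    expression otherwise. Rows follow ``cell_ids``, columns ``gene_ids``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene id")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell id")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("raw counts must be non-negative")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.cell_ids):
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class LabelMap:
    """Bijection between K cell-type names and contiguous class indices."""

    names: list[str]
    index_of: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.names = list(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate class names")
        self.index_of = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def from_labels(cls, labels) -> "LabelMap":
        """Build a map from observed labels, ordered by first appearance."""
        return cls(list(dict.fromkeys(labels)))

    def __len__(self) -> int:
        return len(self.names)

    def encode(self, labels) -> np.ndarray:
        unknown = sorted(set(labels) - set(self.names))
        if unknown:
            raise ValueError(f"labels outside map: {unknown}")
        return np.array([self.index_of[l] for l in labels], dtype=np.int64)

    def decode(self, indices) -> list[str]:
        return [self.names[int(i)] for i in indices]


# ----------------------------------------------------------------- readers
def read_matrix(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from dense CSV/TSV or Matrix Market + sidecars.

    ``fmt`` is inferred from the suffix when omitted (``.mtx`` vs anything
    else). Returns raw counts (``normalized=False``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        for f in (genes_file, barcodes_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file: {f}")
        mat = spio.mmread(path)
        genes = genes_file.read_text().splitlines()
        # tolerate 10x-style multi-column gene files; first column is the id
        genes = [g.split("\t")[0] for g in genes if g]
        barcodes = [b for b in barcodes_file.read_text().splitlines() if b]
        if mat.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(genes)} genes "
                f"x {len(barcodes)} barcodes"
            )
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat).T
        return ExpressionMatrix(values, genes, barcodes)
    if fmt == "csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        with open(path) as fh:  # pandas mangles duplicate headers; check raw
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene id")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.duplicated().any():
            raise ValueError("duplicate cell id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric entries in expression matrix")
        return ExpressionMatrix(values, [str(g) for g in df.columns],
                                [str(c) for c in df.index])
    raise ValueError(f"unknown format: {fmt}")


def write_matrix(m: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Inverse of :func:`read_matrix` for both supported formats."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path), sparse.coo_matrix(m.values.T))
        (path.parent / "genes.tsv").write_text("\n".join(m.gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    elif fmt == "csv":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(
            path, sep=sep)
    else:
        raise ValueError(f"unknown format: {fmt}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column ``cell_id,cell_type`` CSV into a dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id,cell_type")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_labels(m: ExpressionMatrix, path) -> None:
    if m.labels is None:
        raise ValueError("matrix has no labels")
    pd.DataFrame({"cell_id": m.cell_ids, "cell_type": m.labels}).to_csv(
        path, index=False)


def attach_labels(m: ExpressionMatrix, label_of: dict[str, str]) -> ExpressionMatrix:
    missing = [c for c in m.cell_ids if c not in label_of]
    if missing:
        raise ValueError(f"{len(missing)} cells without labels, e.g. {missing[:3]}")
    return replace(m, labels=[label_of[c] for c in m.cell_ids])


# ------------------------------------------------------------ preprocessing
def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Per-cell normalisation: ln(1 + scale_factor * count / cell_total).

    Each cell's counts are divided by its total, scaled, and log1p-transformed,
    so ``sum_g expm1(value)`` recovers ``scale_factor`` exactly per cell.
    Zeros stay zeros. Cells with total count 0 are rejected rather than
    allowed to produce NaN.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total count: {names}")
    values = np.log1p(scale_factor * m.values / totals[:, None])
    return replace(m, values=values, normalized=True)


def align_genes(query: ExpressionMatrix, reference_genes) -> ExpressionMatrix:
    """Reorder query columns to a reference gene list.

    Query genes absent from the reference are dropped; reference genes absent
    from the query are zero-filled. Matching is exact string equality.
    """
    reference_genes = list(reference_genes)
    if len(set(reference_genes)) != len(reference_genes):
        raise ValueError("reference gene list contains duplicates")
    pos = {g: j for j, g in enumerate(query.gene_ids)}
    matched = [g for g in reference_genes if g in pos]
    if not matched:
        raise ValueError("no overlap between query and reference genes")
    out = np.zeros((query.n_cells, len(reference_genes)), dtype=np.float64)
    for j, g in enumerate(reference_genes):
        if g in pos:
            out[:, j] = query.values[:, pos[g]]
    n_dropped = query.n_genes - len(matched)
    n_filled = len(reference_genes) - len(matched)
    logger.info("align_genes: %d matched, %d dropped, %d zero-filled",
                len(matched), n_dropped, n_filled)
    return replace(query, values=out, gene_ids=reference_genes)


def split_train_test(
    m: ExpressionMatrix, train_fraction: float = 0.8, seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Uniform random row split into floor(f*C) train cells and the rest."""
    if m.labels is None:
        raise ValueError("split requires labels")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_cells)
    n_train = int(np.floor(train_fraction * m.n_cells))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train, test = m.subset_cells(train_idx), m.subset_cells(test_idx)
    for name, part in (("train", train), ("test", test)):
        counts = pd.Series(part.labels).value_counts()
        for lbl in set(m.labels) - set(counts.index):
            warnings.warn(f"label '{lbl}' has no cells in the {name} partition")
    return train, test
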