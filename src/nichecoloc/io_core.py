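"""Reading, validation, QC filtering and normalization of sparse count matrices.

Counts are held genes x observations (cells or spots) as ``scipy.sparse``
arrays, mirroring the 10x Matrix Market convention (matrix rows = features,
columns = barcodes). Two layers exist: ``raw`` integer counts and the
``log1p_cp10k`` layer, ln(1 + 10,000 * count / cell_total), the log-normalized
counts-per-10k transform used for all expression comparisons downstream.

QC follows the droplet-data conventions of the gastric-cancer atlas this
package targets: cells are retained with total UMI in [501, 7000] and
mitochondrial fraction <= 20%; genes detected in fewer than 3 retained cells
are dropped. The gene filter runs after the cell filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("nichecoloc")

RAW = "raw"
LOG1P_CP10K = "log1p_cp10k"

__all__ = [
    "ExpressionMatrix",
    "QCReport",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_cell_meta",
    "qc_filter",
    "normalize_cp10k_log1p",
]


class FormatError(ValueError):
    """An input file does not match the expected on-disk format."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Sparse gene x observation count matrix with identifier sidecars.

    Parameters
    ----------
    genes
        Ordered, unique gene symbols (length = number of matrix rows).
    barcodes
        Ordered, unique observation identifiers (matrix columns).
    counts
        ``scipy.sparse`` matrix, genes x observations. Nonnegative integers
        for the ``raw`` layer, nonnegative finite reals for ``log1p_cp10k``.
    layer_tag
        Either ``"raw"`` or ``"log1p_cp10k"``.
    """

    genes: np.ndarray
    barcodes: np.ndarray
    counts: sp.csr_array
    layer_tag: str = RAW

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=object)
        barcodes = np.asarray(self.barcodes, dtype=object)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "barcodes", barcodes)
        counts = self.counts
        if not sp.issparse(counts):
            counts = sp.csr_array(np.asarray(counts))
        counts = sp.csr_array(counts)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes")
        data = counts.data
        if self.layer_tag == RAW:
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValueError("raw layer must contain nonnegative integers")
        elif self.layer_tag == LOG1P_CP10K:
            if data.size and (not np.all(np.isfinite(data)) or np.any(data < 0)):
                raise ValueError("normalized layer must be finite and >= 0")
        else:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_obs(self) -> int:
        return len(self.barcodes)

    def obs_totals(self) -> np.ndarray:
        """Total counts per observation (UMI totals on the raw layer)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_indexer(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def gene_values(self, gene: str) -> np.ndarray:
        """Dense per-observation vector for one gene."""
        idx = self.gene_indexer()
        if gene not in idx:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self.counts[[idx[gene]], :].toarray().ravel()

    def subset(self, gene_mask=None, obs_mask=None) -> "ExpressionMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        om = np.ones(self.n_obs, bool) if obs_mask is None else np.asarray(obs_mask)
        counts = sp.csr_array(sp.csc_array(self.counts[gm, :])[:, om])
        return ExpressionMatrix(self.genes[gm], self.barcodes[om], counts, self.layer_tag)


@dataclass
class QCReport:
    """Per-rule accounting of what a ``qc_filter`` pass removed.

    A cell can fail several rules at once, so per-rule removals may sum to
    more than the net number of cells dropped.
    """

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_low_umi: int = 0
    removed_high_umi: int = 0
    removed_high_mito: int = 0
    removed_excluded_barcode: int = 0
    removed_rare_genes: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells_out > self.n_cells_in or self.n_genes_out > self.n_genes_in:
            raise ValueError("QC cannot add cells or genes")
        per_rule = (
            self.removed_low_umi
            + self.removed_high_umi
            + self.removed_high_mito
            + self.removed_excluded_barcode
        )
        if per_rule < self.n_cells_in - self.n_cells_out:
            raise ValueError("per-rule removals below net cell loss")

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "removed_low_umi": self.removed_low_umi,
            "removed_high_umi": self.removed_high_umi,
            "removed_high_mito": self.removed_high_mito,
            "removed_excluded_barcode": self.removed_excluded_barcode,
            "removed_rare_genes": self.removed_rare_genes,
            "params": self.params,
        }


def _read_identifier_file(path: str | Path, symbol_column: bool = False) -> np.ndarray:
    """One identifier per line; 10x feature files may carry extra columns.

    With ``symbol_column`` the gene symbol is taken from column 2 when the
    file has >= 2 tab-separated columns, else column 1.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if symbol_column and df.shape[1] >= 2:
        col = df.iloc[:, 1]
    else:
        col = df.iloc[:, 0]
    return col.to_numpy(dtype=object)


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a Matrix Market counts matrix with gene/barcode sidecar files.

    Raises
    ------
    FormatError
        If the matrix dimensions do not match the sidecar lengths; the message
        names the offending file.
    ValueError
        On duplicate identifiers.
    """
    mat = sp.csr_array(mmread(matrix_path))
    genes = _read_identifier_file(genes_path, symbol_column=True)
    barcodes = _read_identifier_file(barcodes_path)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{genes_path}: {len(genes)} identifiers but matrix has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} identifiers but matrix has "
            f"{mat.shape[1]} columns"
        )
    return ExpressionMatrix(genes, barcodes, mat, layer_tag=RAW)


def write_counts(em: ExpressionMatrix, out_dir: str | Path, prefix: str = "matrix") -> dict:
    """Write matrix.mtx + genes.tsv + barcodes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    field_kind = "integer" if em.layer_tag == RAW else "real"
    mmwrite(paths["matrix"], sp.coo_matrix(em.counts), field=field_kind)
    pd.Series(em.genes).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(em.barcodes).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return paths


def read_cell_meta(path: str | Path, em: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read a cell metadata TSV (columns: barcode, cluster, tissue, sample).

    When ``em`` is given, every barcode must be present in the matrix.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "cluster", "tissue", "sample"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if meta["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cell metadata")
    for col in ("cluster", "tissue"):
        if meta[col].isna().any() or (meta[col].str.len() == 0).any():
            raise ValueError(f"empty {col} labels in cell metadata")
    if em is not None:
        unknown = set(meta["barcode"]) - set(em.barcodes)
        if unknown:
            raise ValueError(
                f"{len(unknown)} metadata barcodes absent from matrix "
                f"(e.g. {sorted(unknown)[:3]})"
            )
    return meta


def qc_filter(
    em: ExpressionMatrix,
    min_umi: int = 501,
    max_umi: int = 7000,
    max_mito_pct: float = 20.0,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
    exclude_barcodes=None,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply droplet QC: UMI window, mitochondrial cap, then rare-gene filter.

    Cells are retained when total UMI lies in ``[min_umi, max_umi]`` and the
    percentage of counts on ``mito_prefix`` genes is <= ``max_mito_pct``.
    Genes are then retained when detected (count > 0) in at least
    ``min_cells_per_gene`` surviving cells. ``exclude_barcodes`` accepts an
    externally derived drop list (e.g. doublet calls).

    Removing every cell is reported with a warning, not an exception.
    """
    if em.layer_tag != RAW:
        raise ValueError("qc_filter requires the raw layer")
    totals = em.obs_totals()
    mito_genes = np.array([str(g).startswith(mito_prefix) for g in em.genes])
    if mito_genes.any():
        mito_totals = np.asarray(em.counts[mito_genes, :].sum(axis=0)).ravel()
    else:
        mito_totals = np.zeros(em.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_totals / totals, 0.0)

    low = totals < min_umi
    high = totals > max_umi
    mito_fail = mito_pct > max_mito_pct
    excluded = np.zeros(em.n_obs, bool)
    if exclude_barcodes is not None:
        drop = set(exclude_barcodes)
        excluded = np.array([b in drop for b in em.barcodes])
    keep_cells = ~(low | high | mito_fail | excluded)

    if not keep_cells.any():
        logger.warning("qc_filter removed every cell")

    cell_sub = em.subset(obs_mask=keep_cells)
    detected = np.asarray((cell_sub.counts > 0).sum(axis=1)).ravel()
    keep_genes = detected >= min_cells_per_gene
    out = cell_sub.subset(gene_mask=keep_genes)

    report = QCReport(
        n_cells_in=em.n_obs,
        n_cells_out=out.n_obs,
        n_genes_in=em.n_genes,
        n_genes_out=out.n_genes,
        removed_low_umi=int(low.sum()),
        removed_high_umi=int(high.sum()),
        removed_high_mito=int(mito_fail.sum()),
        removed_excluded_barcode=int(excluded.sum()),
        removed_rare_genes=int((~keep_genes).sum()),
        params={
            "min_umi": min_umi,
            "max_umi": max_umi,
            "max_mito_pct": max_mito_pct,
            "min_cells_per_gene": min_cells_per_gene,
            "mito_prefix": mito_prefix,
        },
    )
    return out, report


def normalize_cp10k_log1p(em: ExpressionMatrix) -> ExpressionMatrix:
    """Log-normalize raw counts: value = ln(1 + 10,000 * count / cell_total).

    Zero counts map to zero so sparsity is preserved. Cells with zero total
    get all-zero values and are flagged in the log.
    """
    if em.layer_tag != RAW:
        raise ValueError("normalize_cp10k_log1p requires the raw layer")
    totals = em.obs_totals()
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d observation(s) with zero total; normalized to all-zero", n_zero)
    scale = np.where(totals > 0, 1e4 / np.where(totals > 0, totals, 1.0), 0.0)
    # column-wise scaling, then elementwise log1p on the sparse data
    scaled = sp.csr_array(em.counts.astype(float).multiply(scale[np.newaxis, :]))
    scaled.data = np.log1p(scaled.data)
    return ExpressionMatrix(em.genes, em.barcodes, scaled, layer_tag=LOG1P_CP10K)


def ensure_normalized(em: ExpressionMatrix) -> ExpressionMatrix:
    """Return a log1p_cp10k layer, normalizing on the fly if given raw counts."""
    return em if em.layer_tag == LOG1P_CP10K else normalize_cp10k_log1p(em)
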