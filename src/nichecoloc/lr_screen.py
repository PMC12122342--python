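"""Ligand-receptor pair screening and Wilcoxon differential expression.

The screening step follows the iTALK-style recipe: for each cell type, take
the top 50% most highly expressed genes (by mean log-normalized expression,
among genes with nonzero mean), then count database ligand-receptor records
whose ligand falls in the sender's top set and receptor in the receiver's —
direction-sensitive, totalled and per category (cytokine, growth factor,
immune checkpoint, other).

Differential expression between two cell groups uses the two-sided Wilcoxon
rank-sum test per gene on normalized values with Benjamini-Hochberg FDR
control; genes at adjusted p < 0.01 and |log2FC| > 1 are labelled up/down.
Concordance between single-cell and bulk fold changes is the Spearman rank
correlation over the top-1000 genes by absolute single-cell log2FC.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import LOG1P_CP10K, ExpressionMatrix
from .spatial import wilcoxon_rank_sum

logger = logging.getLogger("nichecoloc")

CATEGORIES = ("cytokine", "growth factor", "immune checkpoint", "other")

__all__ = [
    "load_lr_database",
    "top_expressed_genes",
    "count_lr_pairs",
    "rank_sum_deg",
    "logfc_concordance",
]


def load_lr_database(path: str | Path | None = None) -> pd.DataFrame:
    """Load a ligand-receptor database TSV (ligand, receptor, category).

    The packaged default is a small curated table around the CXCL16-CXCR6
    axis and the type-17 interleukins (IL17A/IL17F-IL17RA, IL26-IL20RA/IL10RB,
    IL22-IL22RA1, IL16-CD4) plus assorted controls; real screens should
    supply a full database in the same format.
    """
    if path is None:
        ref = resources.files("nichecoloc.data") / "lr_pairs_core.tsv"
        with resources.as_file(ref) as p:
            db = pd.read_csv(p, sep="\t")
    else:
        db = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor", "category"}
    if not required <= set(db.columns):
        raise ValueError(f"LR database needs columns {sorted(required)}")
    if db.duplicated(subset=["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) pairs in database")
    unknown = set(db["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown LR categories: {sorted(unknown)}")
    return db


def top_expressed_genes(
    em: ExpressionMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    fraction: float = 0.5,
) -> list[str]:
    """Top-``fraction`` most highly expressed genes of one cell type.

    Genes are ranked by mean normalized expression over the type's cells;
    only genes with nonzero mean enter the denominator, and the top
    ``ceil(fraction * n_nonzero)`` are returned. Ties at the cut keep the
    lexicographically smaller symbol.
    """
    if em.layer_tag != LOG1P_CP10K:
        raise ValueError("top_expressed_genes requires the log1p_cp10k layer")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    cells = meta.loc[meta["cluster"] == cell_type, "barcode"]
    if cells.empty:
        raise ValueError(f"unknown cell type {cell_type!r}")
    pos = pd.Index(em.barcodes).get_indexer(cells)
    if (pos < 0).any():
        raise ValueError("metadata barcodes missing from matrix")
    sub = em.subset(obs_mask=np.isin(np.arange(em.n_obs), pos))
    means = np.asarray(sub.counts.mean(axis=1)).ravel()
    nonzero = means > 0
    n_keep = int(np.ceil(fraction * nonzero.sum()))
    ranked = sorted(
        zip(em.genes[nonzero], means[nonzero]), key=lambda gv: (-gv[1], gv[0])
    )
    return [g for g, _ in ranked[:n_keep]]


def count_lr_pairs(
    sender_genes, receiver_genes, database: pd.DataFrame
) -> dict[str, int]:
    """Count database records with ligand in sender and receptor in receiver.

    Direction-sensitive (sender -> receiver). Returns per-category counts
    plus ``"total"``. An empty database yields zero counts with a warning.
    """
    if database.empty:
        logger.warning("empty LR database; all counts zero")
    senders, receivers = set(sender_genes), set(receiver_genes)
    hit = database["ligand"].isin(senders) & database["receptor"].isin(receivers)
    counts = {cat: 0 for cat in CATEGORIES}
    for cat, n in database.loc[hit, "category"].value_counts().items():
        counts[cat] = int(n)
    counts["total"] = int(hit.sum())
    return counts


def rank_sum_deg(
    em: ExpressionMatrix,
    group_a_barcodes,
    group_b_barcodes,
    p_adj_cut: float = 0.01,
    lfc_cut: float = 1.0,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE with BH correction and direction labels.

    The test runs on the log-normalized values; log2FC = log2((mean_a + eps)
    / (mean_b + eps)) with the means taken on the de-logged counts-per-10k
    scale (expm1 of the log layer), so a k-fold change in expression reports
    a log2FC near log2(k). ``up`` requires adjusted p < ``p_adj_cut`` and
    log2FC > ``lfc_cut``; ``down`` is symmetric; everything else is ``ns``.
    """
    if em.layer_tag != LOG1P_CP10K:
        raise ValueError("rank_sum_deg requires the log1p_cp10k layer")
    a_set, b_set = list(group_a_barcodes), list(group_b_barcodes)
    shared = sorted(set(a_set) & set(b_set))
    if shared:
        raise ValueError(f"groups overlap on barcodes: {shared[:5]}")
    if len(a_set) < 3 or len(b_set) < 3:
        raise ValueError("each group needs >= 3 cells")
    order = pd.Index(em.barcodes)
    ia = order.get_indexer(a_set)
    ib = order.get_indexer(b_set)
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("group barcodes missing from matrix")
    X = em.counts.toarray()
    A, B = X[:, ia], X[:, ib]

    pvals = np.empty(em.n_genes)
    for g in range(em.n_genes):
        if np.array_equal(np.sort(A[g]), np.sort(B[g])) or len(
            np.unique(np.concatenate([A[g], B[g]]))
        ) == 1:
            pvals[g] = 1.0
        else:
            _, pvals[g] = wilcoxon_rank_sum(A[g], B[g])
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = np.log2(
        (np.expm1(A).mean(axis=1) + eps) / (np.expm1(B).mean(axis=1) + eps)
    )
    direction = np.where(
        (padj < p_adj_cut) & (lfc > lfc_cut),
        "up",
        np.where((padj < p_adj_cut) & (lfc < -lfc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": em.genes,
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "direction": direction,
        }
    ).set_index("gene")


def logfc_concordance(
    deg_sc: pd.DataFrame, deg_bulk: pd.DataFrame, top_n: int = 1000
) -> tuple[float, float]:
    """Spearman correlation of single-cell vs bulk log2 fold changes.

    Selects the ``top_n`` genes by absolute single-cell log2FC among genes
    present in both tables, then correlates the two log2FC vectors. Both
    inputs are DataFrames indexed by gene with a ``log2fc`` column. Requires
    >= 10 shared genes.
    """
    shared = deg_sc.index.intersection(deg_bulk.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    sc_lfc = deg_sc.loc[shared, "log2fc"]
    chosen = sc_lfc.abs().sort_values(ascending=False).index[:top_n]
    rho, p = stats.spearmanr(
        deg_sc.loc[chosen, "log2fc"], deg_bulk.loc[chosen, "log2fc"]
    )
    return float(rho), float(p)
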