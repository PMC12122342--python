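"""Binned-control gene-signature scoring.

The score of a gene set in one cell is the mean normalized expression of the
set's genes minus the mean of expression-matched control genes: genes are
ranked by their dataset-wide mean expression, cut into ``n_bins``
equal-frequency bins, and ``n_ctrl`` controls are sampled per set gene from
that gene's bin. Subtracting bin-matched controls removes the coupling
between signature score and cell complexity that a plain mean would carry.

The tumor-minus-normal differential score — score(tumor markers) minus
score(normal markers) under a shared control seed — nominates malignant
cells among epithelial ones.

Ties in mean expression are broken by gene symbol so that binning, and hence
the whole score, is reproducible for a fixed seed. Controls are sampled
without replacement when the bin is large enough, with replacement
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_core import LOG1P_CP10K, ExpressionMatrix

logger = logging.getLogger("nichecoloc")

__all__ = [
    "GeneSet",
    "ScoreVector",
    "module_score",
    "differential_signature_score",
    "read_gene_sets",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ScoreVector:
    """Per-barcode signature scores plus the parameters that produced them."""

    scores: pd.Series
    gene_set: str
    n_bins: int
    n_ctrl: int
    seed: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(float))):
            raise ValueError("scores must be finite")


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from two-column TSV (set_name, gene) or YAML mapping."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        return {name: GeneSet(name, tuple(genes)) for name, genes in raw.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"], dtype=str)
    return {
        name: GeneSet(name, tuple(sub["gene"]))
        for name, sub in df.groupby("set_name", sort=True)
    }


def _dense_mean_rows(em: ExpressionMatrix, rows: np.ndarray) -> np.ndarray:
    """Mean over the given gene rows (with multiplicity), per observation."""
    return np.asarray(em.counts[rows, :].mean(axis=0)).ravel()


def _expression_bins(em: ExpressionMatrix, n_bins: int) -> tuple[np.ndarray, list]:
    """Assign every gene to an equal-frequency bin of dataset-mean expression.

    Returns (bin_id per gene index, list of index arrays per bin). Genes are
    ordered by (mean, symbol); if there are fewer distinct means than bins the
    bin count is reduced with a warning.
    """
    means = np.asarray(em.counts.mean(axis=1)).ravel()
    n_distinct = len(np.unique(means))
    n_eff = min(n_bins, n_distinct)
    if n_eff < n_bins:
        logger.warning(
            "reducing control bins from %d to %d (distinct mean-expression values)",
            n_bins,
            n_eff,
        )
    order = np.lexsort((em.genes.astype(str), means))
    chunks = np.array_split(order, n_eff)
    bin_id = np.empty(em.n_genes, dtype=int)
    for b, chunk in enumerate(chunks):
        bin_id[chunk] = b
    return bin_id, [np.sort(c) for c in chunks]


def module_score(
    em: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Score a gene set per cell against expression-matched controls.

    Requires the ``log1p_cp10k`` layer. Genes of the set missing from the
    matrix are dropped with a warning; an empty intersection is an error.
    """
    if em.layer_tag != LOG1P_CP10K:
        raise ValueError("module_score requires the log1p_cp10k layer")
    idx = em.gene_indexer()
    present = [g for g in gene_set.genes if g in idx]
    missing = [g for g in gene_set.genes if g not in idx]
    if missing:
        logger.warning(
            "gene set %r: %d gene(s) not in matrix: %s",
            gene_set.name,
            len(missing),
            ",".join(missing[:5]),
        )
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")

    bin_id, bins = _expression_bins(em, n_bins)
    rng = np.random.default_rng(seed)
    ctrl_rows = []
    for g in sorted(present):
        bin_members = bins[bin_id[idx[g]]]
        if len(bin_members) >= n_ctrl:
            picked = rng.choice(bin_members, size=n_ctrl, replace=False)
        else:
            picked = rng.choice(bin_members, size=n_ctrl, replace=True)
        ctrl_rows.append(picked)
    ctrl_rows = np.concatenate(ctrl_rows)

    set_rows = np.array([idx[g] for g in present])
    scores = _dense_mean_rows(em, set_rows) - _dense_mean_rows(em, ctrl_rows)
    return ScoreVector(
        scores=pd.Series(scores, index=em.barcodes, name=gene_set.name),
        gene_set=gene_set.name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        extras={"n_genes_used": len(present), "n_genes_missing": len(missing)},
    )


def differential_signature_score(
    em: ExpressionMatrix,
    tumor_panel: GeneSet,
    normal_panel: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Tumor-marker score minus normal-marker score, shared seed.

    Positive values nominate malignant-leaning cells. Overlapping genes
    between the two panels are legal but reduce contrast; they are warned
    about explicitly.
    """
    overlap = sorted(set(tumor_panel.genes) & set(normal_panel.genes))
    if overlap:
        logger.warning(
            "tumor and normal panels share %d gene(s): %s", len(overlap), ",".join(overlap)
        )
    s_tumor = module_score(em, tumor_panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s_normal = module_score(em, normal_panel, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    diff = s_tumor.scores - s_normal.scores
    diff.name = f"{tumor_panel.name}-minus-{normal_panel.name}"
    return ScoreVector(
        scores=diff,
        gene_set=diff.name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        extras={"overlap": overlap},
    )
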