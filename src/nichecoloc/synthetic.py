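"""Synthetic fixtures for every pipeline stage.

Three generators cover the statistical structures the analyses assume, so the
whole pipeline is testable without any sequencing download:

* ``simulate_composition`` — cluster x tissue cell-count tables drawn from an
  independence baseline with multiplicative distortions planted on chosen
  cells, for exercising Ro/e recovery;
* ``simulate_spatial`` — a staggered hexagonal spot lattice (Visium-style
  array coordinates) with negative-binomial marker counts, a tunable
  tumor–Tc17 co-occurrence boost ``beta`` (log-odds added to Tc17 membership
  in tumor spots) and a tunable CXCL16→CXCR6 coupling ``delta`` (added to the
  CXCR6 NB mean in Tc17 spots whose neighborhood holds a CXCL16+ tumor spot);
  ``beta = delta = 0`` is the null;
* ``simulate_paired_bulk`` — per-group pseudobulk profiles with lognormal
  replicate noise, for fold-change concordance checks.

All generators are pure functions of (configuration, seed). The negative
binomial (mean/dispersion parameterization) is the noise model throughout —
the de facto distribution for UMI counts. A note on ``simulate_composition``:
planting a multiplicative fold f on one cell of the joint does NOT make its
Ro/e equal f, because the fold leaks into the row and column marginals; the
returned truth therefore carries the exact Ro/e implied by the distorted
joint, which recovery tests should target. The leakage is small when the
planted cell's baseline marginal mass is small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .composition import CompositionTable
from .io_core import RAW, ExpressionMatrix, write_counts
from .spatial import RING1, SAME_SPOT, SpotGeometry

TUMOR_MARKERS = ("KRT17", "PRAME", "GNGT1", "GJB5", "PI3")
TC17_MARKERS = ("CD8A", "CD8B", "IL17A", "RORC")
LIGAND = "CXCL16"
RECEPTOR = "CXCR6"

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_composition",
    "simulate_spatial",
    "simulate_paired_bulk",
    "simulate_two_group_counts",
    "bulk_logfc_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the spatial simulator.

    Defaults give a 40 x 50 lattice (2,000 spots), tumor prior 0.30, Tc17
    prior 0.15, marker counts NB(mu=4, theta=2), off-type background
    NB(mu=0.01), and 60 filler genes NB(mu=30, theta=10) so that spot totals
    sit comfortably inside the [501, 7000] UMI QC window.
    """

    rows: int = 40
    cols: int = 50
    tumor_prior: float = 0.30
    tc17_prior: float = 0.15
    beta: float = 0.0
    delta: float = 0.0
    marker_mu: float = 4.0
    marker_theta: float = 2.0
    background_mu: float = 0.01
    background_theta: float = 1.0
    ligand_mu: float = 3.0
    receptor_mu: float = 2.0
    n_filler: int = 60
    filler_mu: float = 30.0
    filler_theta: float = 10.0
    neighborhood: str = SAME_SPOT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid too small: need at least 2 x 2 spots")
        for name in ("marker_mu", "marker_theta", "background_mu", "background_theta",
                     "ligand_mu", "receptor_mu", "filler_mu", "filler_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tumor_prior", "tc17_prior"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not (np.isfinite(self.beta) and np.isfinite(self.delta)):
            raise ValueError("beta and delta must be finite")
        if self.neighborhood not in (SAME_SPOT, RING1):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")


@dataclass
class SimTruth:
    """Ground truth recorded by a generator run."""

    tumor_mask: np.ndarray | None = None
    tc17_mask: np.ndarray | None = None
    coupled_mask: np.ndarray | None = None
    beta: float = 0.0
    delta: float = 0.0
    planted_folds: dict = field(default_factory=dict)
    analytic_roe: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        d = {"beta": self.beta, "delta": self.delta}
        for name in ("tumor_mask", "tc17_mask", "coupled_mask"):
            arr = getattr(self, name)
            if arr is not None:
                d[name] = np.asarray(arr).astype(int).tolist()
        if self.planted_folds:
            d["planted_folds"] = {f"{c}|{t}": f for (c, t), f in self.planted_folds.items()}
        return d


def _nb(rng: np.random.Generator, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Negative binomial draws in (mean, dispersion) parameterization."""
    mu = np.asarray(mu, float)
    theta = np.broadcast_to(np.asarray(theta, float), mu.shape)
    return rng.negative_binomial(theta, theta / (theta + mu))


def simulate_composition(
    clusters,
    tissues,
    n_cells: int,
    planted: dict | None = None,
    seed: int = 0,
    cluster_probs=None,
    tissue_probs=None,
) -> tuple[CompositionTable, SimTruth]:
    """Draw a cluster x tissue count table with planted enrichment.

    The baseline joint is the product of cluster and tissue probabilities
    (uniform unless given); ``planted`` maps (cluster, tissue) to a
    multiplicative fold > 0 applied before renormalization. ``n_cells`` cells
    are then drawn multinomially. The returned truth records both the planted
    folds and the exact Ro/e of the distorted joint.
    """
    clusters, tissues = list(clusters), list(tissues)
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    if len(tissues) < 1 or len(clusters) < 1:
        raise ValueError("need at least one cluster and one tissue")
    pc = (
        np.full(len(clusters), 1 / len(clusters))
        if cluster_probs is None
        else np.asarray(cluster_probs, float)
    )
    pt = (
        np.full(len(tissues), 1 / len(tissues))
        if tissue_probs is None
        else np.asarray(tissue_probs, float)
    )
    if not (np.isclose(pc.sum(), 1) and np.isclose(pt.sum(), 1)):
        raise ValueError("cluster/tissue probabilities must sum to 1")
    joint = np.outer(pc, pt)
    planted = planted or {}
    for (c, t), fold in planted.items():
        if fold <= 0:
            raise ValueError(f"fold for ({c}, {t}) must be > 0")
        joint[clusters.index(c), tissues.index(t)] *= fold
    z = joint.sum()
    if not np.isfinite(z) or z <= 0:
        raise ValueError("planted folds make the joint unnormalizable")
    joint /= z

    row, col = joint.sum(axis=1), joint.sum(axis=0)
    analytic = pd.DataFrame(
        joint / np.outer(row, col), index=clusters, columns=tissues
    )

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, joint.ravel()).reshape(joint.shape)
    table = CompositionTable(
        pd.DataFrame(counts, index=pd.Index(clusters, name="cluster"),
                     columns=pd.Index(tissues, name="tissue"))
    )
    return table, SimTruth(planted_folds=dict(planted), analytic_roe=analytic)


def _grid_geometry(rows: int, cols: int) -> SpotGeometry:
    """Visium-convention staggered lattice: col parity matches row parity."""
    recs = []
    for r in range(rows):
        for j in range(cols):
            c = 2 * j + (r % 2)
            recs.append(
                {
                    "barcode": f"spot_{r:03d}_{j:03d}",
                    "in_tissue": 1,
                    "array_row": r,
                    "array_col": c,
                    "pxl_row": round(r * 86.6, 1),
                    "pxl_col": float(c * 50),
                }
            )
    return SpotGeometry(pd.DataFrame(recs).set_index("barcode"))


def simulate_spatial(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[ExpressionMatrix, SpotGeometry, SimTruth]:
    """Simulate a spot lattice with marker counts, co-occurrence and coupling.

    Tumor membership is Bernoulli(tumor_prior) per spot; Tc17 membership is
    Bernoulli(sigmoid(logit(tc17_prior) + beta * tumor)). Marker genes draw
    from NB(marker_mu, marker_theta) in member spots and NB(background_mu)
    elsewhere. CXCL16 behaves as a tumor-expressed ligand; CXCR6 is expressed
    in Tc17 spots and its NB mean gains ``delta`` in Tc17 spots whose
    neighborhood (per ``config.neighborhood``) contains a CXCL16+ tumor spot.
    With ``out_dir`` set, writes matrix.mtx + sidecars, positions.csv and
    truth.json.
    """
    rng = np.random.default_rng(config.seed)
    geom = _grid_geometry(config.rows, config.cols)
    n = len(geom.barcodes)

    tumor = rng.random(n) < config.tumor_prior
    logit0 = np.log(config.tc17_prior / (1 - config.tc17_prior))
    p_tc17 = 1 / (1 + np.exp(-(logit0 + config.beta * tumor)))
    tc17 = rng.random(n) < p_tc17

    genes = (
        list(TUMOR_MARKERS)
        + list(TC17_MARKERS)
        + [LIGAND, RECEPTOR]
        + [f"FILLER{i:03d}" for i in range(config.n_filler)]
    )
    mu = np.full((len(genes), n), config.background_mu)
    theta = np.full((len(genes), n), config.background_theta)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in TUMOR_MARKERS:
        mu[gidx[g], tumor] = config.marker_mu
        theta[gidx[g], tumor] = config.marker_theta
    for g in TC17_MARKERS:
        mu[gidx[g], tc17] = config.marker_mu
        theta[gidx[g], tc17] = config.marker_theta
    mu[gidx[LIGAND], tumor] = config.ligand_mu
    theta[gidx[LIGAND], tumor] = config.marker_theta

    # ligand counts first, so receptor coupling can condition on realized CXCL16+
    ligand_counts = _nb(rng, mu[gidx[LIGAND]], theta[gidx[LIGAND]])
    lig_pos_tumor = tumor & (ligand_counts >= 1)

    if config.neighborhood == SAME_SPOT:
        near_ligand = lig_pos_tumor
    else:
        pos_of = {b: i for i, b in enumerate(geom.barcodes)}
        nbrs = geom.hex_neighbors()
        near_ligand = lig_pos_tumor.copy()
        for b, i in pos_of.items():
            if not near_ligand[i]:
                near_ligand[i] = any(lig_pos_tumor[pos_of[x]] for x in nbrs[b])
    coupled = tc17 & near_ligand

    mu[gidx[RECEPTOR], tc17] = config.receptor_mu
    theta[gidx[RECEPTOR], tc17] = config.marker_theta
    mu[gidx[RECEPTOR], coupled] = config.receptor_mu + config.delta
    for i in range(config.n_filler):
        g = gidx[f"FILLER{i:03d}"]
        mu[g, :] = config.filler_mu
        theta[g, :] = config.filler_theta

    counts = _nb(rng, mu, theta)
    counts[gidx[LIGAND]] = ligand_counts
    em = ExpressionMatrix(
        np.array(genes, dtype=object),
        geom.barcodes,
        sp.csr_array(counts),
        layer_tag=RAW,
    )
    truth = SimTruth(
        tumor_mask=tumor,
        tc17_mask=tc17,
        coupled_mask=coupled,
        beta=config.beta,
        delta=config.delta,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(em, out)
        geom.positions.reset_index().to_csv(out / "positions.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth.to_json_dict()))
    return em, geom, truth


def simulate_paired_bulk(
    em: ExpressionMatrix,
    groups: dict,
    n_replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Pseudobulk profiles with lognormal replicate noise.

    ``groups`` maps group name -> iterable of barcodes. Each replicate of a
    group is the per-gene sum over its cells multiplied by exp(N(0,
    noise_sd)) drawn independently per gene and replicate; ``noise_sd = 0``
    returns the exact pseudobulk sums in every replicate.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    order = pd.Index(em.barcodes)
    out = {}
    for name, barcodes in groups.items():
        pos = order.get_indexer(list(barcodes))
        if (pos < 0).any():
            raise ValueError(f"group {name!r}: barcodes missing from matrix")
        sums = np.asarray(
            em.subset(obs_mask=np.isin(np.arange(em.n_obs), pos)).counts.sum(axis=1)
        ).ravel()
        for r in range(n_replicates):
            noise = (
                np.exp(rng.normal(0.0, noise_sd, size=sums.size))
                if noise_sd > 0
                else 1.0
            )
            out[f"{name}_rep{r + 1}"] = sums * noise
    return pd.DataFrame(out, index=pd.Index(em.genes, name="gene"))


def bulk_logfc_table(
    bulk: pd.DataFrame, group_a: str, group_b: str, eps: float = 1e-9
) -> pd.DataFrame:
    """log2FC table from a replicate bulk profile (columns ``{group}_rep*``)."""
    cols_a = [c for c in bulk.columns if c.startswith(f"{group_a}_rep")]
    cols_b = [c for c in bulk.columns if c.startswith(f"{group_b}_rep")]
    if not cols_a or not cols_b:
        raise ValueError("group replicate columns not found")
    lfc = np.log2((bulk[cols_a].mean(axis=1) + eps) / (bulk[cols_b].mean(axis=1) + eps))
    return pd.DataFrame({"log2fc": lfc})


def simulate_two_group_counts(
    n_genes: int = 500,
    n_cells_per_group: int = 60,
    base_mu: float = 20.0,
    lfc_sd: float = 1.5,
    theta: float = 5.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Two-group NB counts with per-gene fold changes, for concordance tests.

    Gene g has true log2FC ~ N(0, lfc_sd); group means are base_mu shifted
    symmetrically by half the fold. Returns (raw matrix, cell metadata with
    cluster = group, true log2FC per gene).
    """
    rng = np.random.default_rng(seed)
    true_lfc = rng.normal(0.0, lfc_sd, size=n_genes)
    mu_a = base_mu * 2 ** (true_lfc / 2)
    mu_b = base_mu * 2 ** (-true_lfc / 2)
    A = _nb(rng, np.tile(mu_a[:, None], (1, n_cells_per_group)), theta)
    B = _nb(rng, np.tile(mu_b[:, None], (1, n_cells_per_group)), theta)
    genes = np.array([f"G{i:04d}" for i in range(n_genes)], dtype=object)
    barcodes = np.array(
        [f"a_cell{i:03d}" for i in range(n_cells_per_group)]
        + [f"b_cell{i:03d}" for i in range(n_cells_per_group)],
        dtype=object,
    )
    em = ExpressionMatrix(
        genes, barcodes, sp.csr_array(np.hstack([A, B])), layer_tag=RAW
    )
    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "cluster": ["groupA"] * n_cells_per_group + ["groupB"] * n_cells_per_group,
            "tissue": ["tumor"] * n_cells_per_group + ["normal"] * n_cells_per_group,
            "sample": ["sim"] * (2 * n_cells_per_group),
        }
    )
    return em, meta, pd.Series(true_lfc, index=genes, name="true_log2fc")
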