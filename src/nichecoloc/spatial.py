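"""Marker-based spot annotation and tumor–Tc17 colocalization statistics.

Works on array-based spatial transcriptomics (Visium-style): each barcoded
spot has an (array_row, array_col) position on a staggered hexagonal lattice
and a raw count vector. Spots are annotated per cell type by marker
colocalization — a spot is positive when every marker group contributes at
least one gene at or above a raw-count threshold (ANY within group, ALL
across groups). For the Tc17 panel that means a CD8 T-cell marker
(CD8A/CD8B) together with a type-17 marker (IL17A/RORC); tumor regions are
demarcated by gastric-cancer epithelial markers (KRT17/PRAME/GNGT1/GJB5/PI3).

Four statistics then quantify tumor–Tc17 proximity:

* same-spot (or ring-1) composition: the proportion of Tc17-positive spots
  among tumor spots vs non-tumor spots, Fisher exact on the 2x2 table;
* the qualifying-sample rule: a sample enters downstream comparisons only if
  the Tc17 proportion in tumor regions strictly exceeds 5%;
* nearest-distance: Euclidean distance from every spot to its nearest
  Tc17-positive spot, tumor vs non-tumor compared by Wilcoxon rank-sum;
* ligand-conditioned receptor expression: tumor spots split into CXCL16+ and
  CXCL16- by raw ligand count, and normalized CXCR6 expression of Tc17 spots
  in their neighborhood compared between the two sides.

Distances default to plain Euclidean on (array_row, array_col); pixel
coordinates are used when selected. All reported comparisons are invariant
to any common monotone scaling of coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.spatial import cKDTree

from .io_core import RAW, ExpressionMatrix, ensure_normalized

logger = logging.getLogger("nichecoloc")

SAME_SPOT = "same_spot"
RING1 = "ring1"

# Visium staggered lattice: array_col parity matches array_row parity, so the
# six hexagonal neighbours sit at these (row, col) offsets.
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))

__all__ = [
    "SpotGeometry",
    "MarkerPanel",
    "SpatialTestResult",
    "read_positions",
    "load_marker_panels",
    "call_positive_spots",
    "neighborhood_composition",
    "sample_qualifies",
    "nearest_distance_test",
    "ligand_conditioned_receptor",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class SpotGeometry:
    """Per-spot array coordinates, optional pixel coordinates, in-tissue flag."""

    positions: pd.DataFrame  # index=barcode; in_tissue, array_row, array_col[, pxl_row, pxl_col]

    def __post_init__(self) -> None:
        df = self.positions
        for col in ("in_tissue", "array_row", "array_col"):
            if col not in df.columns:
                raise ValueError(f"positions missing column {col!r}")
        if df.index.duplicated().any():
            raise ValueError("duplicate spot barcodes")
        if df.duplicated(subset=["array_row", "array_col"]).any():
            raise ValueError("duplicate (array_row, array_col) positions")

    @property
    def barcodes(self) -> np.ndarray:
        return self.positions.index.to_numpy(dtype=object)

    def coords(self, system: str = "array") -> np.ndarray:
        """N x 2 coordinate matrix in the declared system."""
        df = self.positions
        if system == "array":
            return df[["array_col", "array_row"]].to_numpy(float)
        if system == "pixel":
            if not {"pxl_col", "pxl_row"} <= set(df.columns):
                raise ValueError("pixel coordinates not available")
            pix = df[["pxl_col", "pxl_row"]]
            if pix.isna().any().any():
                raise ValueError("pixel coordinates contain missing values")
            return pix.to_numpy(float)
        raise ValueError(f"unknown coordinate system {system!r}")

    def hex_neighbors(self) -> dict[str, list[str]]:
        """Barcode -> barcodes of the up-to-6 hexagonally adjacent spots."""
        df = self.positions
        loc = {
            (int(r), int(c)): b
            for b, r, c in zip(df.index, df["array_row"], df["array_col"])
        }
        out: dict[str, list[str]] = {}
        for (r, c), b in loc.items():
            out[b] = [
                loc[(r + dr, c + dc)] for dr, dc in HEX_OFFSETS if (r + dr, c + dc) in loc
            ]
        return out


@dataclass(frozen=True)
class MarkerPanel:
    """Cell-type marker logic: ANY gene within each group, ALL groups."""

    cell_type: str
    groups: tuple  # tuple of tuples of gene symbols
    threshold: int = 1

    def __post_init__(self) -> None:
        groups = tuple(tuple(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if not groups or any(len(g) == 0 for g in groups):
            raise ValueError(f"panel {self.cell_type!r}: every group must be nonempty")
        if self.threshold < 1:
            raise ValueError("positivity threshold must be >= 1")

    @property
    def all_genes(self) -> list[str]:
        return [g for grp in self.groups for g in grp]


@dataclass
class SpatialTestResult:
    """Two-group comparison summary: sizes, summaries, statistic, p, direction."""

    test: str
    n_a: int
    n_b: int
    summary_a: float
    summary_b: float
    statistic: float
    pvalue: float
    direction: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0 <= self.pvalue <= 1:
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "summary_a": self.summary_a,
            "summary_b": self.summary_b,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "direction": self.direction,
        }
        d.update(self.extras)
        return d


_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_positions(path: str | Path) -> SpotGeometry:
    """Read a Visium tissue-positions CSV (header optional)."""
    first = Path(path).open().readline()
    has_header = first.lower().startswith("barcode")
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected >= 4 position columns")
    df.columns = _POSITION_COLUMNS[: df.shape[1]]
    df = df.set_index("barcode")
    for col in ("in_tissue", "array_row", "array_col"):
        df[col] = df[col].astype(int)
    return SpotGeometry(df)


def load_marker_panels(path: str | Path | None = None) -> dict[str, MarkerPanel]:
    """Load marker panels from YAML; default ships Tc17 + tumor panels."""
    if path is None:
        ref = resources.files("nichecoloc.data") / "marker_panels.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    panels = {}
    for name, spec in raw.items():
        panels[name] = MarkerPanel(
            cell_type=name,
            groups=tuple(tuple(g) for g in spec["groups"]),
            threshold=int(spec.get("threshold", 1)),
        )
    return panels


def call_positive_spots(
    em: ExpressionMatrix, panels: dict[str, MarkerPanel] | list[MarkerPanel]
) -> pd.DataFrame:
    """Annotate spots: one boolean column per panel, plus ``coloc`` when both
    ``tc17`` and ``tumor`` panels are present.

    Panel genes absent from the matrix are dropped with a warning and the
    group evaluated on the remainder; a panel with no genes present at all is
    an error.
    """
    if em.layer_tag != RAW:
        raise ValueError("spot annotation uses raw counts")
    if isinstance(panels, dict):
        panels = list(panels.values())
    idx = em.gene_indexer()
    labels = pd.DataFrame(index=pd.Index(em.barcodes, name="barcode"))
    for panel in panels:
        present_any = [g for g in panel.all_genes if g in idx]
        if not present_any:
            raise ValueError(f"no genes of panel {panel.cell_type!r} in matrix")
        missing = [g for g in panel.all_genes if g not in idx]
        if missing:
            logger.warning(
                "panel %r: missing gene(s) %s", panel.cell_type, ",".join(missing)
            )
        flag = np.ones(em.n_obs, dtype=bool)
        for group in panel.groups:
            rows = [idx[g] for g in group if g in idx]
            if not rows:
                flag[:] = False
                break
            group_hit = np.asarray(
                (em.counts[rows, :] >= panel.threshold).sum(axis=0)
            ).ravel() > 0
            flag &= group_hit
        labels[panel.cell_type] = flag
    if {"tc17", "tumor"} <= set(labels.columns):
        labels["coloc"] = labels["tc17"] & labels["tumor"]
    return labels


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    Uses the exact null when the smaller group has < 25 observations and the
    pooled sample is tie-free, otherwise the normal approximation with
    midranks, tie correction and continuity correction. The statistic is the
    rank sum W of the first group (midranks for ties).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) < 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum of a
    return w, float(res.pvalue)


def _proportion(num: int, den: int) -> float:
    return num / den if den > 0 else 0.0


def _direction(x: float, y: float) -> str:
    if np.isnan(x) or np.isnan(y) or x == y:
        return "none"
    return "a>b" if x > y else "a<b"


def neighborhood_composition(
    labels: pd.DataFrame,
    geometry: SpotGeometry | None = None,
    tc17: str = "tc17",
    tumor: str = "tumor",
    neighborhood: str = SAME_SPOT,
) -> SpatialTestResult:
    """Tc17 positivity in tumor regions vs elsewhere, Fisher exact.

    ``same_spot``: compares the proportion of Tc17-positive spots among
    tumor-positive spots with the proportion among tumor-negative spots.
    ``ring1``: group a = non-tumor spots hexagonally adjacent to a tumor
    spot, group b = non-tumor spots not adjacent to any tumor spot.

    The proportion among ALL spots (not only tumor/non-tumor split) is also
    reported in ``extras`` since either denominator is defensible.
    """
    t = labels[tumor].to_numpy(bool)
    s = labels[tc17].to_numpy(bool)
    if not t.any():
        raise ValueError("no tumor region")

    if neighborhood == SAME_SPOT:
        in_a = t
        in_b = ~t
    elif neighborhood == RING1:
        if geometry is None:
            raise ValueError("ring1 mode needs geometry")
        nbrs = geometry.hex_neighbors()
        order = {b: i for i, b in enumerate(labels.index)}
        near_tumor = np.zeros(len(labels), bool)
        for b, i in order.items():
            near_tumor[i] = any(t[order[n]] for n in nbrs.get(b, []) if n in order)
        in_a = ~t & near_tumor
        in_b = ~t & ~near_tumor
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")

    a_pos, a_n = int((in_a & s).sum()), int(in_a.sum())
    b_pos, b_n = int((in_b & s).sum()), int(in_b.sum())
    table = [[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]]
    if not s.any():
        logger.warning("no Tc17-positive spots anywhere; reporting p = 1")
        odds, p = np.nan, 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    prop_a, prop_b = _proportion(a_pos, a_n), _proportion(b_pos, b_n)
    return SpatialTestResult(
        test=f"neighborhood_composition[{neighborhood}]",
        n_a=a_n,
        n_b=b_n,
        summary_a=prop_a,
        summary_b=prop_b,
        statistic=float(odds) if np.isfinite(odds) else np.nan,
        pvalue=float(p),
        direction=_direction(prop_a, prop_b),
        extras={
            "table": table,
            "prop_tc17_all_spots": _proportion(int(s.sum()), len(labels)),
        },
    )


def sample_qualifies(
    labels: pd.DataFrame,
    min_prop: float = 0.05,
    tc17: str = "tc17",
    tumor: str = "tumor",
) -> tuple[bool, float, str]:
    """Strict 5%-rule sample filter.

    A sample qualifies when the proportion of Tc17-positive spots among
    tumor-positive spots strictly exceeds ``min_prop``. Returns
    (qualifies, proportion, reason).
    """
    t = labels[tumor].to_numpy(bool)
    s = labels[tc17].to_numpy(bool)
    if not t.any():
        return False, float("nan"), "no tumor region"
    prop = _proportion(int((t & s).sum()), int(t.sum()))
    ok = prop > min_prop
    return ok, prop, "" if ok else f"proportion {prop:.4f} <= {min_prop}"


def nearest_distance_test(
    labels: pd.DataFrame,
    geometry: SpotGeometry,
    coord_system: str = "array",
    tc17: str = "tc17",
    tumor: str = "tumor",
) -> SpatialTestResult:
    """Distance to the nearest Tc17-positive spot: tumor vs non-tumor spots.

    Every spot (including Tc17-positive ones, which contribute distance 0 to
    their own group) gets the Euclidean distance to the nearest Tc17 spot in
    the declared coordinate system; the two groups are compared with the
    two-sided Wilcoxon rank-sum test. Medians are reported as summaries.
    """
    aligned = labels.loc[geometry.barcodes]
    t = aligned[tumor].to_numpy(bool)
    s = aligned[tc17].to_numpy(bool)
    if not s.any():
        raise ValueError("no Tc17 spots")
    coords = geometry.coords(coord_system)
    tree = cKDTree(coords[s])
    dist, _ = tree.query(coords, k=1)
    d_tumor, d_other = dist[t], dist[~t]
    if d_tumor.size == 0 or d_other.size == 0:
        raise ValueError("need both tumor-positive and tumor-negative spots")
    stat, p = wilcoxon_rank_sum(d_tumor, d_other)
    med_a, med_b = float(np.median(d_tumor)), float(np.median(d_other))
    return SpatialTestResult(
        test=f"nearest_distance[{coord_system}]",
        n_a=int(t.sum()),
        n_b=int((~t).sum()),
        summary_a=med_a,
        summary_b=med_b,
        statistic=stat,
        pvalue=p,
        direction=_direction(med_a, med_b),
        extras={"mean_a": float(d_tumor.mean()), "mean_b": float(d_other.mean())},
    )


def ligand_conditioned_receptor(
    em_raw: ExpressionMatrix,
    labels: pd.DataFrame,
    geometry: SpotGeometry | None = None,
    ligand: str = "CXCL16",
    receptor: str = "CXCR6",
    neighborhood: str = SAME_SPOT,
    ligand_threshold: int = 1,
    em_norm: ExpressionMatrix | None = None,
    tc17: str = "tc17",
    tumor: str = "tumor",
) -> SpatialTestResult:
    """Receptor expression in Tc17 spots near ligand-positive vs -negative tumor.

    Tumor-positive spots are split into ligand+ / ligand- by raw ligand count
    >= ``ligand_threshold``. In ``same_spot`` mode the Tc17 spots considered
    are those that are themselves tumor-positive (the spot mixture contains
    both populations); in ``ring1`` mode a Tc17 spot joins the + group when
    any hex-adjacent (or own) tumor spot is ligand-positive, the - group when
    it neighbors only ligand-negative tumor spots, and is excluded otherwise.
    Normalized (log1p CP10K) receptor expression is compared by two-sided
    Wilcoxon rank-sum. An empty group yields p = NaN with an explicit reason.
    """
    if em_raw.layer_tag != RAW:
        raise ValueError("ligand split uses raw counts")
    idx = em_raw.gene_indexer()
    for g in (ligand, receptor):
        if g not in idx:
            raise ValueError(f"gene {g!r} not in matrix")
    norm = ensure_normalized(em_raw) if em_norm is None else em_norm

    order = pd.Index(em_raw.barcodes)
    lab = labels.loc[order]
    t = lab[tumor].to_numpy(bool)
    s = lab[tc17].to_numpy(bool)
    lig_pos = em_raw.gene_values(ligand) >= ligand_threshold
    rec_expr = norm.gene_values(receptor)

    if neighborhood == SAME_SPOT:
        in_plus = s & t & lig_pos
        in_minus = s & t & ~lig_pos
    elif neighborhood == RING1:
        if geometry is None:
            raise ValueError("ring1 mode needs geometry")
        nbrs = geometry.hex_neighbors()
        pos_of = {b: i for i, b in enumerate(order)}
        in_plus = np.zeros(len(order), bool)
        in_minus = np.zeros(len(order), bool)
        for b, i in pos_of.items():
            if not s[i]:
                continue
            hood = [i] + [pos_of[n] for n in nbrs.get(b, []) if n in pos_of]
            tumor_hood = [j for j in hood if t[j]]
            if not tumor_hood:
                continue
            if any(lig_pos[j] for j in tumor_hood):
                in_plus[i] = True
            else:
                in_minus[i] = True
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")

    x_plus, x_minus = rec_expr[in_plus], rec_expr[in_minus]
    extras = {
        "ligand": ligand,
        "receptor": receptor,
        "group_plus": f"{ligand}+",
        "group_minus": f"{ligand}-",
    }
    if x_plus.size == 0 or x_minus.size == 0:
        reason = f"empty {'+' if x_plus.size == 0 else '-'} group"
        logger.warning("ligand_conditioned_receptor: %s", reason)
        return SpatialTestResult(
            test=f"ligand_conditioned_receptor[{neighborhood}]",
            n_a=int(x_plus.size),
            n_b=int(x_minus.size),
            summary_a=float(x_plus.mean()) if x_plus.size else float("nan"),
            summary_b=float(x_minus.mean()) if x_minus.size else float("nan"),
            statistic=float("nan"),
            pvalue=float("nan"),
            direction="none",
            extras={**extras, "reason": reason},
        )
    if np.array_equal(np.sort(x_plus), np.sort(x_minus)) or (
        len(np.unique(np.concatenate([x_plus, x_minus]))) == 1
    ):
        stat, p = float(x_plus.size * (x_plus.size + 1) / 2.0), 1.0
    else:
        stat, p = wilcoxon_rank_sum(x_plus, x_minus)
    mean_a, mean_b = float(x_plus.mean()), float(x_minus.mean())
    return SpatialTestResult(
        test=f"ligand_conditioned_receptor[{neighborhood}]",
        n_a=int(x_plus.size),
        n_b=int(x_minus.size),
        summary_a=mean_a,
        summary_b=mean_b,
        statistic=stat,
        pvalue=p,
        direction=_direction(mean_a, mean_b),
        extras=extras,
    )
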