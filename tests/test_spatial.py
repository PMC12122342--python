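"""Spot annotation, colocalization composition, distances and ligand tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichecoloc import (
    MarkerPanel,
    SpotGeometry,
    call_positive_spots,
    ligand_conditioned_receptor,
    load_marker_panels,
    nearest_distance_test,
    neighborhood_composition,
    normalize_cp10k_log1p,
    sample_qualifies,
    wilcoxon_rank_sum,
)
from conftest import make_matrix

TC17_PANEL = MarkerPanel("tc17", (("CD8A", "CD8B"), ("IL17A", "RORC")))
TUMOR_PANEL = MarkerPanel("tumor", (("KRT17", "PRAME", "GNGT1", "GJB5", "PI3"),))


def geometry(rows_cols, barcodes=None, pixel=False):
    barcodes = barcodes or [f"s{i}" for i in range(len(rows_cols))]
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": 1,
            "array_row": [r for r, _ in rows_cols],
            "array_col": [c for _, c in rows_cols],
        }
    ).set_index("barcode")
    if pixel:
        df["pxl_row"] = df["array_row"] * 10.0
        df["pxl_col"] = df["array_col"] * 10.0
    return SpotGeometry(df)


def labels_frame(tc17, tumor, barcodes=None):
    barcodes = barcodes or [f"s{i}" for i in range(len(tc17))]
    return pd.DataFrame(
        {"tc17": list(tc17), "tumor": list(tumor)},
        index=pd.Index(barcodes, name="barcode"),
    )


# ---------------------------------------------------------------- annotation

def test_marker_logic_any_within_all_across():
    genes = ["CD8A", "CD8B", "IL17A", "RORC"]
    counts = np.array(
        [
            [2, 2],  # CD8A
            [0, 0],  # CD8B
            [1, 0],  # IL17A
            [0, 0],  # RORC
        ]
    )
    em = make_matrix(counts, genes=genes, barcodes=["pos", "neg"])
    flags = call_positive_spots(em, [TC17_PANEL])
    assert bool(flags.loc["pos", "tc17"]) is True  # ANY within group satisfied
    assert bool(flags.loc["neg", "tc17"]) is False  # second group fails


def test_annotation_matches_brute_force_random_toy():
    rng = np.random.default_rng(5)
    genes = TC17_PANEL.all_genes + list(TUMOR_PANEL.all_genes)
    counts = rng.integers(0, 3, size=(len(genes), 20))
    em = make_matrix(counts, genes=genes)
    flags = call_positive_spots(em, [TC17_PANEL, TUMOR_PANEL])
    gi = {g: i for i, g in enumerate(genes)}
    for j, bc in enumerate(em.barcodes):
        for panel in (TC17_PANEL, TUMOR_PANEL):
            want = all(
                any(counts[gi[g], j] >= panel.threshold for g in grp)
                for grp in panel.groups
            )
            assert bool(flags.loc[bc, panel.cell_type]) == want
    assert (flags["coloc"] == (flags["tc17"] & flags["tumor"])).all()
    assert flags["coloc"].sum() <= min(flags["tc17"].sum(), flags["tumor"].sum())


def test_threshold_monotonicity():
    rng = np.random.default_rng(8)
    genes = list(TUMOR_PANEL.all_genes)
    em = make_matrix(rng.integers(0, 5, size=(len(genes), 40)), genes=genes)
    n_pos = [
        call_positive_spots(em, [MarkerPanel("tumor", TUMOR_PANEL.groups, threshold=t)])[
            "tumor"
        ].sum()
        for t in (1, 2, 3, 4)
    ]
    assert all(a >= b for a, b in zip(n_pos, n_pos[1:]))


def test_missing_panel_genes_warned_all_absent_error(caplog):
    em = make_matrix([[1, 0], [0, 1]], genes=["CD8A", "IL17A"], barcodes=["a", "b"])
    with caplog.at_level("WARNING", logger="nichecoloc"):
        flags = call_positive_spots(em, [TC17_PANEL])
    assert any("missing gene" in r.message for r in caplog.records)
    assert bool(flags.loc["a", "tc17"]) is False  # needs both groups
    with pytest.raises(ValueError, match="no genes"):
        call_positive_spots(em, [TUMOR_PANEL])


def test_packaged_panels_load():
    panels = load_marker_panels()
    assert set(panels) == {"tc17", "tumor"}
    assert panels["tc17"].groups == (("CD8A", "CD8B"), ("IL17A", "RORC"))
    assert panels["tumor"].groups == (("KRT17", "PRAME", "GNGT1", "GJB5", "PI3"),)


# ------------------------------------------------- neighborhood composition

def test_composition_no_contrast_when_all_positive():
    lab = labels_frame(tc17=[True] * 6, tumor=[True, True, True, False, False, False])
    res = neighborhood_composition(lab)
    assert res.summary_a == 1.0 and res.summary_b == 1.0
    assert res.pvalue == 1.0


def _fisher_two_sided_oracle(table):
    """Hypergeometric enumeration: sum P(t) over tables with P(t) <= P(obs)."""
    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    rv = stats.hypergeom(n1 + n2, n1, m)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k)
        for k in range(max(0, m - n2), min(n1, m) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-12)
    )


def test_composition_fisher_matches_hypergeometric_enumeration():
    lab = labels_frame(
        tc17=[True] * 8 + [False] * 2 + [True] + [False] * 9,
        tumor=[True] * 10 + [False] * 10,
    )
    res = neighborhood_composition(lab)
    assert res.extras["table"] == [[8, 2], [1, 9]]
    assert res.pvalue == pytest.approx(_fisher_two_sided_oracle([[8, 2], [1, 9]]), rel=1e-9)


def test_composition_errors_and_degenerate_cases(caplog):
    with pytest.raises(ValueError, match="no tumor region"):
        neighborhood_composition(labels_frame([True], [False]))
    with caplog.at_level("WARNING", logger="nichecoloc"):
        res = neighborhood_composition(
            labels_frame([False] * 4, [True, True, False, False])
        )
    assert res.pvalue == 1.0 and res.summary_a == 0.0 and res.summary_b == 0.0


def test_composition_same_spot_ignores_geometry():
    lab = labels_frame([True, False, True, False], [True, True, False, False])
    assert (
        neighborhood_composition(lab, geometry=None).pvalue
        == neighborhood_composition(
            lab, geometry=geometry([(0, 0), (0, 2), (1, 1), (1, 3)])
        ).pvalue
    )


def test_ring1_composition_uses_hex_adjacency():
    # row 0: tumor at (0,0); (0,2) and (1,1) are its hex neighbors; (2,8) is far
    geom = geometry([(0, 0), (0, 2), (1, 1), (2, 8)], barcodes=["t", "n1", "n2", "far"])
    lab = labels_frame(
        tc17=[False, True, True, False],
        tumor=[True, False, False, False],
        barcodes=["t", "n1", "n2", "far"],
    )
    res = neighborhood_composition(lab, geom, neighborhood="ring1")
    assert res.n_a == 2 and res.summary_a == 1.0  # both neighbors Tc17+
    assert res.n_b == 1 and res.summary_b == 0.0  # 'far' is not adjacent


def test_hex_neighbors_interior_count():
    coords = [
        (r, 2 * j + (r % 2)) for r in range(5) for j in range(5)
    ]
    geom = geometry(coords, barcodes=[f"s{r}_{j}" for r in range(5) for j in range(5)])
    nbrs = geom.hex_neighbors()
    assert len(nbrs["s2_2"]) == 6  # interior spot has the full hex ring


# ---------------------------------------------------------- sample qualifies

def test_sample_qualifies_strict_five_percent_rule():
    tumor = [True] * 100
    ok, prop, _ = sample_qualifies(labels_frame([True] * 6 + [False] * 94, tumor))
    assert ok and prop == pytest.approx(0.06)
    ok5, prop5, reason = sample_qualifies(labels_frame([True] * 5 + [False] * 95, tumor))
    assert not ok5 and prop5 == pytest.approx(0.05) and "<=" in reason
    none_ok, prop_nan, reason = sample_qualifies(labels_frame([True], [False]))
    assert not none_ok and np.isnan(prop_nan) and reason == "no tumor region"


# ------------------------------------------------------- nearest distances

def test_nearest_distance_collinear_hand_geometry():
    geom = geometry([(0, 0), (0, 3), (0, 7)], barcodes=["tc", "tum", "non"])
    lab = labels_frame([True, False, False], [False, True, False], ["tc", "tum", "non"])
    res = nearest_distance_test(lab, geom)
    assert res.summary_a == pytest.approx(3.0)  # tumor spot at x=3
    assert res.summary_b == pytest.approx(3.5)  # median of {0 (tc17 spot), 7}


def test_tc17_positive_tumor_spot_has_distance_zero():
    geom = geometry([(0, 0), (0, 4)], barcodes=["both", "other"])
    lab = labels_frame([True, False], [True, False], ["both", "other"])
    res = nearest_distance_test(lab, geom)
    assert res.summary_a == 0.0


def test_nearest_distance_matches_all_pairs_brute_force():
    rng = np.random.default_rng(2)
    coords = [(int(r), int(c)) for r, c in rng.integers(0, 40, size=(30, 2))]
    coords = list(dict.fromkeys(coords))  # unique positions
    n = len(coords)
    tc17 = rng.random(n) < 0.3
    tc17[0] = True
    tumor = rng.random(n) < 0.4
    tumor[1], tumor[2] = True, False
    geom = geometry(coords)
    res = nearest_distance_test(labels_frame(tc17, tumor), geom)
    pts = np.array([(c, r) for r, c in coords], float)
    brute = np.array(
        [min(np.hypot(*(p - q)) for q in pts[tc17]) for p in pts]
    )
    med_a, med_b = np.median(brute[tumor]), np.median(brute[~tumor])
    assert res.summary_a == pytest.approx(med_a)
    assert res.summary_b == pytest.approx(med_b)


def test_distances_invariant_under_rotation_translation():
    rng = np.random.default_rng(4)
    pts = rng.random((20, 2)) * 50
    tc17 = rng.random(20) < 0.4
    tumor = rng.random(20) < 0.5
    tc17[0] = tumor[1] = True
    tumor[0] = False

    def run(xy):
        df = pd.DataFrame(
            {
                "barcode": [f"s{i}" for i in range(20)],
                "in_tissue": 1,
                "array_row": range(20),  # placeholder; pixel system is used
                "array_col": range(20),
                "pxl_row": xy[:, 1],
                "pxl_col": xy[:, 0],
            }
        ).set_index("barcode")
        return nearest_distance_test(
            labels_frame(tc17, tumor), SpotGeometry(df), coord_system="pixel"
        )

    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([100.0, -40.0])
    a, b = run(pts), run(moved)
    assert a.summary_a == pytest.approx(b.summary_a)
    assert a.pvalue == pytest.approx(b.pvalue)


def test_nearest_distance_requires_tc17():
    geom = geometry([(0, 0), (0, 2)])
    with pytest.raises(ValueError, match="no Tc17"):
        nearest_distance_test(labels_frame([False, False], [True, False]), geom)


# ------------------------------------------------ ligand-conditioned receptor

def _ligand_toy():
    """10 colocalized spots; CXCR6 elevated exactly where CXCL16 is present."""
    genes = ["CD8A", "IL17A", "KRT17", "CXCL16", "CXCR6"]
    n = 10
    counts = np.ones((5, n), dtype=int)
    counts[3] = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0]      # CXCL16+ in first six
    counts[4] = [9, 8, 9, 7, 8, 9, 1, 1, 2, 1]      # CXCR6 elevated near ligand
    em = make_matrix(counts, genes=genes)
    lab = labels_frame([True] * n, [True] * n, barcodes=list(em.barcodes))
    return em, lab


def test_ligand_grouping_matches_manual_assignment():
    em, lab = _ligand_toy()
    res = ligand_conditioned_receptor(em, lab)
    assert (res.n_a, res.n_b) == (6, 4)
    norm = normalize_cp10k_log1p(em)
    cxcr6 = norm.gene_values("CXCR6")
    assert res.summary_a == pytest.approx(cxcr6[:6].mean())
    assert res.summary_b == pytest.approx(cxcr6[6:].mean())
    assert res.summary_a > res.summary_b and res.pvalue < 0.05


def test_ligand_identical_receptor_values_give_p_one():
    em, lab = _ligand_toy()
    counts = em.counts.toarray()
    counts[4] = 3  # flat CXCR6
    counts[1] = 2 - counts[3]  # equal spot totals -> identical normalized CXCR6
    flat = make_matrix(counts, genes=list(em.genes), barcodes=list(em.barcodes))
    res = ligand_conditioned_receptor(flat, lab)
    assert res.pvalue == 1.0
    assert res.summary_a == pytest.approx(res.summary_b)


def test_ligand_empty_group_reports_reason(caplog):
    em, lab = _ligand_toy()
    counts = em.counts.toarray()
    counts[3] = 1  # every tumor spot ligand-positive -> empty minus group
    allpos = make_matrix(counts, genes=list(em.genes), barcodes=list(em.barcodes))
    with caplog.at_level("WARNING", logger="nichecoloc"):
        res = ligand_conditioned_receptor(allpos, lab)
    assert np.isnan(res.pvalue) and "empty" in res.extras["reason"]


def test_ligand_ring1_grouping_on_constructed_layout():
    # tc17 spot at (0,2) neighbors a CXCL16+ tumor at (0,0);
    # tc17 spot at (2,8) neighbors only a CXCL16- tumor at (2,6);
    # tc17 spot at (6,20) neighbors no tumor -> excluded
    coords = [(0, 0), (0, 2), (2, 6), (2, 8), (6, 20)]
    names = ["tumA", "tcA", "tumB", "tcB", "tcFar"]
    genes = ["CD8A", "IL17A", "KRT17", "CXCL16", "CXCR6"]
    counts = np.zeros((5, 5), dtype=int)
    counts[0] = [0, 1, 0, 1, 1]
    counts[1] = [0, 1, 0, 1, 1]
    counts[2] = [1, 0, 1, 0, 0]
    counts[3] = [2, 0, 0, 0, 0]   # ligand only in tumA
    counts[4] = [0, 5, 0, 2, 9]
    em = make_matrix(counts, genes=genes, barcodes=names)
    lab = labels_frame(
        [False, True, False, True, True], [True, False, True, False, False], names
    )
    res = ligand_conditioned_receptor(
        em, lab, geometry(coords, barcodes=names), neighborhood="ring1"
    )
    assert (res.n_a, res.n_b) == (1, 1)  # tcA in +, tcB in -, tcFar excluded


def test_ligand_missing_gene_rejected(small_raw):
    lab = labels_frame(
        [True] * small_raw.n_obs, [True] * small_raw.n_obs, list(small_raw.barcodes)
    )
    with pytest.raises(ValueError, match="CXCL16"):
        ligand_conditioned_receptor(small_raw, lab)


# --------------------------------------------------------- Wilcoxon rank-sum

def _exact_rank_sum_oracle(a, b):
    """Two-sided p by exhaustive enumeration of group assignments (no ties)."""
    pooled = np.sort(np.concatenate([a, b]))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    w_obs = sum(ranks[v] for v in a)
    mean_w = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(pooled, n_a):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def test_wilcoxon_equal_multisets_p_one():
    _, p = wilcoxon_rank_sum([1, 2, 3], [3, 1, 2])
    assert p == pytest.approx(1.0)


def test_wilcoxon_exact_matches_enumeration():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    w, p = wilcoxon_rank_sum(a, b)
    assert w == 6.0  # ranks 1+2+3
    assert p == pytest.approx(_exact_rank_sum_oracle(np.array(a), np.array(b)))
    assert p == pytest.approx(2 / 20)  # both extreme assignments of C(6,3)=20
    rng = np.random.default_rng(9)
    for _ in range(3):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.8, 1, 4)
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_exact_rank_sum_oracle(a, b))


def test_wilcoxon_normal_approximation_close_to_exact():
    rng = np.random.default_rng(12)
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
    _, p_exact = wilcoxon_rank_sum(a, b)  # min(n) < 25, no ties -> exact
    p_approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    assert abs(p_exact - p_approx) < 0.005


def test_wilcoxon_empty_group_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        wilcoxon_rank_sum([], [1.0])
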