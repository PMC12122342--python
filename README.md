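# nichecoloc

Statistics for asking whether a rare immune population shares its spatial
niche with tumor cells — built around the gastric-cancer Tc17 question
(IL-17A-producing CD8+ T cells and the CXCL16–CXCR6 recruitment axis), but
applicable to any marker-definable pair of populations measured by
single-cell RNA-seq plus array-based spatial transcriptomics.

The package is aimed at computational biologists who have (i) a cell-level
count matrix with cluster/tissue annotations and (ii) Visium-style spot data,
and who want the following questions answered with explicit, testable
statistics rather than ad hoc scripts:

* **Which clusters prefer which tissue?** The ratio of observed to expected
  cell counts, *Ro/e* = n<sub>ct</sub> / (n<sub>c·</sub> n<sub>·t</sub> / n),
  per (cluster, tissue) under row/column independence; *Ro/e* > 1 marks
  enrichment, < 1 depletion. An optional permutation null (shuffling tissue
  labels over cells) supplies confidence intervals and p-values.
* **Is a cell malignant-leaning?** Binned-control signature scoring:
  score(cell) = mean expression of the gene set − mean of control genes
  matched on dataset-average expression (24 equal-frequency bins, 100
  controls per set gene), and the tumor-minus-normal differential score.
* **Do the two populations co-occur in space?** Spots are annotated by
  marker colocalization (ANY gene within a group, ALL groups; e.g. Tc17 =
  CD8A/CD8B ∧ IL17A/RORC, tumor = KRT17/PRAME/GNGT1/GJB5/PI3), then: Fisher
  exact test on same-spot (or hex-ring) co-occurrence; the strict 5%
  qualifying-sample rule; Wilcoxon rank-sum on nearest-neighbor Euclidean
  distances to the rare population; and Wilcoxon comparison of normalized
  receptor (CXCR6) expression in spots near ligand-positive vs
  ligand-negative (CXCL16±) tumor spots.
* **Do sender and receiver talk?** Direction-sensitive ligand–receptor pair
  counting over the top-50% expressed genes of each cell type, per category;
  per-gene Wilcoxon differential expression with Benjamini–Hochberg control
  (up: adjusted p < 0.01 and log2FC > 1); and Spearman concordance of
  single-cell vs bulk log2 fold changes over the top-1000 genes.

A negative-binomial simulator generates every input — cluster×tissue tables
with planted enrichment, staggered hexagonal spot lattices with a tunable
co-occurrence boost β and ligand→receptor coupling δ, and paired pseudobulk
profiles — so the whole pipeline is validated end-to-end without downloads.

## Worked example

```python
import nichecoloc as nc

cfg = nc.SimConfig(beta=2.0, delta=3.0, seed=1)   # planted co-occurrence + coupling
em, geom, truth = nc.simulate_spatial(cfg)
labels = nc.call_positive_spots(em, nc.load_marker_panels())

comp = nc.neighborhood_composition(labels, geom)
dist = nc.nearest_distance_test(labels, geom)
lig  = nc.ligand_conditioned_receptor(em, labels, geom)
```

This prints (via the summaries on each result object):

```
spots: 2000 tumor+: 671 tc17+: 565 coloc: 342
tc17 proportion: tumor spots 0.510 vs other 0.168, Fisher p = 7.83e-56
qualifies (5% rule): True (proportion 0.510)
nearest-Tc17 distance: tumor median 0.00 vs other 1.41, rank-sum p = 1.23e-42
CXCR6 in Tc17 spots: near CXCL16+ 2.938 vs CXCL16- 1.698, p = 7.04e-13
```

Reading: with a log-odds boost of β = 2, half the tumor spots also carry the
Tc17 signature versus 17% elsewhere, tumor spots sit closer to their nearest
Tc17 spot, the sample clears the 5% Tc17-in-tumor-regions filter, and Tc17
spots adjacent to CXCL16+ tumor show the planted elevation of CXCR6 — each
with its two-sided p-value.

The same steps are available from the shell:

```bash
nichecoloc simulate --seed 1 --out-dir sim/
nichecoloc spatial --mtx sim/matrix.mtx --genes sim/genes.tsv \
    --barcodes sim/barcodes.tsv --positions sim/positions.csv --out results.tsv
nichecoloc roe --counts cluster_by_tissue.tsv --out roe.tsv
```

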