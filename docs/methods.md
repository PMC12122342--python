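# Methods

## Scope and data model

The package operates on sparse gene × observation count matrices (cells or
spatial spots) in the 10x Matrix Market convention, a cell metadata table
(barcode, cluster, tissue, sample), Visium-dialect spot positions, YAML
marker panels and a ligand–receptor TSV. Two expression layers exist: raw
integer counts and the log-normalized layer ln(1 + 10,000·x/total)
("log1p CP10K", scale factor 10,000 — the default of the standard
single-cell toolchains). Raw counts drive QC and marker positivity;
normalized values drive every expression comparison.

## Quality control

Cells are kept when total UMI ∈ [501, 7000] and the percentage of counts on
mitochondrial genes is ≤ 20; genes are then kept when detected in ≥ 3
surviving cells. Choices worth noting:

* The bounds read "fewer than 501 / over 7000 / higher than 20" as an
  inclusive retention window — 501, 7000 and 20.0% all survive.
* Mitochondrial genes are identified by a configurable symbol prefix
  (default `MT-`), the de facto convention for human data.
* The gene filter runs after the cell filter, fixed in that order for
  determinism. QC is applied per input matrix; merged multi-sample matrices
  are filtered as given.
* Doublet detection is out of scope; `qc_filter` accepts an external
  barcode exclusion list instead.
* Removing every cell is a warning, not an exception, so batch pipelines
  can report rather than crash.

QC is idempotent in practice but not by construction: removing genes lowers
cell totals, so a cell sitting exactly at the UMI floor could fail a second
pass. With the simulator's defaults (totals ≈ 1800 ± 300) this never
triggers, and the property is tested under those conditions.

## Ro/e tissue enrichment

For a cluster × tissue count table, expected(c,t) = row(c)·col(t)/N and
Ro/e = observed/expected. Values > 1 are labelled enriched, < 1 depleted;
exact ties at 1 get a distinct "boundary" label (the classical rule uses
strict inequalities in both directions and says nothing about ties); cells
with a zero marginal are "undefined". Ro/e is scale-invariant and satisfies
Σ_t expected·roe = row total, both enforced by tests. Cells are pooled
across samples by default; per-sample tables can be computed by passing
per-sample metadata.

The permutation extension (clearly optional output) permutes tissue labels
over individual cells — preserving both marginals exactly — and reports the
2.5–97.5 percentile band of the null Ro/e plus an add-one two-sided tail
p-value. It requires ≥ 100 permutations and ≥ 2 tissues.

## Signature scoring

Genes are ranked by dataset-mean expression (ties broken lexicographically
by symbol so runs are reproducible), cut into `n_bins = 24` equal-frequency
bins, and each set gene contributes `n_ctrl = 100` control genes drawn from
its own bin — without replacement when the bin is large enough, with
replacement otherwise. The score is mean(set) − mean(control pool), per
cell. If there are fewer distinct means than bins, the bin count shrinks
with a warning. The defaults mirror the documented defaults of the standard
module-scoring tool.

Properties: constant matrices score exactly zero; adding a constant to every
entry leaves scores unchanged (binning order and controls are unaffected);
random gene sets score zero on average. One caveat matters on tiny gene
universes: with bins close to singletons a set gene's only control candidate
is itself and its contribution cancels exactly. This is the intended
behavior of matched-control scoring and disappears at realistic gene counts;
tests on toy matrices use coarser bins.

The malignancy-leaning score is score(tumor panel) − score(normal panel)
under a shared seed; overlapping panel genes are legal but warned about.

## Spot annotation and spatial statistics

A spot is positive for a cell type when every marker group contributes at
least one gene with raw count ≥ threshold (default 1): ANY within group,
ALL across groups. Logic and threshold are configurable; missing panel genes
are dropped with a warning, and a fully absent panel is an error. Raising
the threshold can only shrink the positive set (tested).

* **Neighborhood composition.** Default neighborhood is the spot itself:
  the 2×2 table of tumor± × Tc17± is tested by two-sided Fisher exact —
  chosen over chi-square because per-sample spot counts can be small. The
  `ring1` alternative compares non-tumor spots hexagonally adjacent to a
  tumor spot against non-adjacent non-tumor spots (Visium staggered lattice:
  column parity matches row parity, neighbors at (0,±2), (±1,±1)). The Tc17
  proportion among all spots is reported alongside the tumor/non-tumor split
  since either denominator is defensible.
* **Qualifying samples.** A sample enters downstream comparisons only when
  the Tc17 proportion among tumor spots strictly exceeds 5% (0.05 exactly
  fails); samples without tumor spots fail with an explicit reason.
* **Nearest distances.** Each spot's Euclidean distance to the nearest
  Tc17-positive spot (k-d tree, verified against all-pairs brute force);
  Tc17 spots contribute 0 to their own group. Distances use plain
  (array_row, array_col) coordinates by default — no √3/2 row compression —
  or pixel coordinates on request; the reported comparisons are invariant to
  any common monotone rescaling, and the row-compression factor changes
  distances by < 14% without reordering typical comparisons. Groups are
  compared by two-sided Wilcoxon rank-sum.
* **Ligand-conditioned receptor expression.** Tumor spots split by raw
  ligand count ≥ 1 (CXCL16± by default). In `same_spot` mode the compared
  units are Tc17∧tumor spots on either side of the split; in `ring1` mode a
  Tc17 spot joins the + group if any own-or-adjacent tumor spot is
  ligand-positive, the − group if it neighbors only ligand-negative tumor,
  and is excluded when it neighbors no tumor. The response is normalized
  (log1p CP10K) receptor expression, compared by Wilcoxon rank-sum; an
  empty group returns p = NaN with the reason attached.

**Wilcoxon rank-sum convention** (used everywhere a rank test appears):
midranks for ties; exact null when the smaller group has < 25 observations
and the pooled sample is tie-free, else normal approximation with tie and
continuity corrections. The reported statistic is the rank sum of the first
group. Verified against exhaustive enumeration of assignments at small n.

## Ligand–receptor screening and differential expression

For each cell type the "highly expressed" set is the top ⌈0.5·G⌉ genes by
mean normalized expression, where G counts genes with nonzero mean within
the type — never-expressed genes are excluded from the denominator, ties at
the cut keep the lexicographically smaller symbol. Pair counting is
direction-sensitive: a database record counts when its ligand is in the
sender set and its receptor in the receiver set, totalled and per category
(cytokine / growth factor / immune checkpoint / other). The packaged
database is a small curated table around CXCL16–CXCR6 and the type-17
interleukins plus controls; real screens should supply a full database.

Differential expression: per-gene two-sided Wilcoxon rank-sum on normalized
values, Benjamini–Hochberg adjustment across tested genes ("adjusted
p-value" is interpreted as FDR). log2FC = log2((mean_a + ε)/(mean_b + ε))
with ε = 1e-9, means taken on the de-logged CP10K scale (expm1 of the log
layer) so that a k-fold expression change reports log2FC ≈ log2 k — the
convention of the standard marker-finding tools. Labels: up iff adjusted
p < 0.01 and log2FC > 1; down symmetric. The operation is antisymmetric
under group swap.

Concordance: the top-1000 genes by absolute single-cell log2FC present in
both tables enter a Spearman rank correlation of the two log2FC vectors
(≥ 10 shared genes required).

## Synthetic data

The generators encode the statistical structure the analyses assume; they
are pure functions of (configuration, seed) with bit-identical outputs.

* **Composition.** The joint is outer(cluster probs, tissue probs), with
  multiplicative folds planted on chosen cells before renormalization, then
  a multinomial draw. A planted fold f does **not** make the cell's Ro/e
  equal f — the fold leaks into the marginals (uniform 3×3, f = 3 gives
  Ro/e 1.32 analytically) — so the returned truth records the exact Ro/e of
  the distorted joint, which is what recovery tests target. Leakage is small
  when the planted cell's baseline marginal masses are small: the default
  recovery scenario (cluster mass 0.04, tissue mass 0.04) has analytic
  Ro/e ≈ 2.58 for f = 3.
* **Spatial.** A rows × cols staggered hexagonal lattice (defaults 40 × 50 =
  2,000 spots, the size used in all calibration and power runs). Per spot:
  tumor ~ Bernoulli(0.30); Tc17 ~ Bernoulli(sigmoid(logit(0.15) + β·tumor)).
  Marker counts are NB(μ = 4, θ = 2) in member spots and NB(0.01) elsewhere
  — the background chosen as a realistic per-gene ambient-contamination
  rate giving ≈ 5% false-positive tumor calls from the 5-gene panel. CXCL16
  draws NB(3, 2) in tumor spots; CXCR6 draws NB(2, 2) in Tc17 spots with
  mean 2 + δ where the neighborhood holds a realized CXCL16+ tumor spot.
  Sixty filler genes NB(30, 10) put spot totals ≈ 1,800, inside the QC
  window. β = δ = 0 defines the null; β = 2 is the co-occurrence effect used
  in power runs, and δ = 3 (a 2 → 5 shift of the CXCR6 mean) was chosen once
  as a realistic chemokine-receptor elevation.
* **Paired bulk.** Replicate r of a group is the per-gene pseudobulk sum
  times exp(N(0, noise_sd)) drawn per gene and replicate; noise_sd = 0
  reproduces the sums exactly. The two-group matrix generator for
  concordance runs uses 500 genes with true log2FC ~ N(0, 1.5) at base mean
  20 — a spread typical of tumor-vs-normal epithelium comparisons.

What the simulator does *not* emulate: transcriptome-wide expression (only
markers plus filler), segmentation/imaging artifacts, spot mixtures with
continuous cell-type proportions, batch effects, and spatial autocorrelation
of expression beyond the planted couplings. Passing tests therefore
demonstrate correctness and calibration of the statistics under the stated
generative model, not robustness to every property of real Visium data.

## Calibration and power (computed by the test suite and acceptance script)

Under the null (β = δ = 0, 2,000 spots, 500 seeded runs) the rejection rate
of each spatial test at α = 0.05 must lie in [0.03, 0.07]. With β = 2 the
tumor-side Tc17 proportion exceeds the non-tumor side in ≥ 95/100 seeds;
with δ = 3 the receptor comparison rejects at α = 0.05 in ≥ 90/100 seeds.
Noise-free pseudobulk concordance is exactly ρ = 1; at noise_sd = 0.1,
ρ > 0.95. These are recomputed from scratch by `scripts/acceptance.py`.

## Numerical conventions and degenerate inputs

* Zero-total cells normalize to all-zero vectors and are flagged in the log.
* Equal-multiset or all-constant group comparisons report p = 1 directly,
  avoiding a zero-variance normal approximation.
* Permutation p-values use the add-one estimator, capped at 1.
* Percentile CIs use linear interpolation (NumPy default).
* All random draws flow through `numpy.random.default_rng(seed)`; no global
  state is touched.

## Known limitations

* Ro/e carries no uncertainty by itself; the permutation CI is an extension
  and is marked as such in outputs.
* Marker-based spot annotation treats each spot as positive/negative; it
  does not deconvolve mixtures, so "Tc17 spot" means "spot containing the
  signature", not a pure cell.
* The exact member lists of published cytolytic/anti-inflammatory signature
  sets live in editable config, not hard-coded truth; users should supply
  their own panels for other tissues.
* The ring-1 neighborhood assumes the Visium parity convention; other array
  layouts need a custom adjacency.
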