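# Methods

This note documents the models and numerical choices behind each pipeline
stage, the structure the synthetic generators emulate, and the limits of
what the synthetic benchmarks demonstrate.

## Signature scoring and preprocessing

A signature score is the arithmetic mean of a sample's expression
(log2(TPM+1) for RNA-seq, normalized intensity for arrays) over the
signature's member genes present in the matrix. Signatures with fewer than
`min_genes_found = 2` matched genes are dropped with a log message; a mean
over one gene would be the gene itself, not a set-level summary.

**Outlier removal.** Samples are clustered by average linkage on the
distance 1 − Pearson(signature-score profiles) and cut into two clusters.
The smaller cluster is declared outliers when it holds fewer than 2% of the
samples *and* its mean cross-cluster distance is at least 0.5 (mean
correlation with the majority below 0.5); the cut then repeats once on the
remainder. The separation guard is needed because the top split of a
perfectly homogeneous cohort is arbitrary — without it, the rule flags a
spurious singleton in cohorts that contain no outliers at all. Samples with
zero-variance profiles (for which correlation is undefined) are flagged
directly. Both thresholds are configurable.

**Correlation filter.** A signature is kept iff its best absolute Pearson
correlation with any other signature reaches `min_abs_cor = 0.3`. With
n ≥ 500 samples the null distribution of a correlation magnitude
(≈ |N(0, 1/√n)|, i.e. ~0.045 SD) puts 0.3 far in the tail, so a signature of
pure independent noise is reliably excluded while anything participating in
co-regulated TME structure survives. Retention is monotone: lowering the
threshold can only enlarge the kept set.

**Cox screen.** Each signature is standardized (mean 0, SD 1) and fit in a
univariate proportional-hazards model, so hazard ratios are per-SD and
comparable across signatures. A signature is *protective* (HR < 1) or
*unfavorable* (HR > 1) when its Wald p < 0.05, otherwise neutral;
zero-variance or non-converged fits are reported neutral with a warning.

## Univariate Cox fits

The Cox partial likelihood uses the **Breslow** tie convention throughout —
the simplest closed form, which makes brute-force oracles and reference
implementations agree to machine precision on tie-free data. The
one-parameter fit is a Newton iteration with step-halving on the score and
observed information; the Wald standard error comes from the information at
the optimum, with 95% CIs and two-sided p-values. Non-convergence after 100
iterations returns the null fit (log HR 0) with `converged=False` rather
than a garbage estimate. Kaplan–Meier estimation and the k-sample log-rank
test are delegated to lifelines; at tied times events precede censorings.

**Optimal cutpoints.** A continuous marker is dichotomized by trying every
distinct value inside the (0.1, 0.9) quantile band as a threshold and
keeping the one maximizing the two-group log-rank statistic (ties → lower
cutpoint). The reported p-value is the naive log-rank p at the chosen cut; a
warning states explicitly that it is not adjusted for the maximal selection
and is therefore anti-conservative.

## NMF consensus subtyping

The factorization minimizes the generalized Kullback–Leibler divergence
D(V‖WH) = Σ V log(V/WH) − V + WH by multiplicative updates — the classic
transcriptomic-subtyping variant, whose updates provably never increase the
objective (asserted numerically in tests). W and H are initialized
Uniform(0,1) scaled so mean(WH) = mean(V); on return W's columns are
normalized to sum 1 with the scale folded into H. Iteration stops when the
average per-iteration relative objective decrease (checked every 10
iterations) falls below `tol = 1e-6`, or at `max_iter = 2000`. Input rows
containing negative entries (e.g. user-centered scores) are shifted up by
their minimum with a warning; all-zero rows or columns are errors.

Hard labels assign each sample to the factor with the largest H entry after
scaling each H row by its maximum (ties → smallest factor index); labels are
renumbered by decreasing subtype size so output is deterministic.

**Rank selection.** For each k in 3…8, 50 random restarts are run and their
labelings aggregated into a consensus matrix C (co-clustering frequency).
Stability is summarized by the cophenetic correlation (between 1 − C and the
cophenetic distances of its average-linkage tree) and the dispersion
coefficient mean(4(C − ½)²) ∈ [0, 1]; the chosen k maximizes their product,
ties to the smallest k. Survey restarts use a 500-iteration cap: hard
labelings stabilize long before the KL objective converges at
over-specified ranks, so the cap trades objective precision nobody consumes
for a several-fold speedup. The final model at the chosen k uses 500
restarts at the full iteration budget; labels come from the best-objective
restart, while the consensus over all restarts is kept for stability
reporting. On zero-noise planted cohorts the survey recovers k_true
exactly; the consensus is essentially crisp but the occasional restart that
lands in a local optimum can keep the cophenetic coefficient a hair below
exactly 1.

## Subtype projection

Training centroids are per-subtype means of z-scored signature scores, with
the training standardization parameters stored. A new cohort is z-scored
per signature *within itself* and each sample is assigned the centroid with
the highest Pearson correlation over shared signatures (ties → smallest
subtype index; the per-sample correlation is returned for QC). Cohort-wise
standardization plus correlation makes the projection invariant to any
per-signature affine rescaling of the new cohort — the property needed to
transfer subtypes across array/RNA-seq platform shifts. At least 80% of the
centroid signatures must be present in the new cohort.

## Signature selection ensemble

The random forest and SVM selectors are classifiers, so survival is reduced
to a binary label: with t* the cohort's median follow-up time, samples that
died at or before t* are "poor" (1), samples followed past t* are "good"
(0), and samples censored at or before t* — whose status at the horizon is
unknown — are excluded. Anchoring at the median keeps the classes roughly
balanced; an outcome dominated by one class makes CV accuracy flat at the
majority rate and accuracy-guided selection degenerate. Any user-supplied
binary label can be passed instead.

* **LASSO-Cox** (scikit-survival coxnet path, l1_ratio = 1): a 100-point
  log-spaced λ path; λ* minimizes the 10-fold cross-validated
  partial-likelihood deviance in the Verweij–Van Houwelingen form
  −2·[ll_full(β_train) − ll_train(β_train)], folds stratified by event
  status. Selected set: nonzero coefficients at λ*, fit on the full data.
* **Random forest**: 1000 unpruned sklearn decision trees on bootstrap
  samples (own bagging loop, which exposes the per-tree out-of-bag indices
  that OOB permutation importance needs). Signatures are ranked by mean
  impurity (Gini) importance and by mean OOB accuracy drop when the
  signature's OOB values are permuted; the selected set is the intersection
  of the two top-30 lists.
* **SVM-RFE**: linear SVM (C = 1) on standardized scores; each round drops
  the ⌈10%⌉ of remaining features with smallest squared weights (constant
  features first, with a warning). Each candidate set along the path is
  scored by 5-fold CV accuracy and the smallest set within one standard
  error of the best accuracy is returned; with all features identical the
  alphabetically first survives, making the degenerate case deterministic.

The prognostic set is the exact three-way intersection, in input order.

## Single-cell stage

QC applies three filters in a fixed, documented order (the order matters
for reproducing cell/gene counts): (1) drop cells with mitochondrial count
fraction > 5% (mitochondrial genes = "MT-" name prefix, the human
nomenclature convention), (2) drop cells expressing < 100 genes, (3) drop
genes expressed in < 5 of the remaining cells. Normalization is
ln(1 + 10⁴·count/cell_total). HVGs are the top 2000 genes by variance
standardized against a binned mean–variance trend (20 equal-occupancy bins
of mean expression, bin trend = median variance); zero-variance genes are
never selected. PCA centers and unit-scales each HVG over cells and
projects onto the top 20 right-singular directions, with each component's
sign fixed so its largest-magnitude loading is positive (bit-identical
repeat runs). Clustering builds a k = 20 nearest-neighbor graph (Euclidean
in PC space), weights edges by the Jaccard overlap of the two cells'
neighbor sets, and runs seeded Leiden modularity optimization at
resolution 0.8. Markers are two-sided Wilcoxon rank-sum tests per gene
(normal approximation with tie correction) of each cluster versus all other
cells, with log2FC = log2((mean expm1 + 1)in / (mean expm1 + 1)out),
Benjamini–Hochberg correction within each cluster, and retention thresholds
FDR < 0.05 and |log2FC| > 0.25. Clusters are annotated with the reference
marker set that is most hypergeometrically enriched among the cluster's
retained positive markers ("unknown" without positive markers, "unlabeled"
on an exact tie).

## Ligand-receptor interactions

For pair (L, R) and ordered cluster pair (sender, receiver), the score is
(mean L in sender + mean R in receiver)/2 on log-normalized expression. A
triple is tested only when both genes are expressed in ≥ 10% of their
cluster's cells; gated or missing-gene triples are reported untested rather
than p = 1. Significance permutes the cluster labels of all cells, reusing
the same 1000 permutations across pairs (one seed → one deterministic run),
and uses the add-one estimate p = (1 + #{permuted ≥ observed})/(1 + 1000),
so the smallest attainable p is 1/1001. Only single-gene ligands and
receptors are supported — no heteromeric complexes.

## Synthetic generators

**Bulk.** k_true = 5 subtypes × 60 samples over 50 signatures × 10 genes.
Signatures are assigned round-robin to subtypes; expression is
baseline (5.0) + effect_size (3.0 log2 units) on active genes + N(0, 0.5),
truncated at 0 (so NMF non-negativity holds by construction). Survival is
exponential with per-subtype log hazards spread over ±0.7 around a base
hazard of 0.02/month, and independent exponential censoring tuned to a 30%
censoring fraction — proportional hazards hold exactly, giving Cox
recovery tests a known truth. A separate generator
(`gen_prognostic_scores`) plants 5 informative signatures among 50 (per-SD
log HR 0.8 each, n = 600) for the selection-ensemble benchmarks.

**Single cell.** 4 cell types × 150 cells over 1200 genes. Background
counts are negative binomial (size 2) with per-gene baseline means drawn
from a Gamma (mean 1.0) — a flat baseline would make mean-binned variance
trends degenerate. Marker genes (20 per type, fold 8 in their type) and
ligand/receptor genes get baselines shifted up by 0.4: a planted
fold-change on a silent gene would be no marker at all. Mitochondrial gene
means are scaled so the expected mitochondrial count fraction is 2% in good
cells and 30% in the 10 planted low-quality cells, which also express < 100
genes. One ligand-receptor pair (fold 8) is planted between types 0 → 1.

**What the benchmarks do and do not show.** The generators produce
well-separated, noise-homogeneous structure: passing them demonstrates
correctness of the algorithms and calibration of the tests, not performance
on real cohorts with batch effects, correlated signatures, doublets,
ambient RNA, or overlapping cell states. Batch correction is deliberately
out of scope; inputs are assumed already normalized.

## Problem sizes and determinism

Default benchmark sizes (300 bulk samples, 600 cells, 50 restarts per
surveyed rank, 500 final restarts, 1000 permutations, 500 null replicates)
were chosen so the full suite runs on a single CPU in minutes while leaving
the recovery margins comfortable. Every stochastic stage takes an explicit
seed; pipeline stages derive child seeds deterministically from the master
`RunConfig.seed`, and `run-all` records all parameters, seeds, and output
hashes in a manifest so a run can be verified byte-for-byte.
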