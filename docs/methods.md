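# Methods

`plasticlust` implements a sparse-clustering workflow for small-sample,
high-dimensional molecular development data: expression of `p` proteins or
genes measured in `n` postmortem tissue samples spanning the lifespan, with
`p` of the same order as `n` or far larger. The goal is to partition samples
into data-driven lifespan stages, identify the features that drive the
partition, and condense those features into composite "plasticity
phenotype" descriptors per stage.

## Sparse k-means and the robust trimmed variant

### Model

Sparse k-means assigns each feature `j` a non-negative weight `w_j` and
maximises the weighted between-cluster sum of squares

    maximise   sum_j w_j * BCSS_j(C)
    subject to ||w||_2 <= 1,  ||w||_1 <= s,  w >= 0,

jointly over the partition `C` and the weights. The L1 (lasso) bound `s` in
`(1, sqrt(p)]` controls sparsity: at `s = sqrt(p)` the constraint is
inactive and the solution keeps every feature (weights proportional to the
per-feature BCSS); as `s` approaches 1, the weights of features that do not
separate the clusters are driven to exactly zero. Optimisation alternates

1. k-means in the weighted metric `d_w(x, c) = sum_j w_j (x_j - c_j)^2`
   with the weights held fixed, and
2. the closed-form weight update: soft-threshold the BCSS vector and
   L2-normalise, the threshold chosen by bisection so `||w||_1 = s`
   (`update_weights`). With exactly tied maximal BCSS values the L1 norm of
   the thresholded vector is discontinuous in the threshold; the maximiser
   then lies strictly inside the L2 sphere at `||w||_1 = s` and the solver
   rescales onto that face. This is the one case in which the returned
   weights have `||w||_2 < 1`.

Each alternation re-solves the k-means step from the warm-started centres
*plus* fresh k-means++ seedings in the current metric, keeping the best
objective. This matters in the variable-selection regime: the first
partition forms in the uniform metric, which is dominated by noise features,
and a single warm-started descent cannot escape that basin once the weights
begin to concentrate.

Convergence: relative L1 change of the weights below `1e-4`, or 20
alternations. Restarts: `n_starts` (default 10) independent k-means++
seedings of the whole alternation; deterministic given the seed.

### Trimming (robust variant)

The robust variant excludes, per iteration, the `ceil(alpha * n)` samples
farthest from their centre in the weighted metric (`O_W`) from the centre
updates, and additionally the `ceil(alpha * n)` farthest in the plain
Euclidean metric (`O_E`) from the weight update — an outlier whose
corrupted features happen to carry near-zero weight must not steer the
reweighting. After convergence every excluded sample is assigned to the
nearest centre in the weighted metric and flagged in `outlier_flags`;
`alpha = 0` reduces bit-for-bit to the non-robust run at equal seed.

Three further design choices were forced by measurable failure modes:

* **Small-cluster rule.** Distance trimming cannot flag an extreme sample
  that captures a centre (its distance to itself is zero). After each
  Lloyd convergence, members of clusters kept alive by a single untrimmed
  sample are flagged as potential outliers, the centre is re-seeded, and
  Lloyd re-runs (a bounded refinement; doing this inside the Lloyd loop
  makes it oscillate). Candidate partitions that still hold an untrimmed
  singleton cluster are ranked behind all others.
* **Selection criterion.** Restarts and candidate partitions are compared
  by the *trimmed weighted within-SS* (lower is better) when `alpha > 0`.
  Comparing by between-SS is wrong under trimming: the trim set, and
  therefore the total dispersion, differs between candidates, and a
  partition that wastes a cluster on an extreme outlier inflates its
  between-SS without bound. At `alpha = 0` the two criteria coincide and
  the weighted between-cluster objective is used.
* **Robust standardisation.** Features are z-scored before clustering
  (default on; expression studies normalise to a control and features
  must enter the metric on a common scale). In robust mode the mean/SD
  are estimated with the `ceil(alpha * n)` most extreme rows (by a
  median/MAD multivariate score) excluded: outlier samples inflate the SD
  of exactly the features they corrupt, diluting those features'
  standardised signal. Trimming whole rows keeps the noise/signal scale
  balance intact — per-feature tail-trimming would truncate every noise
  feature's tails and systematically amplify noise, and a MAD scale
  mis-handles multimodal staged trajectories (its "robust scale" is the
  within-stage noise, not the feature's dynamic range).

Seeding in robust mode alternates k-means++ with uniform-random draws:
k-means++ picks centres with probability proportional to squared distance
and therefore seeds on the very outliers trimming is meant to exclude.

Defaults: `alpha = 0.1` (four trimmed samples at the 31-sample study
scale), nearest-centre ties resolved toward the lowest cluster index,
empty clusters re-seeded from the farthest untrimmed sample.

## Choosing k and the lasso bound

### WWSS elbow

`k` is chosen from the elbow of the weighted within-cluster sum of squares
(WWSS) versus `k`, in two phases (`elbow_k`):

1. the robust sparse clustering runs `n_iter` times per `k` over the whole
   range (default 2–9) with fresh seeds;
2. the *median* weight per feature across all those runs defines the
   selected feature support (`weight >= 0.2 * max`), and the WWSS-vs-k
   curve is traced by multi-restart weighted k-means with **uniform**
   weights on that support.

Phase 2 exists because WWSS values produced under per-run adaptive weights
are not commensurable across `k`: at small `k` the lasso re-concentrates
weight on whichever few features make the coarse partition look tight,
which flattens the elbow (measured directly: the per-k adaptive curves
located a six-stage planted `k` in under 15% of seeds, the common-metric
curves in ~96%). The median across runs is used for the support because a
noise feature that captures weight in a few runs would otherwise flood the
within-SS floor of the curve at every `k`; uniform weights on the support
matter because an uneven concentrated metric collapses the stage geometry
onto one axis, whose equally spaced clusters produce an elbow-less
`1/k`-type decay.

The elbow itself is the interior point of maximum discrete curvature
`|y''| / (1 + y'^2)^(3/2)` after normalising both axes to `[0, 1]` and
Savitzky–Golay smoothing (window 3, order 2). Raw second differences are
maximal at the steep small-k end of any dispersion curve regardless of
where the elbow sits; the curvature denominator suppresses exactly that
region, and axis normalisation makes the choice invariant to rescaling the
expression values. Derivatives are taken as central differences at the
interior points — a double-gradient pass smears a kink's curvature onto
the point after it, where the flat slope shrinks the denominator and
biases the pick one step high. The window is the smallest possible because
a typical k range has only eight points and wider windows blur the kink.

### Permutation gap for the bound

`select_l1_bound` computes, for each candidate bound,
`gap(s) = log O(s; data) − mean_b log O(s; permuted data_b)` where `O` is
the weighted between-cluster objective and each permutation shuffles every
feature column independently. The observed objective is averaged over
`n_obs = 3` runs (restart noise on a single run is comparable to the gap
differences of interest). Selection follows the one-standard-error rule:
the smallest candidate whose gap reaches the maximum gap minus one SE of
the permuted log objectives — the sparsest metric the permutation evidence
cannot distinguish from the best. A flat gap curve (no informative
features) therefore returns the smallest candidate.

## Consensus and the age-randomisation null

`run_consensus` re-runs the clustering `n_iter` times (default 100) from
different seeds, aligns labels by ordering clusters by ascending median
sample age (cluster A = youngest, matching how lifespan clusters are
presented), and accumulates a sample × cluster co-assignment count matrix,
per-feature mean weights, and the modal assignment (count ties resolve
toward the younger cluster). Cluster overlap is the Jaccard similarity of
membership sets, a sample belonging to a cluster's set if assigned there
in at least `min_count` runs (default 10% of `n_iter`; the similarity of
small membership sets is otherwise dominated by single samples). Replicate
runs of a subject can be kept as samples or averaged first
(`replicates="keep"|"average"`).

Ages never enter the clustering itself, so the age progression of the
clusters has a clean permutation null (`age_randomization_null`): each
iteration re-clusters the expression matrix from a fresh seed and permutes
the ages over samples. The progression statistic is the Spearman
correlation, across samples, between age and the age-ordered rank of the
sample's cluster. Ordering clusters by median age before ranking induces a
positive bias, but the identical procedure is applied to observed and
permuted age vectors, so the bias cancels in the empirical p-value
`(1 + #{null >= observed}) / (n_iter + 1)`. (The correlation between
cluster rank and cluster median age is *not* usable as a statistic: after
age-ordering it is identically 1.) Per-cluster age IQRs under true and
permuted ages are returned alongside; fewer than 20 iterations flags the
null as degenerate.

## Over-representation analysis

For each feature, a normal null is built from the mean and SD of the
expression over all samples and sampled `n_sim` times (default 10,000). A
cluster is called *over*-represented if its 25th percentile exceeds the
simulated 95th percentile, *under*-represented if its 75th percentile
falls below the simulated 5th, and neutral otherwise. All quantiles use
linear interpolation. Cutoff pairs are configurable (e.g. 1st/99th for a
stricter call, which by construction flags a subset of the default's
calls); `analytic=True` replaces simulation with exact normal quantiles
(mean ± 1.6449·SD at the defaults) — the deterministic `n_sim → ∞` limit.
A zero-SD feature yields neutral calls with a warning. Note the null is
estimated over *all* samples, shifted clusters included, so a large
deviant cluster partially masks itself; this mirrors the procedure as
practised and is the reason calibration tests use small flagged fractions.

## PCA cos², agreement, and composite features

`pca_cos2` performs correlation PCA (SVD of the z-scored matrix); variable
coordinates are `loading × sqrt(eigenvalue)` and
`cos²[j,d] = coord[j,d]² / sum_d' coord[j,d']²` with the sum over every
available dimension, so each feature's cos² over all dimensions sums to 1.
The per-feature sum over the first three dimensions plays the same role
for PCA that the adaptive weight plays for the sparse clustering, and
`weight_cos2_agreement` compares the two: Spearman's rho on the raw
vectors, then Bland–Altman limits of agreement on the max-normalised
vectors (mean difference with t-based 95% CI, limits `mean ± 1.96 SD` with
their CIs, and the features outside the limits).

Composite candidate features come from the basis vectors
(`propose_candidate_features`): among features whose summed cos² exceeds
0.5, per dimension, loadings at or above the 70th percentile of |loading|
form the high-amplitude set; same-sign groups of at least two become a
*sum* and opposite-sign groups an *index* `(A − B)/(A + B)` (bounded in
[−1, 1] for non-negative expression, +1 favouring side A; an index is
undefined, and emitted as NaN, where `A + B = 0`). The procedure is
semi-supervised by design: `pairing_rules` pins expert-chosen
combinations, reflecting that domain knowledge about which proteins form
functional pairs outranks loading heuristics. Candidates are validated by
Pearson correlation against the first three PC score vectors with
Bonferroni correction over `n_features × 3` tests at family alpha 0.05;
a feature is retained if significant on any dimension.

`phenotype_table` reports the median value of each validated feature per
age-ordered cluster. Sum-kind rows share one scale anchored at [0, max
median over all sum features]; index rows are anchored at [−1, +1]. Rows
are ordered by average-linkage hierarchical clustering of `1 − Pearson r`
distances between feature value vectors, and over/under flags from
`ora_classify` applied to the feature values are attached.

## Trajectories and cross-omics coupling

`loess_trajectory` is a locally weighted polynomial regression (default
quadratic, tricube weights over the `span` fraction of nearest samples,
span 0.75). Because the fit at any point is linear in the responses,
pointwise standard errors follow from the smoother rows, with the residual
variance estimated from the fit at the sample points using the standard
approximate degrees of freedom `n − 2 tr(L) + tr(LLᵀ)`; the 95% band is
`fit ± t · se`. `log_age=True` fits on the log-age axis, appropriate for
lifespan data whose dynamics concentrate early, while reporting the grid
in years. The smoother is implemented here because the fits require both
local-quadratic degree and analytic pointwise bands.

`pair_correlations` measures protein–gene coupling on six lifespan age
bins (<1, 1–5, 5–12, 12–20, 20–55, >55 years; right-open at the printed
boundaries): each feature is z-scored within its dataset, samples are
binned, and each pair is correlated across the six bin means. The summary
reports mean and median pair correlation with a percentile-bootstrap 95%
CI of the median (10,000 resamples). Every bin must be populated in both
datasets; the error names the offending bin.

`probe_to_gene` collapses exon-array probes to genes: multi-probe genes
whose probes all pairwise correlate at `r >= 0.9` are averaged; genes
failing the rule keep their highest-variance probe by default
(`on_fail="max_variance"`), or retain every probe tagged `gene|probe`
(`on_fail="keep_all"`). The pairwise reading of the correlation rule is a
documented convention.

## Synthetic lifespan data

The generator emulates the statistical shape of postmortem developmental
panels so that every pipeline stage can be tested against known truth.

* **Ages**: log-uniform on (0.05, 80) years, allocated evenly across the
  stage intervals so every planted stage is populated (postmortem banks
  oversample early life; log-uniform reproduces that density).
  `bin_stratified_ages` instead allocates across the six lifespan age
  bins, guaranteeing the populated bins the pair-correlation procedure
  requires. Caller-supplied ages are accepted for fixed sampling designs.
* **Stages**: planted by a piecewise-constant shift at boundaries equally
  spaced on the log-age axis (human developmental stages occupy roughly
  geometric age intervals). Informative feature `j` of subject `i` is
  `baseline + A_j [(1 − w) g_j(t_i) + w g_j(t_center(stage_i))] + noise`
  with `t` the log-age fraction, `g_j` the trajectory shape (monotone
  increase/decrease, inverted-U with configurable peak age, undulating
  with configurable period, or flat), and `w = 0.85` the share of the
  dynamic range carried by the stage shift. Monotone shapes therefore stay
  strictly monotone in age at zero noise while the stage structure defines
  a well-posed "true k".
* **Defaults**: 31 subjects, 6 stages, 5 informative features (one rising,
  one falling, inverted-U peaking at 2 and at 18 years, one undulating)
  plus 45 noise features; baseline 4, amplitude 8 (≈3-fold developmental
  change, typical of synaptic proteins quantified by Western blot), noise
  SD 0.5 (≈10% CV at adult expression levels). Presets `small7`, `full23`
  and `wide95` mirror 7-, 23- and 95-feature panel sizes; `small7` carries
  three replicate runs per subject.
* **Outliers**: flagged subjects receive ±6-SD shifts on a random quarter
  of the features (at least three), mimicking failed runs or mislabelled
  samples.
* **Paired omics** (`generate_paired_omics`): for a target coupling `r`,
  each paired feature is `r·s + sqrt(1 − r²)·u` where `s` is the base
  feature's noiseless trajectory and `u` an independent smooth random
  trajectory (sum of three random sinusoids of log-age), both standardised
  on their age-bin means — the scale on which the coupling is measured.
  Noise must live at the trajectory level: i.i.d. sample noise would
  average out in the bin means and bias the recovered correlation upward.
  With any measurement noise present the attainable bin-mean correlation
  is strictly below 1, so exact `r = 1` recovery requires the noiseless,
  shared-subject configuration.

What the generator does **not** emulate: heteroscedastic measurement error
across the dynamic range, batch effects between runs, correlated noise
among functionally related proteins, missing values, or the heavy-tailed
biological variance of real postmortem material. Tests passing on this
generator demonstrate that the pipeline recovers the structure it is
designed to detect under clean planted conditions; they do not certify
performance on real data with those additional artefacts.

## Problem sizes used in the shipped experiments

The recovery experiments run 50 generator seeds with elbow search over
k = 2–9 at 3 clustering repetitions per k and 5 restarts per repetition;
the robustness experiments run 20 seeds with three planted outliers; the
permutation null uses 39 iterations (minimal attainable p = 0.025); ORA
calibration uses 100,000 draws; pair-correlation round-trips use 60
subjects × 30 features. These sizes make the full suite and the
acceptance script each complete in a few minutes while leaving the
Monte-Carlo error of every rate well below its acceptance margin.

## Known limitations

* The alternation optimises a non-convex objective; all guarantees are
  empirical (restart-based) rather than global.
* WWSS-based k selection assumes the planted/true clusters dominate a
  common metric; overlapping stage structures with feature-specific
  cluster supports would defeat the pooled-support construction.
* The ORA null is Gaussian by construction; heavy-tailed expression
  distributions will inflate over/under calls.
* Trimming assumes outliers are a small minority (`alpha < 0.5`); gross
  contamination breaks the trimmed scale estimates as well.
* The paired-omics generator couples trajectories feature-by-feature; it
  does not model shared latent regulation across features.
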