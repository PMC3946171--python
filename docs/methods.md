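# Methods

This note documents the models and procedures implemented in `histocyto`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

Quantifying the biology of tumor endothelial cells (EC) in immunostained
histopathology requires three steps: find every nucleus in a field,
decide which cells are EC, and measure marker (analyte) expression in the
cells of each class. EC are rare, pleiomorphic, and scattered through
disorganized tissue, so a classifier trained on examples picked freely by a
human tends to inherit the human's selection bias. The package's central
algorithm instead has the classifier itself choose which cells the expert
should label next.

## Active learning for sparse logistic regression

**Model.** Binary logistic regression over per-cell features with labels
y ∈ {−1, +1} (+1 = EC): P(y = +1 | x) = σ(βᵀx), σ(z) = 1/(1+e⁻ᶻ), with a
leading intercept column of ones in the design. The log-likelihood of a
labeled set is Σᵢ ln σ(yᵢ βᵀxᵢ).

**Sparsity.** An L1 penalty λ‖β₋₀‖₁ on the non-intercept coefficients makes
irrelevant features go to (nearly) zero, performing feature selection inside
training. The non-differentiable |b| is smoothed as √(b² + ε_s) with
ε_s = 10⁻⁶ ("eps-L1"); the smooth penalized likelihood is maximized by
L-BFGS (max 500 iterations, gradient tolerance 10⁻⁸). The intercept is
never penalized — shrinking it would bias the predicted class prevalence.
Features are z-scored with unlabeled-pool statistics before training so the
penalty acts on comparable scales; constant features are dropped with a
warning.

**Penalty schedule.** λ = `lam_scale`·√n_labeled with `lam_scale` = 1 by
default. The score a truly uninformative standardized feature accumulates in
the likelihood gradient grows like √n (a random walk of per-cell
contributions with variance ≈ p(1−p) ≤ ¼), so a √n penalty keeps the
soft-threshold at a constant number of noise standard deviations as labels
accrue: noise features stay suppressed at every budget while genuinely
informative features, whose gradient grows like n, escape the threshold
early. A penalty linear in n would eventually swamp the signal; a constant
penalty would eventually admit noise.

**Query selection.** The Fisher information matrix of the logistic model is
I(β) = Σᵢ wᵢ xᵢxᵢᵀ with wᵢ = σ(βᵀxᵢ)(1 − σ(βᵀxᵢ)). Its inverse lower-bounds
the covariance of the coefficient estimate, so choosing the unlabeled cell
that maximizes det(I + w(x)·xxᵀ) (D-optimal sequential design) shrinks
parameter uncertainty fastest. By the matrix determinant lemma this argmax
equals the argmax of the score w(x)·xᵀI⁻¹x, which is what the implementation
ranks — one linear solve per iteration instead of one determinant per
candidate. The acceptance suite verifies the equivalence against brute-force
determinant evaluation. Ties are broken toward the smallest cell id.
Batches larger than one are selected greedily, updating I with each pick's
expected (label-free) contribution before re-scoring.

**Regularization of I.** Before any cell is labeled, I is singular. A ridge
ε·D with D = identity and ε = 10⁻⁹ keeps the matrix positive definite and
its log-determinant finite at every iteration. The identity was chosen for D
because nothing in the problem distinguishes coordinate directions after
standardization; the constant is config-exposed (`fim_eps`).

**Convergence.** The information gain ln det(I + εD) is recorded after every
refit. The run stops when the relative increase
(G_t − G_{t−1})/max(|G_{t−1}|, 1) stays below `plateau_tol` = 10⁻³ for
`plateau_patience` = 5 consecutive iterations, or after `max_iterations`
(default 50) queries. On the synthetic benchmark the gain typically still
grows at iteration 50, so the iteration cap is the binding constraint there.

**Initialization.** One example per class (configurable), found by scanning
cell ids in a seeded random order and keeping the first of each class;
labels obtained for surplus scanned cells are discarded so the initial set
is exactly class-balanced. With a deterministic oracle the whole run —
query sequence, coefficients, final classification — is a pure function of
the seed, which the reproducibility tests assert.

**Prediction.** p = σ(βᵀx) after applying the stored standardization; a cell
is called EC iff p > 0.5 (strictly, so the boundary case is negative).

## Comparator pipelines

The benchmark harness replays, over independent replicates, four
alternatives at the same labeling budget: logistic regression on uniformly
random labels with no feature selection, and logistic regression after
offline selection of k = 5 features by (a) PCA projection (top principal
components), (b) per-feature Welch t-tests (smallest p-values), or (c)
greedy MRMR in the MID form — relevance MI(f; y) minus mean redundancy
MI(f; s) over already-selected s, with features discretized into 3 bins at
μ ± σ. Offline selection uses the full labeled design by default (a flag
switches to selecting on each replicate's sampled budget). Accuracy at each
step is the fraction correct over all cells outside the training set;
curves report mean ± SEM over replicates. Welch rather than pooled t-tests
because the two classes have no reason to share a variance; k = 5 matches
the number of top features the training UI reports.

## Nuclear segmentation

1. **Thresholding.** Pixel intensities are modeled as a two-component
   mixture of Poisson distributions (dark background, bright nuclei). Every
   candidate gray-level split T is scored by the total negative
   log-likelihood of the mixture with plug-in priors and means; the argmin
   is the threshold (smallest T on ties). Two components were chosen for
   identifiability on the synthetic images; the fit is exhaustive, not
   iterative, so it cannot converge to a local optimum.
2. **Refinement.** Either morphological (hole filling, then opening by
   reconstruction, which removes specks without nibbling the corners of
   surviving components) or a graph-cut binary MRF whose data terms are the
   per-class Poisson negative log-likelihoods and whose pairwise term is a
   Potts penalty (`smoothness`, default 2). The MRF is solved exactly by
   max-flow (`scipy.sparse.csgraph.maximum_flow` on capacities scaled by
   100 and rounded; the foreground is the source side of the min cut,
   recovered by BFS on the residual graph). With `smoothness` = 0 the MRF
   reduces exactly to the per-pixel likelihood-ratio mask.
3. **Seeds.** Scale-normalized Laplacian-of-Gaussian responses are computed
   on a 6-step geometric sigma ladder between `scale_min` = 3 px and
   `scale_max` = 10 px (a nucleus of radius r responds most strongly near
   σ ≈ r/√2; the defaults bracket radii ~4–14 px, matching the generator's
   7 ± 1 px). The image mean is subtracted first because the truncated
   kernel leaves a response residue proportional to the DC offset. Local
   maxima of the across-scale maximum inside the mask are pruned greedily in
   descending response order with minimum separation equal to the stronger
   seed's detected scale.
4. **Clustering.** Mask pixels are partitioned among seeds by ascent on the
   LoG response, implemented as a marker-based watershed of the inverted
   response (the catchment basin of a marker is exactly the steepest-ascent
   cell).
5. **Size filter.** Fragments outside [`min_size`, `max_size`] =
   [20, 2000] px are discarded before merging.
6. **Merging.** Adjacent fragments (4-connectivity) are merged whenever the
   union scores as more nucleus-like than either fragment. The score is
   `merge_alpha`·(log-normal size-prior log-density, normalized to 0 at the
   prior-mean area; prior mean defaults to the median fragment area, spread
   0.6 log units) + (1 − `merge_alpha`)·(region area / area of the
   moments-equivalent ellipse, capped at 1). The ellipse term penalizes
   dumbbell-shaped unions of two real nuclei; the size term penalizes
   fragments. Because a merge requires a strict improvement over the max of
   the pair, the minimum score in the map never decreases and the procedure
   is idempotent. This surrogate score replaces a trained model of
   well-segmented nuclei; it is a deliberate, transparent simplification.

The whole module is deterministic — there is no randomness at any stage,
and all tie-breaks are fixed (gray level, row-major position, smallest id).

## Per-cell features

Intrinsic features of the nuclear channel: area, perimeter, elongation
(major/minor axis ratio of the moments-equivalent ellipse, i.e. the square
root of the second-central-moment eigenvalue ratio), eccentricity,
convexity (area / convex-hull area), mean/total/variance of intensity, and
gradient energy (mean squared gradient magnitude inside the nucleus) as a
chromatin-texture surrogate. Associative features of every other channel:
mean and total intensity inside the nucleus and the mean in a ring obtained
by dilating the nucleus `ring_width` = 2 px and excluding all nucleus
pixels — so a neighbor's pixels are never counted in a cell's surround. The
CD34 surround is the feature that distinguishes EC, whose marker stains the
vessel wall around the nucleus rather than the nucleus itself.

## Analyte quantification

Background DAB staining varies between tumors and between regions of one
tumor, so each analyte channel is corrected by subtracting the mean
intensity over extranuclear pixels (all nuclei dilated by 2 px are excluded
from the estimate to avoid perinuclear bleed), clamping at zero. On an image
with no spurious background the estimate is near zero and the channel is
essentially unchanged. Expression is the mean corrected intensity in the
configured compartment: the nucleus itself for nuclear analytes (Ki67,
p-STAT3), or the nucleus dilated by 2 px (0.5 µm at 400X) for analytes that
also occupy the cytoplasm (p-ERK), with contested dilation pixels claimed
by the nearest nucleus. The mean rather than the sum is used so the
positivity threshold has intensity units independent of nucleus size; a
cell is analyte-positive iff its value strictly exceeds the threshold.
Summaries report, per image, the EC fraction of all cells and the
analyte-positive fraction among EC (missing, not zero, when an image has no
EC), and per tumor the median and 25th/75th percentiles of the per-image
fractions.

## Agreement evaluation

Sensitivity, specificity, PPV and NPV are the standard confusion ratios
with EC as the positive class; zero denominators give missing values.
Cohen's κ = (P_o − P_e)/(1 − P_e) with P_e computed from the two raters'
marginal positive rates; two constant, identical raters have P_e = 1 and κ
is reported missing rather than 1. Agreement partitions count, over the
cells called positive by at least one rater, how many raters called each
positive. Interval estimates use a cluster percentile bootstrap (default
2000 resamples) that resamples whole images with replacement, respecting
the correlation between nuclei from the same image; resamples on which a
metric is undefined are redrawn with a warning. A model-based clustered
variance estimator would need distributional assumptions the data do not
obviously support; the bootstrap is assumption-light and transparent.

## Synthetic data: what it emulates and what it does not

**Tabular generator.** Two-class Gaussian features: informative features
have class means separated by `effect_size` within-class standard
deviations; noise features are identically distributed in both classes;
every cell belongs to one of `n_clusters` image groups that share an
additive mean shift drawn once per cluster from N(0, `cluster_sd`²),
emulating between-image staining and illumination variability. Defaults —
1000 cells, 4 informative + 40 noise features, effect size 2, EC fraction
0.25, 5 clusters, shift scale 0.25 — define the standard benchmark used
throughout the tests.

**Image generator.** Non-overlapping elliptical nuclei (radius 7 ± 1 px,
20 per 256×256 field) on a dim background; EC nuclei (exactly
round(`ec_fraction`·n), default 25%) have major/minor axis ratio 2.5 at
preserved area and carry a bright 2 px CD34 ring (200 gray levels) just
outside their boundary; the analyte channel is bright (150) inside
analyte-positive nuclei, and spurious background adds uniformly across the
whole field, inside nuclei as well as outside — which is what makes a
global background estimate subtractable. Poisson noise is applied to the
rendered mean image (matching the segmentation model); Gaussian (σ = 5) and
noise-free renderings are available. All rounding of fractional counts is
half-up, so example counts are exact.

**Not emulated:** chromatic DAB/hematoxylin overlap and spectral unmixing
artifacts, touching and overlapping nuclei, out-of-focus blur, tissue
architecture, and the full diversity of real EC morphology. Passing the
end-to-end tests therefore shows the pipeline is correct and internally
consistent under its own model assumptions, not that it attains the same
operating characteristics on patient material.

**Simulated oracle.** Answers label queries from ground truth, optionally
flipping each answer independently with a configurable probability to model
rater inconsistency; flips are memoized so repeated queries are answered
consistently within a session.

## Problem sizes used by the tests and the reproduction script

The reproduction script and the end-to-end acceptance test use 20 images of
20 nuclei (≈400 cells) with up to 50 active-learning queries; the
learning-curve comparison uses 25 replicates at a 50-label budget on the
1000-cell tabular benchmark. These sizes give stable averages while keeping
a full run in minutes on one core.

## Known limitations

- The merge score is a fixed surrogate, not trained on curated
  segmentations; heavily clumped nuclei will be under-split.
- The two-component Poisson mixture assumes a single foreground intensity
  population; strongly bimodal nuclear staining would need a third
  component.
- λ = √n is a schedule, not a tuned value; for feature sets whose
  informative effects are much weaker than the benchmark's, `lam_scale`
  should be lowered.
- Cohen's κ is implemented for binary ratings only; weighted or multi-class
  agreement is out of scope.
- The cluster bootstrap gives percentile intervals only; no bias
  correction or acceleration is applied.
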