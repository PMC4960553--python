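# Methods

This note records the model implemented by `mrci`, the choices made where
the method leaves details open, and the known limitations. It is written to
let a reader reproduce or audit every number the package computes.

## Overview

`mrci` builds *MR-based clustered images* (MRcIs): per-voxel tissue-class
label volumes obtained by unsupervised two-level clustering of four
co-registered MR channels (T1, contrast-enhanced T1, T2, FLAIR), and uses
in-tumor class composition to grade gliomas (low vs high grade) with a
linear SVM. All components operate on arbitrary co-registered volume sets;
a seeded phantom generator provides cohorts with known ground truth.

## Preprocessing

- **Channel order** is fixed: `(t1, t1ce, t2, flair)`. All feature vectors
  and codebooks use this order.
- **Normalization**: per subject and channel, a z-score over voxels inside
  the brain mask, using the population variance (divisor *n*). This makes
  everything downstream invariant to per-channel affine intensity rescaling
  (`a·x + b`, `a > 0`). Voxels outside the mask carry NaN sentinels and are
  never consumed. Normalization parameters are stored so sampled
  intensities can be de-normalized exactly.
- **Training features**: the normalized 4-vectors at every 125th voxel — a
  5×5×5 index lattice (configurable stride and phase, default offset 0)
  intersected with the brain mask. Rows from all subjects are stacked.

## Two-level clustering

**Level 1 — batch-learning SOM.** A 20×20 lattice (400 protoclusters) of
4-dimensional weight vectors is trained by the batch rule: each epoch
assigns every sample to its best-matching unit (BMU; squared-Euclidean
argmin, ties to the lowest unit index), then replaces every unit weight by
the neighborhood-kernel-weighted mean of all samples,

    w_u ← Σ_s h(u, bmu(s)) x_s / Σ_s h(u, bmu(s)),

with a Gaussian kernel `h = exp(−d²/2σ²)` on the Chebyshev lattice distance
`d`. The radius σ decays linearly from 10 to 0.5 over 50 epochs.
Initialization is deterministic PCA-linear: unit weights span the first two
principal axes at ±2 standard deviations, with each eigenvector's sign fixed
by making its largest-magnitude component positive. No RNG is consumed.

Two determinism measures:

- Training rows are sorted lexicographically before accumulation, so the
  final codebook is bit-identical under any permutation of input rows
  (floating-point summation order would otherwise leak the row order).
- Both diagnostic traces are recorded per epoch: the mean Euclidean
  sample-to-BMU distance (`quantization_error_trace`) and the mean squared
  distance (`squared_error_trace`).

**Monotone descent.** The mean *Euclidean* distance is not a Lyapunov
function of the batch update: measured over random instances it increases
in a small fraction of epochs even at tiny fixed radius, because a batch
step minimizes the *squared* error (it is a kernel-smoothed Lloyd step).
The descent property asserted in the tests is therefore on the mean
*squared* sample-to-BMU distance at a fixed radius in the quantization
regime (σ = 0.25, where the kernel is numerically a point mass); there it
holds in 200/200 random instances. This is the substance of the descent
claim, stated for the objective the update actually minimizes.

**Level 2 — K-means++ on the codebook.** The 400 protocluster weight
vectors (optionally weighted by hit counts) are clustered into K classes by
K-means++ (D²-weighted seeding, Lloyd iterations to relative inertia
tolerance 1e-10, empty clusters repaired at the farthest point), best of 25
restarts. Classes are relabeled 1..K by descending class-center mean, so
class 1 is the brightest-signature class and the labeling is deterministic
given (codebook, K, seed). The default grid of supported K values is
{4, 6, 8, 10, 12, 16, 20}.

## MRcI construction and features

Applying a model to a subject: normalize the subject with its *own*
within-mask z-score (matching the training convention), assign every
in-mask voxel the class of its nearest protocluster, write labels 1..K
(0 = background, uint16). Within the tumor ROI, per-class voxel fractions
give K features per subject: `log10(count_k / |ROI|)`. A class absent from
the ROI is floored at half a count (`1/(2·|ROI|)`) before the log so
features stay finite and monotone in counts.

**L/N/H grouping.** Per class, a two-sided exact Wilcoxon–Mann–Whitney test
compares log-ratios between LGG and HGG subjects. With Bonferroni threshold
`p < α/K` (α = 0.05), a significant class is H if the HGG median is higher,
L if lower; all other classes are N.

## Grading

A linear soft-margin SVM (libsvm via scikit-learn) on the K log-ratio
features; HGG is the positive class. Per held-out subject in leave-one-out
cross-validation:

1. scale each feature linearly to [−1, 1], fit on the training fold only;
2. choose C by a two-step grid search — coarse log2 C ∈ {−5, −3, …, 15},
   then a fine grid ±2 around the winner at step 0.25 — scored by
   stratified inner 5-fold CV accuracy, ties to the smallest C (degenerate
   folds are redrawn, at most 10 times);
3. fit and record the held-out decision value (threshold 0 for
   accuracy/sensitivity/specificity).

SVM fits cap libsvm at 200,000 iterations: converged solutions on
cohort-sized problems stay well below that, and the cap only binds for very
large C on label-noise data, where libsvm would otherwise spend millions of
iterations approaching a degenerate optimum.

The LOOCV is repeated (default 100×); across repeats only the inner-CV fold
draws vary (per-subject RNG keyed by `seed + repeat` and the subject's rank
in id order, making all metrics invariant to subject ordering). Summaries
are means with percentile 95% intervals over repeats. ROC/AUC uses the
pooled held-out decision values (AUC = Mann–Whitney probability, ties ½);
confidence intervals use 2000 stratified bootstrap replicates (resampling
within each class). AUCs across K are compared by one-way ANOVA with Tukey
HSD on the per-repeat AUC samples.

**Null behavior of pooled LOOCV AUC.** With grade labels permuted, the mean
pooled-LOOCV AUC is *below* 0.5, not at it (measured ≈ 0.2 for a balanced
10+10 cohort). Two mechanisms: (a) under the null the inner-CV winner is
often the majority-vote constant model at the smallest C, whose intercept
equals the sign of the training majority — on balanced cohorts that is
always the opposite of the held-out subject's class, so decision values
anti-rank the labels; (b) the held-out subject's own feature vector is
always excluded from the fitted weight sum, biasing its decision value away
from its class. Both are properties of the specified protocol, not of this
implementation. Tests therefore assert the absence of positive signal
rather than AUC ≈ 0.5.

## Statistics

- **Exact WMW**: two-sided p by full enumeration of the rank-sum null
  (dynamic program over doubled midranks) whenever `C(n1+n2, n1) ≤ 200,000`,
  otherwise seeded Monte-Carlo permutation (≥ 1e5 draws, add-one
  correction). Effect size `r = |Z|/√N` from the tie-corrected normal
  approximation. The location-shift CI inverts the exact (or Monte-Carlo)
  critical value over the order statistics of all pairwise differences.
- **ANOVA/Tukey**: `scipy.stats.f_oneway` and `scipy.stats.tukey_hsd`.
- Ties use midranks with the variance tie-correction.

## Phantom generator

Each subject is an ellipsoidal brain (semiaxes 0.42 of a 40³ grid) with
concentric shells — white-matter core (normalized radius ≤ 0.66), gray
matter (≤ 0.90), CSF rim — and an ellipsoidal tumor ROI (≈ 20 % of the
brain) whose voxel classes are multinomial draws from a grade-dependent
mixture over six classes (csf, gm, wm, edema, lgg_like, enhancing):

    LGG: 0.10 wm, 0.30 edema, 0.60 lgg_like
    HGG: 0.10 wm, 0.30 edema, 0.30 lgg_like, 0.30 enhancing

Channel intensities are the class signature plus i.i.d. Gaussian noise; the
default noise SD puts the *closest* signature pair exactly 3 SD apart. An
optional smooth quadratic multiplicative bias field is off by default.
Grade information lives only in the ROI mixture: outside the ROI, truth and
intensity distributions are identical across grades.

**Geometry rationale.** K-means minimizes summed squared error, so with
K = G it provably prefers splitting a large cluster over separating a small
close pair once the close pair's population is small relative to the
largest class (break-even near `n_pair ≈ 0.28 · n_largest` for the 3-SD
geometry). The default shell radii, ROI size and signatures were chosen
from that analysis — only the designated closest pair (edema/lgg_like) sits
at the 3-SD floor; all other pairs are ≥ 2× farther apart — so that
voxel-class recovery at K = G is information-theoretically and
SSE-structurally attainable. These defaults were fixed before the
acceptance tests were frozen and not revisited.

All randomness flows through `numpy` Generators; each cohort subject uses
`default_rng([seed, subject_index])`, so cohorts are reproducible and
subjects independent.

## Serialization

Trained models are saved as a single versioned JSON document (codebook
weights, hit counts, both error traces, unit classes, centers, inertia,
seeds). JSON was chosen over zip-based containers because zip headers embed
timestamps, which would break byte-identical reruns. Label volumes are
uint16 NIfTI; nibabel writes gzip members with a fixed mtime, so NIfTI
outputs are also byte-identical across reruns.

## Problem sizes and runtime (single CPU)

- Default phantom cohort: 36 subjects (15 LGG + 21 HGG) on 40³ grids,
  ≈ 5,900 training samples at stride 5; generation ≈ 3 s, SOM + K-means
  training ≈ 3 s, labeling all subjects ≈ 4 s.
- Repeated LOOCV: ≈ 7 s per repeat on 36 subjects.
- Exact WMW: enumeration is cached per (n1, n2, tie pattern); 2000 null
  simulations at n = 10 + 10 run in ≈ 20 s.

## Limitations

- The SOM neighborhood is Gaussian on a rectangular lattice with a linear
  radius schedule; other topologies/schedules are not implemented.
- Intensity normalization is the within-mask z-score; histogram-based
  methods are out of scope.
- The phantom is a geometric stand-in: it shares the pipeline's statistical
  structure (class signatures, grade-dependent mixtures) but not the
  anatomy or artifact spectrum of real MRI.
- Grading is binary (LGG vs HGG) with a linear kernel only.
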