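# Methods

## The model

`idsim` quantifies which individual-difference factors drive inter-subject
(dis)similarity of neural response patterns to persuasive messages. The unit of
analysis is the unordered subject pair: with *n* subjects there are
*m* = *n*(*n*−1)/2 pairs, indexed lexicographically.

For each region of interest (ROI) the regressand is the Euclidean distance
between the two subjects' activity patterns in that ROI's mask, taken from each
subject's contrast statistical parametric map (SPM). Masks are Manhattan
(L1) balls of radius 2 voxels around a peak coordinate — exactly 25 voxels; the
general ball size is (2r+1)(2r²+2r+3)/3. Peaks are given in MNI mm and mapped
to voxel indices through an explicit affine (ties round half away from zero).
A mask that leaves the grid is an error, never clipped: clipping would change
pattern dimensionality between datasets.

The explanatory similarity vectors are, per pair:

- **Neural controls.** `wbFxnSim`: Euclidean distances between whole-brain
  vectors of the contrast map, the structural (gray-matter probability)
  segmentation, and the two control-condition maps (scrambled video, blank
  screen). `ROIneur`: the same three control distances restricted to the ROI's
  mask. Whole-brain structural/control similarity is grouped with `wbFxnSim`;
  the grouping is configurable because reasonable alternatives exist.
- **Intrinsic traits.** Marijuana-use risk, sensation seeking, compliance:
  each scale is scored as the arithmetic mean of its Likert items, and pair
  similarity is |scoreᵢ − scoreⱼ|. The mean (rather than sum) summary is
  inert downstream because unique-variance credit is invariant to affine
  transforms of a regressor.
- **Message (PSA) ratings.** For each of pMSV, pAS, AdLike, pos, neg and
  thought valence, subjects have a per-video profile (32 videos by default).
  Each contributes three pair vectors: the Pearson correlation of the two
  profiles (entered as 1−r so every regressor reads as a dissimilarity),
  |Δ profile mean| and |Δ profile sd| (sd with the n−1 denominator). pos/neg
  average 3 positive and 7 negative of the 14 emotion items; the remaining 4
  items are carried but unused. Thought valence is the stay-away minus
  want-try difference of two 7-point items; the sign convention is inert for
  |Δ| similarity.
- **Subject intercepts** (`subints`): one 0/1 column per subject, two ones per
  row. Their unique variance is the individual-difference variance that is
  explainable in principle but unexplained by the measured variables.

Missing responses are imputed per question (per measure × item × video cell,
across subjects) with the mean of the non-missing responses — this preserves
that question's mean exactly and matches a completely-at-random missingness
model. An all-missing question is an error.

## Estimation: round-robin ΔR²

All member columns plus a global intercept and the subject-intercept block are
stacked into one OLS design (member columns are z-scored for coefficient
readability; this does not affect any R²-based quantity). The design is rank
deficient by construction — the subint block row-sums are the constant 2 — so
fits use minimum-norm least squares; R² depends only on the column space, so
this is inert.

Credit per named group *g* is the unique variance

  ΔR²_g = R²_full − R²_(full − g)  ≥ 0 (nested models),

and the **shared variance** is R²_full − Σ_g ΔR²_g — the variance explained
only by the covariance among predictors. Negative shared variance
(suppression) is reported with a warning, never clamped. The per-ROI identity
Σ ΔR² + shared + residual = 1 holds to 1e−10 and is asserted in tests.
Floating-point negative ΔR² (below ~1e−15) is floored at zero; a genuinely
negative value cannot occur for nested fits.

Category summaries (neural / intrinsic / psa, plus shared, unexplained and
residual carried as-is) sum each ROI's group ΔR² within category and then
average over ROIs within each source bucket (a priori, exploratory,
confirmatory), without shrinkage.

## Inference: subject-level permutation p*

Pair-level similarities are dyadically dependent — each subject contributes
n−1 pairs to every vector — so row-wise permutation of pairs is invalid. The
null implemented here relabels the **focal group's underlying subjects**: a
random permutation is applied to the group's subject-level data and the
group's pair columns are recomputed from the relabeled data (all member
vectors of a group share one permutation, preserving their mutual
dependence). Because every similarity used depends only on the unordered pair
of subject data, this recomputation equals reindexing the symmetric pair
matrix, which is how it is implemented (and verified against direct
recomputation in tests). All other columns and the response stay fixed; the
focal ΔR² is recomputed per draw via projection onto the fixed columns'
orthogonal complement, so each draw costs one small least-squares solve.

The one-tailed pseudo p-value is p* = (1 + #{ΔR²_null ≥ ΔR²_obs}) / (B+1),
with B = 999 by default (B ≥ 19 enforced); under exchangeability the test is
exact at levels k/(B+1). p* is uncorrected by design: it is used for
dimensionality reduction, not confirmatory inference. The probit transform
z = Φ⁻¹(1−p*) (p* clipped to [1/(B+1), 1−1/(B+1)]) is the clustering feature.

Two deliberate boundaries: the subject-intercept group gets no p* (permuting
its columns leaves their span invariant, so the null is degenerate), and a
subject bootstrap mode (resample subjects with replacement, drop self-pairs,
refit on surviving rows) is provided for sensitivity analysis only — the
permutation scheme is the default because it is the simplest resampling that
honors the n−1-pairs-per-subject constraint.

## ROI profiling

ROIs are clustered on their z profiles (one z per regressor group) by
agglomerative Ward clustering on Euclidean distances. K defaults to the
silhouette-maximizing value in 2..min(10, n−1), ties toward smaller K, with an
explicit override (e.g. K=6). Cluster labels are renumbered in order of first
appearance so output is deterministic; the partition is invariant to ROI row
order up to relabeling.

Cluster-level ΔR² profiles are summarized per variable with a normal–normal
MAP estimate under a zero-centered prior:

  MAP = x̄ · n·τ² / (n·τ² + σ²),

so |MAP| ≤ |x̄| always, larger and more homogeneous clusters shrink less, and
MAP → x̄ as τ² → ∞. Default hyperparameters per variable are moment
estimates: σ² pools the within-cluster variance; τ² is the variance of the raw
cluster means minus its sampling part σ²·mean(1/n_k), floored at 0. With a
single cluster there is no between-cluster information and the prior is left
flat (no shrinkage). The binding contracts are the qualitative ones (shrink
toward zero, monotone in cluster size/homogeneity); the specific normal–normal
operationalization is this package's concrete choice.

A strength-of-evidence table lists, per ROI, the groups with p* strictly below
a threshold (default 0.05), ordered by p*.

## Synthetic cohorts

The generator emulates the target study design: 28 subjects, 32 videos, the
packaged 23-ROI peak table on a 5 mm grid (36×44×36 voxels, origin
(−90, −126, −72) mm), 25-voxel masks, and a whole-brain field of 4000 voxels
(all ROI voxels plus a random in-grid sample). Defaults are fixed at those
values; smaller configurations are explicit choices in tests and examples.

Per subject, each of the nine latent variables is standard normal. Intrinsic
items are integer Likert responses `clip(round(mid + 0.8·u + ε))`, so scale
scores track the latent trait with realistic discretization noise. Ratings are
continuous Likert-bounded values `clip(center + a·u + video effect + ε)` with
per-measure loadings of 0.5–0.8, video effect sd 0.5 and item noise sd 0.7 —
values chosen once to give within-measure reliability in the range typical for
multi-item self-report, and to keep degenerate profiles (zero variance over
videos, which the pipeline correctly rejects) out of the generator's support.
Missingness is injected completely at random at rate 0.02 by default (the
imputation rule assumes MCAR).

An ROI's driver coupling is `pattern = template + γ·t·direction + ε` with one
unit signal direction per ROI and i.i.d. noise of sd σ, giving the closed-form
expected squared pair distance γ²(tᵢ−tⱼ)² + 2σ²V used as the generator's
validation oracle. γ for "trait explains fraction f of pattern variance" is
σ√(V·f/(1−f)); f = 0.5 (γ = 5 at σ = 1, V = 25) is the "strong signal" setting.
Whole-brain maps embed the ROI patterns at their peak locations inside the
noise field, so whole-brain similarity is genuinely correlated with ROI
similarity. Control-condition and structural maps share a template across
subjects but carry no trait coupling.

What the generator does **not** emulate: spatial autocorrelation and smoothness
of real SPMs, subject-level global amplitude differences, non-random
missingness, correlated latent traits, multi-component trait→pattern
couplings, and any temporal structure (generation is at the contrast-map
level). Passing tests therefore demonstrate the estimator's statistical
properties under the assumed structure, not robustness to those violations.

## Numerical choices and problem sizes

- Rank detection uses an SVD threshold of 1e−10 relative to the largest
  singular value; partition identities are asserted at 1e−10.
- mm→voxel rounding is half away from zero for determinism across platforms.
- The marijuana-risk scale's published item list is external to this package;
  scoring defaults to a 5-item 1–5 scale and is configurable via `ScaleDef`.
- Simulation-based checks use study-sized cohorts (n = 28, B = 199) on a
  compact 20³ grid with 2–4 ROIs and a 400-voxel whole-brain field: the
  calibration and recovery properties under test depend on the subject count
  and resampling depth, not on the ROI count, and the compact setting keeps
  replicate counts high (200 null replicates, 100 recovery replicates).
- Null calibration defines rejection as p* ≤ α, the exact-level event for a
  permutation p-value on the grid k/(B+1); the strength table uses the strict
  inequality that its evidence-listing convention implies.

## Known limitations

- The constrained resampling scheme is one concrete operationalization of
  subject-level dyadic inference; aligning exactly with any particular
  deposited analysis would require consulting that analysis code, and a
  disagreement would be reported, not hidden.
- p* values are uncorrected and intended for profiling; with ~11 groups × 23
  ROIs, a handful of sub-0.05 cells is expected under the global null.
- The MAP summary is a visualization aid, not a posterior inference; its
  hyperparameters are moment estimates, not marginal-likelihood optima.
- With fewer pairs than design columns (n ≤ ~9 at the default grouping) the
  full model saturates: R² = 1 and all explained variance is shared. The
  8-subject miniature cohort exists for fast smoke tests of plumbing, not for
  statistical checks.
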