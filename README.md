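# idsim

Similarity-based individual-differences analysis of neural response patterns
to persuasive messages.

Group-average fMRI analyses treat between-subject variability as noise. This
package treats it as signal: it asks **which individual-difference factors
make two people's brain responses to the same messages more or less alike**.
It is written for cognitive/communication neuroscientists running
region-of-interest (ROI) analyses of per-subject contrast maps alongside
trait questionnaires and per-message ratings — and for methodologists who
want the estimator's statistical properties to be testable without access to
any particular fMRI dataset (a synthetic-cohort generator is a first-class
part of the package).

## The statistic

For *n* subjects, every measure is converted to a vector over the
*m* = *n*(*n*−1)/2 unordered subject pairs:

- neural patterns → Euclidean distance ‖**p**ᵢ − **p**ⱼ‖ between the two
  subjects' activity patterns in a 25-voxel ROI mask (Manhattan-ball radius 2);
- univariate trait scores → |tᵢ − tⱼ|;
- per-video rating profiles → three components: Pearson r (entered as 1−r),
  |Δ profile mean|, |Δ profile sd|.

Each ROI's pattern-distance vector **d** is regressed on all explanatory
similarity vectors plus participant-specific intercepts. Credit is assigned
per group *g* of regressors by the round-robin unique variance

  ΔR²_g = R²_full − R²_(full−g),  shared = R²_full − Σ_g ΔR²_g,

so that Σ_g ΔR²_g + shared + residual = 1 for every ROI. Because each subject
contributes n−1 pairs to every vector, inference uses a subject-level
resampling null: the focal group's subject data are relabeled by a random
permutation, its pair columns recomputed, and the one-tailed pseudo p-value

  p\* = (1 + #{ΔR²_null ≥ ΔR²_obs}) / (B + 1)

is reported per ROI × group. ROIs are clustered on their probit-transformed
p\* profiles (Ward's criterion) and cluster-level ΔR² profiles are summarized
with MAP-shrunken means x̄·nτ²/(nτ²+σ²) under a zero-centered prior. See
`docs/methods.md` for the full model and its assumptions.

## Worked example

`examples/` contains one short script per capability. The variance partition
for a cohort in which sensation seeking is planted as the driver of one ROI
(`python examples/03_variance_partition.py`):

```
full-model R2 = 0.899  (378 pairs, driver = SSscore)
unique variance per regressor group (% of pattern-distance variance):
  subints      7.32%
  wbFxnSim     5.33%
  SSscore      5.18%
  AdLike       0.20%
  ...
  shared      71.46%   (explained only jointly)
  residual    10.09%
```

The planted driver (SSscore) dominates every non-control variable; `subints`
is subject-specific variance explainable only by unmeasured factors, and the
large shared component reflects that the whole-brain control similarity
carries the embedded ROI signal too. Permutation inference on a planted
thought-valence driver (`python examples/04_permutation_inference.py`):

```
group        dR2 %      p*      z   (B=499 subject permutations)
wbFxnSim      2.05   0.002   2.88
ThVal         9.28   0.002   2.88
pMSV          0.20   0.026   1.94
neg           0.13   0.070   1.48
...
```

Only the planted driver (and the whole-brain control, which genuinely carries
it) reaches small p\*; z = Φ⁻¹(1−p\*) is the feature ROIs are clustered on.

A full run — scoring, similarities, per-ROI partition, p\*, Ward clustering,
MAP profiles — is one call:

```python
from idsim import analyze_cohort, generate_cohort, miniature_config
report = analyze_cohort(generate_cohort(miniature_config(seed=11)), B=199, seed=2)
```

or, from the shell, over an on-disk dataset:

```bash
idsim simulate data/ --seed 3        # or bring your own NIfTI/TSV + CSV inputs
idsim validate data/
idsim run config.yaml                # writes delta_r2.csv, pstar.csv, clusters.csv, ...
idsim report results/                # SVG cluster-profile bars
```

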