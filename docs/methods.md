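# Methods

`dediff` implements a pattern-similarity analysis of age-related neural
dedifferentiation: searchlight maps of item- and category-level neural
distinctiveness, nonparametric cluster-mass inference on within- and
between-group contrasts, partial least squares correlation (PLSC) linking
distinctiveness to recognition memory, and trial-wise
distinctiveness–memory association. Because the pipeline is exercised on
synthetic cohorts with a known generative model, every stage can be
validated against closed forms or brute-force oracles.

## Study design emulated by the generator

A session has three scanned parts plus a recognition test:

* **TD1** (first target-detection): three object runs (320 objects split
  106/107/107 by default) followed by one scene run (60 scenes). Twenty
  objects and ten scenes are target-detection catch trials and are
  excluded from every similarity metric. Of the remaining objects, 250
  are paired with the 50 non-target scenes and 50 are baseline.
* **TD2**: the same 320 objects re-presented across three runs; scenes
  are not repeated.
* **Retrieval**: the 250 paired objects return on a matching (n=100),
  mismatching (n=100) or new (n=50) scene, intermixed with 150 new
  objects; participants judge item (old/new) and pair (old/new).

Run labels are globally unique (TD1: 1–4, TD2: 5–7, retrieval: 8), so the
cross-run restriction on similarity is a single integer comparison.
Pseudorandomization is a uniform shuffle under the design seed; no
first-order balancing constraints are imposed.

## Voxel signal model

For a trial showing stimulus *i* of category *c*, the beta at an
in-region voxel *v* is

    beta = sqrt(a_cat) * C_v(c) + sqrt(b_item) * I_v(i)
         + sqrt(1 - a_cat - b_item) * eps_v(trial)

with C, I, eps independent unit-variance Gaussians. Consequences used
throughout the tests:

* expected Pearson r between same-category, different-item trials is
  `a_cat`;
* expected r between two presentations of the same item is
  `a_cat + b_item` (times the stability parameter ρ on the item share if
  ρ < 1);
* object–scene correlations are 0 in expectation.

Voxels outside the signal region are pure noise. Group differences are
expressed as different (a_cat, b_item) per age group; optional truncated-
Gaussian jitter of these fractions across subjects (SD in
variance-fraction units, default 0.02 in the pipeline config) supplies
the between-person variance the brain–behavior analyses need. Because
components are unit-variance Gaussian per voxel, `tanh` of the mean
Fisher-z similarity is a consistent estimator of the shared-variance
fraction; the package recovers a_cat and b_item to ±0.03 at 5,000 voxels.

What the generator does **not** emulate: scanner drift and motion
artifacts, spatial autocorrelation of noise, hemodynamic variability
across regions, attentional fluctuations, and any representational
change induced by the object–scene association task. Passing tests
therefore validate the estimators' algebra and calibration, not their
robustness to those real-data nuisances.

### Memory model

Retrieval outcomes are Bernoulli with
`logit P(hit) = beta0 + beta1_item * d_item + beta1_cat * d_cat`, where
d are the subject's realized trial-wise distinctiveness values over the
signal region on their raw Fisher-z scale — so both within-subject trial
variation and between-subject differences (via the parameter jitter)
propagate into memory. New objects are correctly rejected with a fixed
specificity (default 0.85); the source study models only old-item
outcomes, so false alarms carry no signal here. Pair judgments reuse the
logistic with the category slope only — the pairing task is
scene-contextual and the generator needs a pair Pr column for PLSC; this
is a generator choice, not an estimator assumption. One caveat: the
generator ties distinctiveness levels together only through shared
anchor-trial noise, so the trial-wise item~category association in
pipeline output is near zero by construction; the two-stage estimator is
instead validated on directly simulated slopes (0.18) where the ground
truth is unambiguous.

## Trial-wise GLM (least-squares-single)

Each trial gets its own ordinary-least-squares model: a stick function at
stimulus onset convolved with the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, dispersions 1 s, ratio 1/6, 32 s support, unit-sum
kernel), one identical regressor pooling all other trials of the run, six
motion series, an indicator for the first three dummy volumes, and an
intercept. Design choices:

* sticks are impulses (duration 0), not boxcars;
* no HRF derivatives, prewhitening, or high-pass filtering — the
  synthetic data carry no drift or autocorrelation;
* the implicit mask keeps voxels whose mean signal exceeds 0.4 × the
  grand mean of voxel means (SPM-style); when the grand mean is not
  positive the mask is disabled rather than empty;
* rank-deficient designs fall back to the pseudo-inverse with a logged
  warning.

Noise-free data generated from a trial's own design are inverted to the
true coefficients within 1e-6, and recovery RMSE scales linearly with
injected noise SD.

## Searchlight similarity

Searchlights are exact lattice balls of radius 4 mm on the 2 mm grid (33
voxels), centered on in-mask voxels, truncated to in-mask neighbors;
centers with fewer than `min_voxels` (default 5) usable neighbors are
invalid. Similarity is the Fisher z (atanh) of the Pearson correlation
across searchlight voxels, computed per pair and then averaged; r is
clipped at 1 − 1e-7 so identical synthetic patterns stay finite.
Similarity is only assessed between trials from different runs.

* **Item level** (cross-phase): within-item = mean z between an object's
  TD1 and TD2 patterns; between-item = mean z over all TD1×TD2 object
  pairs excluding the same-object pairs. TD1×TD1 and TD2×TD2 object
  pairs are not used at this level.
* **Category level** (TD1 only): within-category = mean z over
  object–object pairs from different runs; between-category = mean z over
  all object–scene pairs.
* Distinctiveness is the within-minus-between difference at each level.

Missing voxels are dropped per pair (pairwise-complete deletion); a trial
missing more than half of a searchlight invalidates that searchlight for
that trial. Group analyses use only voxels valid in every subject.
Trial-wise extraction treats a back-projected cluster mask as one pattern
(no sub-searchlights). On instances small enough to enumerate, every map
value equals an independent O(n²) double-loop implementation to 1e-12.

The scene-pairing control contrast — (within-scene − between-scene)
object-pair similarity per phase, TD2 minus TD1 — is exactly zero in
expectation under the generator, which ties nothing to the pairing; its
variants restrict to correct-pair objects or to strong-memory scenes
(3–5 of a scene's pairs remembered vs 0–2).

## Cluster-mass permutation inference

Voxelwise t maps (dependent: one-sample on paired differences;
independent: pooled-variance two-sample — the classic neuroimaging
choice, Welch not used) are thresholded at two-sided p < 0.005 (0.01 for
control contrasts) and grouped into sign-separated 26-connected
components; the cluster statistic is the sum of member t values. The
Monte-Carlo null records, per permutation (condition swaps / sign flips
for dependent designs, size-preserving label shuffles for independent),
the maximum |mass| over both signs — the max-statistic convention that
controls family-wise error across clusters. p uses the add-one
convention (1 + #{null ≥ |mass|})/(n_perm + 1); a cluster is reported
significant when p < 0.05 and it has ≥ 10 voxels. The size rule is
applied at reporting, not inside the null, and is configurable.
Zero-variance voxels are invalidated with a logged count.

With 500 permutations and 200 replicate null cohorts on a 12³ grid, the
empirical family-wise error sits inside the binomial 95% band around
0.05 (the calibration run counts significance by Monte-Carlo p alone;
adding the 10-voxel filter would only push the rate down). With a
category-share difference of 0.10 vs 0.05 between groups of 20, a
significant category-level cluster overlapping the signal region is
detected in ≥ 80% of seeded replicates.

## PLSC

The n×3 neural block (cluster-wise distinctiveness) and n×2 behavior
block (item and pair Pr) are z-scored columnwise (optionally within age
group) and their 3×2 Pearson correlation matrix is decomposed by SVD.
Only the first latent variable is tested: a permutation test shuffles Y
rows relative to X (10,000 by default) and compares the first singular
value; bootstrap ratios divide the original neural saliences by their SE
over resamples (10,000 by default), sign-aligned to the original by dot
product, with |BSR| > 1.96 read as robust. Degenerate resamples with a
constant column are redrawn and counted; the SE is floored at 1e-12.
The first behavior salience is forced non-negative (saliences are only
defined up to a joint sign). Resampling is unstratified by default with
a stratified-by-group option.

## Behavioral scoring and two-stage models

Pr pools hits and correct rejections over all scored old and new trials;
chance is the response probability times the old-trial fraction
(0.5 × 250/400 = 0.3125, reported as 0.31); bias is
FAR/(1 − (HR − FAR)), with the 0/0 case at perfect discrimination
returned as its limit 0. Pair judgments are scored on all old-pair
trials by default, with a flag to condition on a correct item response.

Random-slopes mixed models are replaced by a two-stage
summary-statistics scheme: one slope per subject (logistic for binary
memory outcomes, clipped at ±10 under separation; OLS otherwise), then a
one-sample t on slopes for the main effect and a two-sample t across age
groups for the interaction. This is exact for balanced designs and
avoids a mixed-model dependency; the trial tables can be exported
long-format for external mixed-model replication.

## Problem sizes and reproducibility

The shipped configuration runs cohorts of 2 × 8 subjects on a 12³ grid
with 40 objects and 200 permutations, completing in a few minutes on one
CPU; calibration suites use 200 null replicates at 500 permutations, and
recovery suites 20 seeded replicates at n = 20/20. These sizes were
chosen so that every acceptance property is measured with useful
statistical resolution at desk scale. All stochastic stages take
explicit seeds (design, betas, memory, permutation, bootstrap), spawned
from one master seed via `numpy.random.SeedSequence`; identical
configurations produce byte-identical reports. Volumes are stored
float32; statistics are computed in float64.

## Known limitations

* The generator's independence assumptions (white noise across voxels
  and trials) make calibration results a best case; spatially correlated
  noise would enlarge null cluster masses and is not modeled.
* Item- and category-level distinctiveness share no generative factor,
  so cross-level association analyses are demonstrations of machinery,
  not of a recoverable effect, unless the user injects coupling.
* The two-stage association analysis understates random-slope shrinkage
  relative to a full GLMM when trial counts differ strongly across
  subjects.
* No surface formats, no atlas labeling, no TFCE or random-field
  alternatives to the cluster-mass statistic.
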