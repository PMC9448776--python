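# Methods

This note documents the models, estimators and numerical choices behind
`morphdiverge`, what the synthetic data generator does and does not
emulate, and the design decisions taken where the methodology left room.

## Problem setting

A VBM study produces, per subject, a modulated gray-matter-volume (GMV)
map on a common grid. Different preprocessing pipelines produce different
maps from the same scans. The package quantifies that divergence at four
levels: raw map similarity, reliability of the voxel/image measurements,
agreement of mass-univariate inference, and portability of multivariate
predictors. All analyses operate on a `VolumeStack`
(subjects × masked-voxels matrix bound to a grid and boolean mask;
C-order flattening of mask indices, 0-based throughout). Before any
between-pipeline comparison the masks are intersected, since voxel-wise
ICC and overlap are undefined off a shared support.

## Synthetic multi-pipeline generator

The generator's role is to provide controllable ground truth, not
realistic brains. Each subject has one latent map

  value(v) = baseline(v) + sex offset(v) + age slope(v)·(age − mean age)
             + subject intercept + voxel noise,

with baseline a fixed smooth field (~0.3–0.7, the scale of modulated GM
fractions), region-localized effects, subject intercepts N(0, subject_sd)
shared across voxels, and iid voxel noise. Each "pipeline" then observes

  out = smooth( shift( latent × gain × bias field ) ) + noise,

where the bias field is built from low-order separable cosines (amplitude =
maximum fractional deviation, the canonical smooth MR inhomogeneity
model), the sub-voxel shift uses linear interpolation with edge clamping
(a stand-in for normalization disagreement), and smoothing is Gaussian
with zero padding. The bias field and shift are fixed per pipeline
(systematic); only the additive noise is redrawn per subject.

Scaling of effects: a sex effect of size `d` shifts the region's voxels by
±δ/2 with δ = d·sqrt(subject_sd² + voxel_noise_sd²/m) for an m-voxel
region, so that the standardized mean difference of the *region mean*
equals d; a two-sample t on the region mean is the recovery oracle. This
also means d caps the achievable accuracy of any classifier that can only
use this region's mean — multivariate tests that require high accuracy
plant per-voxel effects instead.

Defaults are chosen to mirror a typical sex-difference cohort (n = 200,
half female, ages uniform 18–26; TIV normal per sex, F 1350 / M 1500 ml,
SD 110 ml, truncated at 3 SD) and GMV effect sizes in the commonly
reported range (|d| ≈ 0.5–0.8 for sex, a fraction of a percent of GM per
year for age). The default grid is 24 × 28 × 24 voxels at a nominal 2 mm
spacing with an ellipsoidal mask — small enough that permutation tests run
at full strength on one CPU. All randomness flows from a single root seed
through documented per-operation substreams (`SeedSequence` spawn keys),
so a dataset is bit-reproducible from its spec.

What the generator does **not** emulate: tissue segmentation and its
errors, registration beyond a rigid sub-voxel shift, spatially structured
(non-stationary) noise, site/scanner effects, or any TIV→GMV coupling.
Passing tests therefore demonstrate correctness of the estimators and the
qualitative orderings under controlled divergence — not that any specific
real pipeline pair would attain a particular ICC or accuracy.

Two interactions are worth knowing when designing scenarios. First,
homogeneity (inter-subject similarity) is *raised* by any transform that
smooths — including the implicit smoothing of interpolation — because
subject-specific voxel noise is suppressed while the shared baseline
survives; homogeneity orderings across pipelines are therefore only
noise-ordered between transforms with equal smoothing. Second, I2C2
responds monotonically to growing divergence only while the systematic
replicate offset (e.g. from a gain difference) stays small relative to
between-subject variance; a large offset drives λ negative, after which
added noise moves λ back toward 0. Negative values are reported unclipped
with a flag.

## Similarity and homogeneity

Pearson r between two maps over the mask, clipped to |r| ≤ 1 − 1e−7
before z = atanh(r) so identical maps yield a large finite z. Constant
maps are flagged and their pairs set undefined (NaN), which propagates as
exclusion from means. Homogeneity is the per-subject mean z to all other
subjects within a pipeline; the exclusion rule flags subjects below
mean − 2·SD by default. The repeated-measures ANOVA uses the textbook
one-way RM decomposition, F = MS_pipeline / MS_(subject×pipeline), with
paired-t post hocs and Bonferroni multiplication capped at 1; no
sphericity correction is applied (plain RM F, noted in outputs). Since the
per-subject unit entering the ANOVA is a modeling choice, two separate
ANOVAs are provided: within-pipeline homogeneity scores, and per-subject
mean same-subject cross-pipeline z.

## Replicability estimators

Voxel ICC uses the balanced two-way sums-of-squares decomposition;
consistency ICC(3,1) is the default (two-way mixed, single measurement),
with absolute-agreement ICC(2,1) as a sensitivity option. For balanced
designs this equals the REML mixed-model estimate, which is the implemented
contract (asserted against explicit sums-of-squares oracles). Voxels with
zero total variance are undefined, counted, and excluded from summaries.

I2C2 is the method-of-moments image intraclass correlation: per voxel the
within-subject variance is estimated from replicate deviations around the
subject mean (for J = 2 replicates, mean (W_i1 − W_i2)²/2) and the total
variance from grand-mean-centered deviations; λ = 1 − Σwithin/Σtotal over
voxels. Grand-mean centering is the cited estimator's convention and
matters: subject-mean centering gives different totals. For a single
voxel the estimator reduces to the one-way variance-ratio ICC(1), which is
tested as a consistency check. Category labels use the conventional bins
(<0.4 poor, 0.4–0.59 fair, 0.60–0.74 good, >0.74 excellent; boundaries
0.4 → fair, 0.60 → good, 0.74 → good).

## Mass-univariate inference

Per-voxel OLS with a single-column contrast (sex: F=0/M=1 indicator next
to the intercept; age: years), t = cᵀβ/se. Zero-residual voxels are
guarded (t well-defined, possibly infinite; never NaN). Three thresholding
regimes are run independently and reported side by side:

- **voxel_p** — parametric per-sign one-tailed threshold t > t_isf(p, df)
  (the SPM convention for a directional contrast; the signed pair jointly
  covers the two-sided test at 2p).
- **cluster_fwe** — permutation max-cluster-extent FWE. Random-field
  theory is deliberately not implemented; the permutation route targets
  the same family-wise error and is verifiable by simulation. Clusters
  form at the voxel threshold (26-connectivity default; 6/18 available,
  matching the differing FSL/SPM conventions) and survive when their
  extent's permutation p = (1 + #{null max ≥ extent})/(n_perm + 1) ≤ α.
- **tfce_fwe** — permutation max-TFCE FWE. TFCE(v) = Σ_h e(v,h)^E h^H dh
  with the standard E = 0.5, H = 2 and dh = max(stat)/100 (all
  configurable). The step rule makes the discrete transform exactly
  self-similar under rescaling: TFCE(c·t) = c^(H+1)·TFCE(t). The sweep is
  implemented as one descending threshold pass with an incremental
  union-find (numba), which keeps TFCE cheap enough to sit inside
  permutation loops. The negative side is processed on the negated map.

Permutation inference uses the Freedman–Lane scheme: the nuisance-only
model is fit once, its residual rows are permuted and added back to the
nuisance fit, and the full-model t-map is recomputed; both FWE regimes
consume the same permutation stream when run together. Error control is
per contrast sign (consistent with reporting separate M>F / F>M columns);
negating the response swaps the signed masks exactly. Empirical FWE is
verified on null simulations at the default grid (~200 simulations at
n_perm = 500, inside the 95% binomial band around α = 0.05). The null maps
are smoothed with the standard 8 mm kernel first, as every VBM workflow
does: on unsmoothed iid noise the suprathreshold voxels at p < 0.001 are
isolated singletons, so the max-extent null degenerates to a few tied
integers and the cluster test becomes extremely conservative — a property
of the statistic on unsmooth data, not of this implementation.

Unthresholded-map comparison is the Pearson correlation of t-maps over the
mask, reported as a full pipeline × pipeline matrix.

## Overlap taxonomy

Each voxel in the union of significant voxels (per sign and regime — the
two signs are never pooled, matching separate directional tables) is
assigned to exactly the subset of pipelines that detected it. Percentages
use the union as denominator and sum to 100 before rounding; the rendered
table orders rows unique → pairwise → triple → full intersection, prints
two decimals, and marks absent subsets with an em-dash. Voxel-level set
operations only; no cluster matching or spatial tolerance.

## MVPA

`split_matched` sorts each sex by age (ties broken by a seeded shuffle)
and alternates assignment, giving sex counts equal within one and closely
matched age means. Feature selection refits the linear model on B
stratified bootstrap resamples of the training half; per-voxel
z = mean(w)/SD(w), two-sided normal p, Benjamini–Hochberg FDR at q ≤ 0.05.
This bootstrap-z reading of "weight stability" is a design choice; B and q
are configuration. The deployed model is refit on the full training set
(5-fold CV is recorded as an internal performance estimate only — with C
fixed there is nothing to tune). Classification is a hinge-loss linear SVM
(C = 1) trained without intercept on train-mean-centered features, so the
decision rule is sign(w·(x − c)) with c frozen from training; regression
is linear SVR (ε = 0.1, C = 1) with intercept. Freezing c avoids test-set
leakage; the price is that a global intensity gain g on a target pipeline
shifts decisions by (g−1)·w·c, so label invariance under gain holds
outside that offset band rather than unconditionally. Transfer applies
each source pipeline's voxel set, center and weights to every target
pipeline's test stack (shared mask makes indices commensurable; features
are not re-selected on the target); performance is accuracy (sex) or
Pearson r (age), with Cohen's d computed on decision values grouped by
true sex (pooled-SD formula) — the quantity d is computed on is recorded
in output metadata. The ">5 voxels per cluster" filter on stability maps
is display-only and never affects prediction.

## Orchestration and determinism

`run_full_analysis` executes simulate → similarity → replicability →
massuni → overlap → mvpa from one YAML-serializable config; every stage
records its status in `manifest.json` as it completes, so a failing stage
leaves earlier artifacts intact and is surfaced by name. All numeric
tables are byte-reproducible from (config, seed). The desk-scale default
profile (grid 24 × 28 × 24, n = 120, n_perm = 500, B = 500) is the
package's own choice of a tractable single-CPU problem size; the larger
counts used by large-cohort studies (e.g. 5000 permutations/bootstraps)
are plain configuration values.

## Known limitations

- Cluster-FWE is permutation-based; parametric random-field-theory
  thresholds (and small-volume correction, nonstationarity correction)
  are out of scope.
- I2C2 confidence intervals are not provided.
- The generator's pipelines share one latent anatomy by construction;
  real between-pipeline disagreement includes segmentation and
  registration failures outside this model.
- RM-ANOVA is reported without sphericity correction.
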