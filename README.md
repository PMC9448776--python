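# morphdiverge

**Between-pipeline variability analysis for voxel-based morphometry (VBM).**

Structural-MRI studies routinely estimate voxel-wise gray-matter volume
(GMV) with one of several preprocessing pipelines (CAT12, FSLVBM, FSLANAT,
sMRIPrep-style custom workflows) and then ask which regions differ between
groups, change with age, or predict a phenotype. The pipeline choice alone
can move those answers substantially. `morphdiverge` packages the complete
comparison methodology — and a synthetic multi-pipeline data generator with
known ground truth — so the whole chain can be exercised, tested and
calibrated on a desk-scale problem:

- **Spatial similarity & homogeneity** — Pearson correlation of GMV maps
  over the analysis mask, Fisher-z transformed (z = atanh r); per-subject
  homogeneity (mean z to all other subjects within a pipeline) with an
  SD-rule quality exclusion; one-way repeated-measures ANOVA across
  pipelines with Bonferroni paired post hocs.
- **Replicability** — voxel-wise two-way mixed-effects consistency
  ICC(3,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E) treating pipelines as
  raters, and the whole-image I2C2,
  λ = 1 − tr(within-subject) / tr(total), with the conventional
  poor / fair / good / excellent bins (<0.4 / 0.4–0.59 / 0.60–0.74 / >0.74).
- **Mass-univariate GLMs** — per-voxel OLS (sex contrast with age + TIV
  covariates; age association with sex + TIV), thresholded at voxel
  p < 0.001, by permutation max-cluster-extent FWE (Freedman–Lane), and by
  permutation max-TFCE FWE (E = 0.5, H = 2, dh = max|t|/100), plus Pearson
  correlations between unthresholded t-maps.
- **Overlap taxonomy** — exclusive-intersection accounting of significant
  voxels across pipelines ({A unique}, {A ∩ B}, …, full intersection), with
  percentages of the union that sum to 100 before rounding.
- **MVPA transfer** — sex- and age-matched train/test split, bootstrap
  weight-stability feature selection (z = mean/SD over resamples, BH-FDR),
  linear SVM (C = 1) / SVR (ε = 0.1, C = 1), and the source × target
  pipeline transfer matrix (accuracy or Pearson r, Cohen's d of decision
  values).

## Worked example

```python
from morphdiverge.report import RunConfig, run_full_analysis

cfg = RunConfig(seed=2, n_subjects=120, grid_shape=(12, 14, 12),
                models=("sex",), regimes=("voxel_p",), mvpa_B=200)
bundle = run_full_analysis(cfg)
print(bundle["summary"])
```

prints (abridged):

```
Spatial similarity
  within-pipeline homogeneity RM-ANOVA: F(3,357) = 7210.346, p = 0
    mean homogeneity z [cat_like]: 1.119
    mean homogeneity z [fslvbm_like]: 0.914
    mean homogeneity z [fslanat_like]: 0.934
    mean homogeneity z [smriprep_like]: 0.698
  mean same-subject between-pipeline z: 0.766

Replicability (I2C2 per pipeline pair)
  cat_like vs fslvbm_like: I2C2 = 0.477 (fair), mean voxel ICC = 0.730
  cat_like vs smriprep_like: I2C2 = 0.050 (poor), mean voxel ICC = 0.481
  fslvbm_like vs fslanat_like: I2C2 = 0.547 (fair), mean voxel ICC = 0.588
  ...

Overlap taxonomy (percent of union, exclusive subsets)
  sex:voxel_p:positive (union 4 voxels): fslvbm_like (unique) 50.00%, ...

MVPA transfer
  sex (accuracy, source rows x target columns, n_test = 60):
          cat_like: 1.00 1.00 0.97 0.77
       fslvbm_like: 1.00 0.90 0.90 0.80
      fslanat_like: 0.75 0.88 0.98 0.73
     smriprep_like: 0.53 0.60 0.58 0.68
```

The four built-in pipeline transforms observe one shared latent anatomy
through different systematic distortions (gain, smooth multiplicative bias,
sub-voxel displacement, extra smoothing, noise). The readout mirrors the
empirical between-pipeline findings such studies report: the denoised
CAT-like pipeline is the most homogeneous, pairwise I2C2 sits in the
poor-to-fair range, thresholded sex-difference voxels are largely
pipeline-unique, and sex prediction transfers well among similar pipelines
but degrades sharply to and from the most divergent one — all of it here a
ground-truth consequence of the injected distortions, not an estimation
artifact.

A command-line interface mirrors the library
(`morphdiverge simulate | similarity | replicability | glm | overlap |
mvpa | run-all | report`); `run-all` takes a YAML config and writes TSV/JSON
artifacts, `manifest.json` and `summary.txt` to the output directory.

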