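"""Spatial similarity and homogeneity of GMV maps within and between pipelines.

Similarity between two maps is the Pearson correlation of their voxel values
over the analysis mask, variance-stabilized with Fisher's z = atanh(r).
Per-subject homogeneity is the mean z to all other subjects' maps within a
pipeline and is used for quality exclusion.  A one-way repeated-measures
ANOVA (factor: pipeline) with Bonferroni-corrected paired post hocs compares
similarity levels across pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volio import VolumeStack

__all__ = [
    "R_CLIP_EPS",
    "fisher_z",
    "spatial_similarity",
    "homogeneity",
    "flag_low_homogeneity",
    "rm_anova_pipeline",
    "AnovaResult",
    "SimilarityResult",
    "pipeline_similarity",
]

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh so that
#: identical maps yield a large finite z instead of infinity
R_CLIP_EPS: float = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform with r clipped to +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS))


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two (n, V) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    bad_a = sa == 0
    bad_b = sb == 0
    sa = np.where(bad_a, 1.0, sa)
    sb = np.where(bad_b, 1.0, sb)
    r = (ac @ bc.T) / np.outer(sa, sb)
    if bad_a.any() or bad_b.any():
        warnings.warn(
            f"{int(bad_a.sum())}+{int(bad_b.sum())} constant image(s); "
            "their similarity values are undefined",
            RuntimeWarning,
            stacklevel=3,
        )
        r[bad_a, :] = np.nan
        r[:, bad_b] = np.nan
    return r


def spatial_similarity(
    stack_a: VolumeStack, stack_b: VolumeStack | None = None
) -> np.ndarray:
    """Fisher-z similarity matrix between all image pairs.

    With one stack, returns the symmetric within-stack matrix with NaN on
    the diagonal (self-pairs excluded).  With two stacks (same mask), returns
    the (n_a, n_b) cross-stack matrix; same-subject cross-pipeline values
    sit on the diagonal when subject order matches.

    Constant images are flagged with a warning and their pairs set to NaN.
    """
    if stack_a.n_voxels < 2:
        raise ValueError("need >= 2 mask voxels to correlate maps")
    if stack_b is None:
        z = fisher_z(_corr_matrix(stack_a.data, stack_a.data))
        np.fill_diagonal(z, np.nan)
        return z
    if stack_b.n_voxels != stack_a.n_voxels:
        raise ValueError("stacks must share one mask")
    return fisher_z(_corr_matrix(stack_a.data, stack_b.data))


def homogeneity(z_within: np.ndarray) -> np.ndarray:
    """Per-subject homogeneity: mean z over all pairs involving the subject.

    Self-pairs (NaN diagonal) and undefined pairs are excluded from the mean.
    """
    z_within = np.asarray(z_within, dtype=float)
    if z_within.shape[0] < 3:
        raise ValueError("homogeneity needs >= 3 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(z_within, axis=1)


def flag_low_homogeneity(
    scores: np.ndarray, threshold_sd: float = 2.0
) -> np.ndarray:
    """Indices of subjects with homogeneity < mean - threshold_sd * SD.

    The default 2-SD rule mirrors the common sample-homogeneity quality
    check used to exclude poorly preprocessed images.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("homogeneity scores must be finite")
    if np.isinf(threshold_sd):
        return np.array([], dtype=int)
    cut = scores.mean() - threshold_sd * scores.std(ddof=1)
    return np.flatnonzero(scores < cut)


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Bonferroni paired post hocs."""

    F: float
    df1: int
    df2: int
    p: float
    posthoc: pd.DataFrame  # columns: pair_a, pair_b, mean_diff, t, p_raw, p_bonf

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "posthoc": self.posthoc.to_dict(orient="records"),
        }


def rm_anova_pipeline(
    values: pd.DataFrame | np.ndarray, pipeline_names: list[str] | None = None
) -> AnovaResult:
    """Repeated-measures ANOVA of subject x pipeline similarity scores.

    F = MS_pipeline / MS_(subject x pipeline); post hoc paired t-tests for
    all pipeline pairs with Bonferroni multiplication (capped at 1).  No
    sphericity correction is applied (plain repeated-measures F).
    """
    if isinstance(values, pd.DataFrame):
        pipeline_names = list(values.columns)
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if pipeline_names is None:
            pipeline_names = [f"pipeline{i}" for i in range(x.shape[1])]
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need a complete table with >= 3 subjects x >= 2 pipelines")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed (no imputation)")

    n, p = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    pipe_means = x.mean(axis=0)
    ss_pipe = n * float(((pipe_means - grand) ** 2).sum())
    resid = x - subj_means[:, None] - pipe_means[None, :] + grand
    ss_err = float((resid**2).sum())
    df1, df2 = p - 1, (n - 1) * (p - 1)
    if ss_pipe == 0.0:
        f, pval = 0.0, 1.0
    elif ss_err == 0.0:
        f, pval = np.inf, 0.0
    else:
        f = (ss_pipe / df1) / (ss_err / df2)
        pval = float(stats.f.sf(f, df1, df2))

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    rows = []
    for i, j in pairs:
        t, praw = stats.ttest_rel(x[:, i], x[:, j])
        rows.append(
            {
                "pair_a": pipeline_names[i],
                "pair_b": pipeline_names[j],
                "mean_diff": float(x[:, i].mean() - x[:, j].mean()),
                "t": float(t),
                "p_raw": float(praw),
                "p_bonf": float(min(1.0, praw * len(pairs))),
            }
        )
    return AnovaResult(F=float(f), df1=df1, df2=df2, p=pval,
                       posthoc=pd.DataFrame(rows))


@dataclass
class SimilarityResult:
    """Similarity summaries for a set of pipelines on one cohort."""

    within_z: dict[str, np.ndarray]  # per pipeline: n x n Fisher-z matrix
    homogeneity: pd.DataFrame  # subject x pipeline homogeneity scores
    between_same_subject: pd.DataFrame  # subject x pipeline-pair same-subject z
    within_anova: AnovaResult
    between_anova: AnovaResult | None


def pipeline_similarity(stacks: dict[str, VolumeStack]) -> SimilarityResult:
    """Full similarity analysis across pipelines.

    Within-pipeline: per-subject homogeneity per pipeline, compared across
    pipelines with a repeated-measures ANOVA.  Between-pipeline: same-subject
    cross-pipeline z for every pipeline pair, with a second RM-ANOVA over
    per-subject mean cross-pipeline z per pipeline.
    """
    names = list(stacks)
    if len(names) < 2:
        raise ValueError("need >= 2 pipelines")
    first = stacks[names[0]]
    subject_ids = list(first.subject_ids)
    within_z = {name: spatial_similarity(stacks[name]) for name in names}
    homog = pd.DataFrame(
        {name: homogeneity(within_z[name]) for name in names}, index=subject_ids
    )
    pair_cols = {}
    cross_mean = {name: [] for name in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            z = spatial_similarity(stacks[a], stacks[b])
            d = np.diag(z)
            pair_cols[f"{a}|{b}"] = d
            cross_mean[a].append(d)
            cross_mean[b].append(d)
    between = pd.DataFrame(pair_cols, index=subject_ids)
    per_pipe_cross = pd.DataFrame(
        {name: np.mean(np.column_stack(v), axis=1) for name, v in cross_mean.items()},
        index=subject_ids,
    )
    return SimilarityResult(
        within_z=within_z,
        homogeneity=homog,
        between_same_subject=between,
        within_anova=rm_anova_pipeline(homog),
        between_anova=rm_anova_pipeline(per_pipe_cross) if len(names) > 2 else None,
    )
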