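"""Cross-pipeline replicability: voxel-wise ICC(3,1) maps and whole-image I2C2.

Treating pipelines as "raters" of the same subjects, voxel-level univariate
replicability is the two-way mixed-effects consistency intraclass correlation
ICC(3,1); whole-image multivariate replicability is the image intraclass
correlation coefficient I2C2 = 1 - trace(within-subject variance) /
trace(total variance), summed over mask voxels.

For the balanced subject x pipeline design used here the sums-of-squares
ICC(3,1) equals the REML mixed-model estimate, which is the implemented
contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .volio import VolumeStack

__all__ = [
    "ICCMap",
    "I2C2Result",
    "voxel_icc",
    "icc_from_table",
    "i2c2",
    "i2c2_from_array",
    "categorize_reliability",
    "pairwise_replicability",
]


@dataclass
class ICCMap:
    """Per-voxel ICC with its variance components.

    icc = (MS_R - MS_E) / (MS_R + (k-1) MS_E) at every voxel (consistency
    flavor); ``n_undefined`` counts voxels with zero total variance, whose
    ICC is NaN and excluded from summaries.
    """

    icc: np.ndarray
    ms_r: np.ndarray
    ms_e: np.ndarray
    k: int
    flavor: str
    n_undefined: int

    def summary(self) -> dict:
        valid = self.icc[np.isfinite(self.icc)]
        return {
            "mean_icc": float(valid.mean()) if valid.size else float("nan"),
            "median_icc": float(np.median(valid)) if valid.size else float("nan"),
            "n_voxels": int(self.icc.size),
            "n_undefined": self.n_undefined,
        }


@dataclass
class I2C2Result:
    """Image intraclass correlation: lambda = 1 - trace_within / trace_total."""

    lam: float
    trace_within: float
    trace_total: float
    n_subjects: int
    n_replicates: int
    negative: bool  # lambda < 0 is reported unclipped but flagged

    @property
    def category(self) -> str:
        return categorize_reliability(self.lam)


def icc_from_table(ratings: np.ndarray, flavor: str = "icc3") -> np.ndarray:
    """Vectorized ICC over the last axis of an (n, k[, V]) ratings array.

    flavor "icc3": two-way mixed, consistency, single measurement (3,1).
    flavor "icc2": two-way random, absolute agreement (2,1), for sensitivity.
    Voxels with zero total variance yield NaN.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
        squeeze = True
    else:
        squeeze = False
    n, k, _ = y.shape
    if n < 3 or k < 2:
        raise ValueError("ICC needs >= 3 subjects and >= 2 raters")
    grand = y.mean(axis=(0, 1))
    subj_mean = y.mean(axis=1)  # (n, V)
    rater_mean = y.mean(axis=0)  # (k, V)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_rater = n * ((rater_mean - grand) ** 2).sum(axis=0)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_rater
    ms_r = ss_subj / (n - 1)
    ms_c = ss_rater / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if flavor == "icc3":
            denom = ms_r + (k - 1) * ms_e
        elif flavor == "icc2":
            denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        else:
            raise ValueError(f"unknown ICC flavor {flavor!r}")
        icc = np.where(denom > 0, (ms_r - ms_e) / np.where(denom == 0, 1, denom),
                       np.nan)
    icc = np.where(ss_total == 0, np.nan, icc)
    return (icc[0], ms_r[0], ms_e[0]) if squeeze else (icc, ms_r, ms_e)


def voxel_icc(stacks: list[VolumeStack], flavor: str = "icc3") -> ICCMap:
    """Voxel-wise ICC map across >= 2 aligned pipeline stacks.

    Stacks must share mask, grid and subject order; each pipeline acts as a
    rater in a balanced subject x pipeline table per voxel.
    """
    _check_aligned(stacks)
    y = np.stack([s.data for s in stacks], axis=1)  # (n, k, V)
    if y.shape[0] < 3:
        raise ValueError("voxel ICC needs >= 3 subjects")
    icc, ms_r, ms_e = icc_from_table(y, flavor=flavor)
    n_undef = int(np.sum(~np.isfinite(icc)))
    return ICCMap(icc=icc, ms_r=ms_r, ms_e=ms_e, k=len(stacks), flavor=flavor,
                  n_undefined=n_undef)


def i2c2_from_array(y: np.ndarray) -> I2C2Result:
    """I2C2 from an (n_subjects, n_replicates, n_voxels) array.

    Method-of-moments estimator with grand-mean centering per voxel:
    within-subject variance per voxel from replicate deviations around the
    subject mean (for J=2 this is mean (W_i1 - W_i2)^2 / 2); total variance
    across all n*J images.  lambda = 1 - sum(within) / sum(total).
    """
    y = np.asarray(y, dtype=float)
    n, j, v = y.shape
    if n < 3 or j < 2:
        raise ValueError("I2C2 needs >= 3 subjects and >= 2 replicates")
    subj_mean = y.mean(axis=1, keepdims=True)
    within = ((y - subj_mean) ** 2).sum(axis=(0, 1)) / (n * (j - 1))
    grand = y.mean(axis=(0, 1), keepdims=True)
    total = ((y - grand) ** 2).sum(axis=(0, 1)) / (n * j - 1)
    tr_within = float(within.sum())
    tr_total = float(total.sum())
    if tr_total <= 0:
        raise ValueError("degenerate data: zero total trace")
    lam = 1.0 - tr_within / tr_total
    return I2C2Result(lam=lam, trace_within=tr_within, trace_total=tr_total,
                      n_subjects=n, n_replicates=j, negative=lam < 0)


def i2c2(stacks: list[VolumeStack]) -> I2C2Result:
    """I2C2 across >= 2 aligned pipeline stacks (pipelines as replicates)."""
    _check_aligned(stacks)
    y = np.stack([s.data for s in stacks], axis=1)
    return i2c2_from_array(y)


def categorize_reliability(value: float) -> str:
    """Conventional reliability bins: <0.4 poor, 0.4-0.59 fair, 0.60-0.74 good,
    >0.74 excellent."""
    if not np.isfinite(value):
        raise ValueError("reliability value must be finite")
    if value < 0.4:
        return "poor"
    if value < 0.6:
        return "fair"
    if value <= 0.74:
        return "good"
    return "excellent"


def pairwise_replicability(stacks: dict[str, VolumeStack]) -> pd.DataFrame:
    """ICC summary + I2C2 (with category) for every pipeline pair.

    Mirrors the paper-style supplementary table layout: one row per pair.
    """
    rows = []
    for a, b in combinations(stacks, 2):
        pair = [stacks[a], stacks[b]]
        iccmap = voxel_icc(pair)
        res = i2c2(pair)
        rows.append(
            {
                "pipeline_a": a,
                "pipeline_b": b,
                "mean_icc": iccmap.summary()["mean_icc"],
                "median_icc": iccmap.summary()["median_icc"],
                "i2c2": res.lam,
                "category": res.category,
                "negative_flag": res.negative,
            }
        )
    return pd.DataFrame(rows)


def _check_aligned(stacks: list[VolumeStack]) -> None:
    if len(stacks) < 2:
        raise ValueError("need >= 2 stacks")
    ref = stacks[0]
    for s in stacks[1:]:
        if s.n_voxels != ref.n_voxels or tuple(s.grid.shape) != tuple(ref.grid.shape):
            raise ValueError("stacks must share grid and mask")
        if list(s.subject_ids) != list(ref.subject_ids):
            raise ValueError("stacks must have aligned subjects")
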