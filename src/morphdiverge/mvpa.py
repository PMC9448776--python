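"""Multivariate pattern analysis: sex classification and age regression
with bootstrap-stability feature selection and cross-pipeline transfer.

The decoding path mirrors the standard structural-MRI MVPA recipe: split the
cohort into sex- and age-matched train/test halves, select stable voxels by
bootstrap resampling of a linear model's weights (z = mean/SD over
resamples, Benjamini–Hochberg FDR), refit on the full training set, then
apply each pipeline's trained pattern to test data from every pipeline to
build the transfer matrix (accuracy for sex, Pearson r for age, Cohen's d of
the decision-value distributions as effect size).

Feature centering is learned on the training data only and frozen for all
targets; classification decisions use a zero-intercept rule on the centered
features, which makes predicted labels exactly invariant to a positive
global intensity gain of the target data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC, LinearSVR
from statsmodels.stats.multitest import multipletests

from .volio import VolumeStack, validate_table

__all__ = [
    "SplitPlan",
    "LinearModelSpec",
    "StabilityMask",
    "FittedPredictor",
    "TransferMatrix",
    "split_matched",
    "bootstrap_stability",
    "train_predictor",
    "evaluate_transfer",
    "cohens_d",
    "NoStableFeaturesError",
]


class NoStableFeaturesError(RuntimeError):
    """Bootstrap selection returned zero stable voxels."""


@dataclass(frozen=True)
class LinearModelSpec:
    """Linear decoder configuration (SVM for sex, SVR for age)."""

    task: str = "classify_sex"  # or "regress_age"
    C: float = 1.0
    epsilon: float = 0.1
    folds: int = 5

    def __post_init__(self) -> None:
        if self.task not in ("classify_sex", "regress_age"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class SplitPlan:
    """Sex- and age-matched train/test split."""

    train_ids: list[str]
    test_ids: list[str]
    report: dict
    seed: int


def split_matched(table: pd.DataFrame, seed: int = 0) -> SplitPlan:
    """Split a cohort into two sex- and age-matched halves.

    Within each sex, subjects are sorted by age (ties broken by a seeded
    shuffle) and assigned alternately to the two sides, so sex counts differ
    by at most one per side and mean ages track each other closely.
    """
    table = validate_table(table)
    if len(table) < 4:
        raise ValueError("need >= 4 subjects to split")
    if table["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for sex in ("F", "M"):
        sub = table[table["sex"] == sex]
        order = rng.permutation(len(sub))  # randomize ties before stable sort
        sub = sub.iloc[order]
        sub = sub.iloc[np.argsort(sub["age"].to_numpy(), kind="stable")]
        ids = list(sub["subject_id"])
        train.extend(ids[0::2])
        test.extend(ids[1::2])
    t_tab = table.set_index("subject_id")
    report = {
        "train_sex_counts": t_tab.loc[train, "sex"].value_counts().to_dict(),
        "test_sex_counts": t_tab.loc[test, "sex"].value_counts().to_dict(),
        "train_mean_age": float(t_tab.loc[train, "age"].mean()),
        "test_mean_age": float(t_tab.loc[test, "age"].mean()),
    }
    return SplitPlan(train_ids=train, test_ids=test, report=report, seed=seed)


def _fit_linear(X: np.ndarray, y: np.ndarray, spec: LinearModelSpec,
                seed: int = 0):
    """Fit the linear decoder on (already centered) features."""
    if spec.task == "classify_sex":
        model = LinearSVC(C=spec.C, loss="hinge", fit_intercept=False,
                          dual=True, tol=1e-6, max_iter=100_000,
                          random_state=seed)
    else:
        model = LinearSVR(C=spec.C, epsilon=spec.epsilon, tol=1e-6,
                          max_iter=100_000, random_state=seed)
    model.fit(X, y)
    return model


@dataclass
class StabilityMask:
    """Bootstrap weight-stability selection result."""

    mean_weight: np.ndarray
    weight_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    selected: np.ndarray
    B: int
    q_threshold: float
    n_redraws: int = 0

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def bootstrap_stability(
    X: np.ndarray,
    y: np.ndarray,
    spec: LinearModelSpec,
    B: int = 500,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> StabilityMask:
    """Select stable voxels by bootstrap resampling of decoder weights.

    B resamples with replacement (stratified by class for classification)
    each refit the linear model; per-voxel z = mean(w)/SD(w) over resamples,
    two-sided normal p, Benjamini–Hochberg FDR; voxels with q <= q_threshold
    are selected.  Deterministic for a fixed seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 8:
        raise ValueError("need >= 8 training subjects")
    rng = np.random.default_rng(seed)
    center = X.mean(axis=0)
    Xc = X - center
    classify = spec.task == "classify_sex"
    classes = np.unique(y) if classify else None
    if classify and classes.size != 2:
        raise ValueError("classification needs exactly two classes")

    weights = np.empty((B, X.shape[1]))
    n_redraws = 0
    for b in range(B):
        if classify:
            idx_parts = []
            for cls in classes:
                members = np.flatnonzero(y == cls)
                idx_parts.append(rng.choice(members, size=members.size,
                                            replace=True))
            idx = np.concatenate(idx_parts)
        else:
            idx = rng.choice(n, size=n, replace=True)
        # stratified draws always contain both classes; this redraw guard
        # only matters if a caller disables stratification upstream
        for _ in range(10):
            if not classify or np.unique(y[idx]).size == 2:
                break
            n_redraws += 1
            idx = rng.choice(n, size=n, replace=True)
        model = _fit_linear(Xc[idx], y[idx], spec, seed=seed)
        weights[b] = np.ravel(model.coef_)

    mean_w = weights.mean(axis=0)
    sd_w = weights.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_w > 0, mean_w / np.where(sd_w == 0, 1.0, sd_w),
                     np.sign(mean_w) * np.inf)
    z = np.where((sd_w == 0) & (mean_w == 0), 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    selected = q <= q_threshold
    return StabilityMask(mean_weight=mean_w, weight_sd=sd_w, z=z, p=p, q=q,
                         selected=selected, B=B, q_threshold=q_threshold,
                         n_redraws=n_redraws)


@dataclass
class FittedPredictor:
    """A trained linear pattern, portable across pipelines.

    Carries the source pipeline label, the selected voxel index set (indices
    into the shared mask), and the training-set centering vector; prediction
    on any target stack restricted to those voxels is
    ``decision = (X - center) @ w`` (+ intercept for regression).
    """

    task: str
    source: str
    voxel_idx: np.ndarray
    center: np.ndarray
    weights: np.ndarray
    intercept: float
    classes: np.ndarray | None
    cv_score: float
    spec: LinearModelSpec

    def decision_values(self, stack_data: np.ndarray) -> np.ndarray:
        Xc = stack_data[:, self.voxel_idx] - self.center
        return Xc @ self.weights + self.intercept

    def predict(self, stack_data: np.ndarray) -> np.ndarray:
        d = self.decision_values(stack_data)
        if self.task == "classify_sex":
            return np.where(d > 0, self.classes[1], self.classes[0])
        return d

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "source": self.source,
            "voxel_idx": self.voxel_idx.tolist(),
            "center": self.center.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "classes": None if self.classes is None else self.classes.tolist(),
            "cv_score": self.cv_score,
            "spec": {"task": self.spec.task, "C": self.spec.C,
                     "epsilon": self.spec.epsilon, "folds": self.spec.folds},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "FittedPredictor":
        d = json.loads(Path(path).read_text())
        return cls(
            task=d["task"], source=d["source"],
            voxel_idx=np.asarray(d["voxel_idx"], dtype=int),
            center=np.asarray(d["center"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            classes=None if d["classes"] is None else np.asarray(d["classes"]),
            cv_score=float(d["cv_score"]),
            spec=LinearModelSpec(**d["spec"]),
        )


def train_predictor(
    X: np.ndarray,
    y: np.ndarray,
    spec: LinearModelSpec,
    voxel_idx: np.ndarray | None = None,
    source: str = "",
    seed: int = 0,
) -> FittedPredictor:
    """Train the deployed linear pattern on the full training set.

    ``voxel_idx`` restricts training to the stability-selected voxels (the
    indices are kept on the model so targets resolve the same voxels).  The
    recorded ``cv_score`` is an internal 5-fold cross-validation estimate
    (accuracy or Pearson r); the deployed model is refit on all rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if voxel_idx is None:
        voxel_idx = np.arange(X.shape[1])
    voxel_idx = np.asarray(voxel_idx, dtype=int)
    if voxel_idx.size == 0:
        raise NoStableFeaturesError(
            "no stable features selected; the pattern cannot be trained"
        )
    Xs = X[:, voxel_idx]
    center = Xs.mean(axis=0)
    Xc = Xs - center
    classify = spec.task == "classify_sex"

    # internal CV performance estimate; fold count capped by the smallest
    # class (classification) or the sample size so tiny cohorts still run
    if classify:
        max_folds = int(min(np.bincount(np.searchsorted(np.unique(y), y))))
    else:
        max_folds = len(y) // 2
    folds = max(2, min(spec.folds, max_folds))
    splitter = (StratifiedKFold(folds, shuffle=True, random_state=seed)
                if classify else KFold(folds, shuffle=True, random_state=seed))
    scores = []
    for tr, te in splitter.split(Xc, y if classify else None):
        m = _fit_linear(Xc[tr], y[tr], spec, seed=seed)
        if classify:
            pred = m.predict(Xc[te])
            scores.append(float(np.mean(pred == y[te])))
        else:
            pred = m.predict(Xc[te])
            if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
                scores.append(0.0)
            else:
                scores.append(float(np.corrcoef(pred, y[te])[0, 1]))
    model = _fit_linear(Xc, y, spec, seed=seed)
    return FittedPredictor(
        task=spec.task,
        source=source,
        voxel_idx=voxel_idx,
        center=center,
        weights=np.ravel(model.coef_),
        intercept=0.0 if classify else float(np.ravel(model.intercept_)[0]),
        classes=np.sort(np.unique(y)) if classify else None,
        cv_score=float(np.mean(scores)),
        spec=spec,
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled-SD formula d = (mean_a - mean_b) / s_pooled."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


@dataclass
class TransferMatrix:
    """Cross-pipeline prediction performance.

    ``performance``: source x target accuracy (sex) or Pearson r (age);
    the diagonal is within-pipeline performance.  ``effect_size``: Cohen's d
    between the decision-value distributions of the two true-sex groups
    (classification only).
    """

    task: str
    performance: pd.DataFrame
    effect_size: pd.DataFrame | None
    n_test: int


def evaluate_transfer(
    models: dict[str, FittedPredictor],
    test_stacks: dict[str, VolumeStack],
    y_true: np.ndarray,
) -> TransferMatrix:
    """Apply each source pipeline's pattern to every target pipeline's test data.

    Test subjects must be aligned (same order) across target stacks;
    ``y_true`` is the sex label vector or the true age vector in that order.
    """
    y_true = np.asarray(y_true)
    sources = list(models)
    targets = list(test_stacks)
    ref_ids = list(test_stacks[targets[0]].subject_ids)
    for t in targets[1:]:
        if list(test_stacks[t].subject_ids) != ref_ids:
            raise ValueError("test subjects must be aligned across target stacks")
    task = models[sources[0]].task
    perf = pd.DataFrame(index=sources, columns=targets, dtype=float)
    eff = pd.DataFrame(index=sources, columns=targets, dtype=float) \
        if task == "classify_sex" else None
    for s in sources:
        model = models[s]
        for t in targets:
            data = test_stacks[t].data
            if task == "classify_sex":
                pred = model.predict(data)
                perf.loc[s, t] = float(np.mean(pred == y_true))
                d = model.decision_values(data)
                g1 = d[y_true == model.classes[1]]
                g0 = d[y_true == model.classes[0]]
                eff.loc[s, t] = cohens_d(g1, g0)
            else:
                pred = model.predict(data)
                if np.ptp(pred) == 0:
                    perf.loc[s, t] = float("nan")
                else:
                    perf.loc[s, t] = float(np.corrcoef(pred, y_true)[0, 1])
    return TransferMatrix(task=task, performance=perf, effect_size=eff,
                          n_test=len(ref_ids))
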