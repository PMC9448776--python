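"""Mass-univariate GLMs with voxel-p, permutation cluster-FWE and TFCE-FWE.

Each analysis fits an ordinary-least-squares GLM per voxel (e.g. sex contrast
with age and TIV covariates, or an age association with sex and TIV
covariates) and thresholds the resulting t-map under one of three regimes:

* ``voxel_p``     — parametric t-distribution threshold at voxel p.
* ``cluster_fwe`` — permutation max-cluster-extent FWE: clusters formed at a
  voxel threshold survive if their extent exceeds the permutation null of the
  maximum cluster extent (Freedman–Lane residual permutation).
* ``tfce_fwe``    — permutation max-TFCE FWE on the TFCE-transformed t-map.

Family-wise error is controlled per contrast sign; the positive and negative
masks are produced symmetrically (negating the response swaps them exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._tfce import connectivity_structure, neighbor_table, tfce_from_values
from .volio import VolumeStack

__all__ = [
    "DesignError",
    "DesignMatrix",
    "build_design",
    "GLMResult",
    "fit_glm",
    "ThresholdedStatMap",
    "threshold_voxel",
    "TFCEParams",
    "tfce_transform",
    "permutation_fwe",
    "cluster_fwe",
    "tfce_fwe",
    "unthresholded_correlation",
    "tmap_correlation_matrix",
]


class DesignError(ValueError):
    """Invalid (e.g. rank-deficient) design matrix."""


@dataclass
class DesignMatrix:
    """Design matrix with named columns and a contrast vector.

    Sex is coded as an F=0 / M=1 indicator next to the intercept, so the sex
    contrast is +/- the indicator column (positive = male > female).
    """

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise DesignError("X/columns shape mismatch")
        if self.contrast.shape != (self.X.shape[1],):
            raise DesignError("contrast length must equal number of columns")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.corrcoef(self.X, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise DesignError(
                f"design is rank deficient (rank {rank} < {self.X.shape[1]}); "
                f"most collinear columns: {self.columns[i]!r}, {self.columns[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


def build_design(
    table: pd.DataFrame, model: str, covariates: tuple[str, ...] | None = None
) -> DesignMatrix:
    """Design for the two standard VBM models.

    model "sex": intercept + sex(F=0/M=1) + age + TIV, contrast on sex.
    model "age": intercept + age + sex + TIV, contrast on age.
    Pass ``covariates`` to override the default nuisance set.
    """
    cols: list[str] = ["intercept"]
    mats = [np.ones(len(table))]
    sex = (table["sex"] == "M").to_numpy(dtype=float)
    if model == "sex":
        tested, tested_vec = "sex", sex
        default_cov = ("age", "tiv")
    elif model == "age":
        tested, tested_vec = "age", table["age"].to_numpy(dtype=float)
        default_cov = ("sex", "tiv")
    else:
        raise ValueError(f"unknown model {model!r}")
    cols.append(tested)
    mats.append(tested_vec)
    for cov in covariates if covariates is not None else default_cov:
        cols.append(cov)
        mats.append(sex if cov == "sex" else table[cov].to_numpy(dtype=float))
    X = np.column_stack(mats)
    contrast = np.zeros(X.shape[1])
    contrast[cols.index(tested)] = 1.0
    return DesignMatrix(X=X, columns=cols, contrast=contrast)


@dataclass
class GLMResult:
    """Per-voxel OLS fit with a contrast t-map."""

    beta: np.ndarray  # (p, V)
    t: np.ndarray  # (V,)
    df: int
    sigma2: np.ndarray  # (V,)
    contrast: np.ndarray
    design_columns: list[str]
    mask: np.ndarray
    grid_shape: tuple[int, ...]

    def t_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape)
        vol[self.mask] = self.t
        return vol


def _t_stats(
    Y: np.ndarray, X: np.ndarray, pinvX: np.ndarray, c: np.ndarray,
    c_var: float, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    cb = c @ beta
    se = np.sqrt(sigma2 * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, cb / np.where(se == 0, 1.0, se),
                     np.sign(cb) * np.inf)
    t = np.where((se == 0) & (cb == 0), 0.0, t)
    return beta, t, sigma2


def fit_glm(stack: VolumeStack, design: DesignMatrix,
            contrast: np.ndarray | None = None) -> GLMResult:
    """Fit the per-voxel OLS GLM and compute the contrast t-map.

    Both contrast signs are derivable from one fit: the t-map for -c is the
    negation of the t-map for c.
    """
    X = design.X
    c = np.asarray(contrast, dtype=float) if contrast is not None else design.contrast
    if X.shape[0] != stack.n_subjects:
        raise DesignError("design rows must align with stack subjects")
    df = design.df
    if df < 1:
        raise DesignError("no residual degrees of freedom")
    pinvX = np.linalg.pinv(X)
    c_var = float(c @ np.linalg.inv(X.T @ X) @ c)
    beta, t, sigma2 = _t_stats(stack.data, X, pinvX, c, c_var, df)
    return GLMResult(beta=beta, t=t, df=df, sigma2=sigma2, contrast=c,
                     design_columns=list(design.columns), mask=stack.mask,
                     grid_shape=tuple(stack.grid.shape))


@dataclass
class ThresholdedStatMap:
    """Signed significance mask for one thresholding regime."""

    regime: str  # voxel_p | cluster_fwe | tfce_fwe
    sign: str  # positive | negative
    mask: np.ndarray  # boolean volume
    params: dict = field(default_factory=dict)
    clusters: pd.DataFrame | None = None  # cluster_fwe: extent + p per cluster

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_voxel(glm: GLMResult, p: float = 0.001) -> dict[str, ThresholdedStatMap]:
    """Parametric voxel-level thresholding at the stated p, per sign.

    Uses the one-tailed t threshold per contrast sign (the SPM convention for
    a directional contrast at voxel p); the pair of signed masks jointly
    covers the two-sided test at 2p.
    """
    if glm.df < 1:
        raise ValueError("df must be >= 1")
    tcrit = float(stats.t.isf(p, glm.df))
    out = {}
    for sign, sel in (("positive", glm.t > tcrit), ("negative", glm.t < -tcrit)):
        vol = np.zeros(glm.grid_shape, dtype=bool)
        vol[glm.mask] = sel
        out[sign] = ThresholdedStatMap(
            regime="voxel_p", sign=sign, mask=vol,
            params={"p": p, "t_crit": tcrit, "df": glm.df},
        )
    return out


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents and integration rule.

    E=0.5, H=2 are the standard published defaults; the integration step is
    dh = max(stat)/n_steps, which makes TFCE exactly self-similar under
    positive rescaling of the statistic (scale c -> TFCE scale c^(H+1)).
    """

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def tfce_transform(
    stat: np.ndarray,
    params: TFCEParams = TFCEParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """TFCE transform of a statistic array of any dimensionality.

    Only the positive part is enhanced; process the negated map for the
    negative side.  With ``mask`` given, voxels outside it are ignored.
    """
    stat = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map must be finite")
    if mask is None:
        mask = np.ones(stat.shape, dtype=bool)
    nb = neighbor_table(mask, params.connectivity)
    vals = stat[mask]
    out = np.zeros(stat.shape)
    out[mask] = tfce_from_values(vals, nb, params.E, params.H, params.n_steps)
    return out


# ---------------------------------------------------------------------------
# Freedman–Lane permutation engine


def _freedman_lane_setup(Y: np.ndarray, design: DesignMatrix):
    """Precompute reduced-model fit for Freedman–Lane permutation of a
    single-column contrast."""
    c = design.contrast
    nz = np.flatnonzero(c)
    if nz.size != 1:
        raise DesignError("permutation inference requires a single-column contrast")
    keep = np.ones(design.X.shape[1], dtype=bool)
    keep[nz[0]] = False
    Z = design.X[:, keep]
    fitted = Z @ (np.linalg.pinv(Z) @ Y)
    resid = Y - fitted
    return fitted, resid


def permutation_fwe(
    stack: VolumeStack,
    design: DesignMatrix,
    *,
    regimes: tuple[str, ...] = ("cluster_fwe", "tfce_fwe"),
    cluster_forming_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 500,
    connectivity: int = 26,
    tfce_params: TFCEParams | None = None,
    seed: int = 0,
    signs: tuple[str, ...] = ("positive", "negative"),
) -> dict[str, dict[str, ThresholdedStatMap]]:
    """Permutation FWE thresholding; both regimes share one permutation pass.

    Freedman–Lane: nuisance-model residuals are permuted and added back to
    the nuisance fit; each permutation yields a full t-map from which the
    maximum cluster extent (at the cluster-forming threshold) and the
    maximum TFCE value are recorded per sign.  Observed clusters / TFCE
    voxels survive when their permutation p = (1 + #{null >= obs}) /
    (n_perm + 1) is <= alpha.

    Returns {regime: {"positive": ThresholdedStatMap, "negative": ...}}.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tfce_params = tfce_params or TFCEParams(connectivity=connectivity)
    rng = np.random.default_rng(seed)
    glm = fit_glm(stack, design)
    df = glm.df
    tcrit = float(stats.t.isf(cluster_forming_p, df))
    mask = stack.mask
    struct = connectivity_structure(mask.ndim, connectivity)
    want_cluster = "cluster_fwe" in regimes
    want_tfce = "tfce_fwe" in regimes
    nb = neighbor_table(mask, tfce_params.connectivity) if want_tfce else None

    X, c = design.X, glm.contrast
    pinvX = np.linalg.pinv(X)
    c_var = float(c @ np.linalg.inv(X.T @ X) @ c)
    fitted, resid = _freedman_lane_setup(stack.data, design)

    sign_flip = {"positive": 1.0, "negative": -1.0}
    unknown = [s for s in signs if s not in sign_flip]
    if unknown:
        raise ValueError(f"unknown signs {unknown}")
    null_cluster = np.zeros((n_perm, len(signs)))
    null_tfce = np.zeros((n_perm, len(signs)))
    n = stack.n_subjects
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = fitted + resid[perm]
        _, tp, _ = _t_stats(Yp, X, pinvX, c, c_var, df)
        for s, sign in enumerate(signs):
            signed = sign_flip[sign] * tp
            if want_cluster:
                null_cluster[b, s] = _max_cluster_extent(signed, tcrit, mask, struct)
            if want_tfce:
                pos = np.maximum(signed, 0.0)
                null_tfce[b, s] = tfce_from_values(
                    pos, nb, tfce_params.E, tfce_params.H, tfce_params.n_steps
                ).max(initial=0.0)

    out: dict[str, dict[str, ThresholdedStatMap]] = {}
    if want_cluster:
        out["cluster_fwe"] = {}
        for s, sign in enumerate(signs):
            signed_t = glm.t if sign == "positive" else -glm.t
            mask_out, clusters = _threshold_clusters(
                signed_t, tcrit, mask, struct, null_cluster[:, s], alpha, n_perm
            )
            out["cluster_fwe"][sign] = ThresholdedStatMap(
                regime="cluster_fwe", sign=sign, mask=mask_out,
                params={
                    "cluster_forming_p": cluster_forming_p, "alpha": alpha,
                    "n_perm": n_perm, "connectivity": connectivity,
                    "inference": "permutation max-cluster-extent (Freedman-Lane)",
                    "seed": seed,
                },
                clusters=clusters,
            )
    if want_tfce:
        out["tfce_fwe"] = {}
        for s, sign in enumerate(signs):
            signed_t = glm.t if sign == "positive" else -glm.t
            tf = tfce_from_values(np.maximum(signed_t, 0.0), nb, tfce_params.E,
                                  tfce_params.H, tfce_params.n_steps)
            null_sorted = np.sort(null_tfce[:, s])
            n_ge = n_perm - np.searchsorted(null_sorted, tf, side="left")
            pvox = (1.0 + n_ge) / (n_perm + 1.0)
            vol = np.zeros(mask.shape, dtype=bool)
            vol[mask] = (pvox <= alpha) & (tf > 0)
            out["tfce_fwe"][sign] = ThresholdedStatMap(
                regime="tfce_fwe", sign=sign, mask=vol,
                params={
                    "alpha": alpha, "n_perm": n_perm,
                    "E": tfce_params.E, "H": tfce_params.H,
                    "n_steps": tfce_params.n_steps,
                    "connectivity": tfce_params.connectivity,
                    "inference": "permutation max-TFCE (Freedman-Lane)",
                    "seed": seed,
                },
            )
    return out


def _max_cluster_extent(t_flat: np.ndarray, tcrit: float, mask: np.ndarray,
                        struct: np.ndarray) -> int:
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = t_flat > tcrit
    labels, n_lab = ndimage.label(vol, structure=struct)
    if n_lab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _threshold_clusters(
    t_flat: np.ndarray, tcrit: float, mask: np.ndarray, struct: np.ndarray,
    null_max: np.ndarray, alpha: float, n_perm: int
) -> tuple[np.ndarray, pd.DataFrame]:
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = t_flat > tcrit
    labels, n_lab = ndimage.label(vol, structure=struct)
    keep = np.zeros(mask.shape, dtype=bool)
    rows = []
    if n_lab:
        sizes = np.bincount(labels.ravel())[1:]
        null_sorted = np.sort(null_max)
        for lab, size in enumerate(sizes, start=1):
            n_ge = n_perm - np.searchsorted(null_sorted, size, side="left")
            p = (1.0 + n_ge) / (n_perm + 1.0)
            surv = p <= alpha
            if surv:
                keep |= labels == lab
            rows.append({"label": lab, "extent": int(size), "p_fwe": float(p),
                         "survives": bool(surv)})
    return keep, pd.DataFrame(rows)


def cluster_fwe(stack: VolumeStack, design: DesignMatrix, *,
                cluster_forming_p: float = 0.001, alpha: float = 0.05,
                n_perm: int = 500, connectivity: int = 26,
                seed: int = 0) -> dict[str, ThresholdedStatMap]:
    """Permutation max-cluster-extent FWE thresholding (both signs)."""
    res = permutation_fwe(
        stack, design, regimes=("cluster_fwe",),
        cluster_forming_p=cluster_forming_p, alpha=alpha, n_perm=n_perm,
        connectivity=connectivity, seed=seed,
    )
    return res["cluster_fwe"]


def tfce_fwe(stack: VolumeStack, design: DesignMatrix, *,
             alpha: float = 0.05, n_perm: int = 500,
             params: TFCEParams | None = None,
             seed: int = 0) -> dict[str, ThresholdedStatMap]:
    """Permutation max-TFCE FWE thresholding (both signs)."""
    res = permutation_fwe(
        stack, design, regimes=("tfce_fwe",), alpha=alpha, n_perm=n_perm,
        tfce_params=params, seed=seed,
    )
    return res["tfce_fwe"]


# ---------------------------------------------------------------------------
# unthresholded-map comparison


def unthresholded_correlation(glm_a: GLMResult, glm_b: GLMResult) -> float:
    """Pearson correlation of two unthresholded t-maps over the shared mask."""
    if glm_a.t.shape != glm_b.t.shape:
        raise ValueError("t-maps must share one mask")
    a, b = glm_a.t, glm_b.t
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant t-map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def tmap_correlation_matrix(glms: dict[str, GLMResult]) -> pd.DataFrame:
    """Full pipeline x pipeline correlation matrix of unthresholded t-maps."""
    names = list(glms)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        r = unthresholded_correlation(glms[a], glms[b])
        out.loc[a, b] = out.loc[b, a] = r
    return out
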