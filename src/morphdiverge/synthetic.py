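"""Synthetic multi-pipeline GMV cohorts with known ground truth.

The generator emulates the statistical structure of a typical VBM study of
healthy adults: every subject has one latent gray-matter-volume map (shared
anatomy + region-localized sex effects + linear age slopes + a between-subject
random intercept + voxel noise), and each "preprocessing pipeline" observes a
distorted version of that latent map (intensity gain, smooth multiplicative
bias field, sub-voxel displacement, extra smoothing, additive noise).

Because the latent anatomy is shared, within/between-pipeline similarity,
voxel ICC, I2C2, GLM overlap, and prediction transfer all have controllable
ground truth: identical pipeline transforms force perfect replicability,
while increasingly divergent transforms degrade it monotonically.

All randomness flows from a single root seed; each operation draws from an
independent, documented stream (``_rng``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volio import Grid, VolumeStack, validate_table, write_stack

__all__ = [
    "InvalidSpecError",
    "CohortSpec",
    "SexEffect",
    "AgeEffect",
    "EffectSpec",
    "PipelineTransformSpec",
    "SyntheticDataset",
    "default_grid",
    "default_mask",
    "box_region",
    "default_effects",
    "default_transforms",
    "make_cohort",
    "make_latent_stack",
    "apply_pipeline_transform",
    "generate_dataset",
]


class InvalidSpecError(ValueError):
    """A generator specification violates its invariants."""


# stream ids for the per-operation RNG substreams
_STREAM_COHORT = 1
_STREAM_LATENT = 2
_STREAM_TRANSFORM = 3


def _rng(root_seed: int, stream: int, offset: int = 0) -> np.random.Generator:
    """Independent generator for (root seed, operation stream, offset)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(root_seed) % (2**31),
                               spawn_key=(stream, offset))
    )


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class CohortSpec:
    """Demographics of a simulated cohort.

    Defaults mirror a sex-difference study sample: n=200, half female,
    ages uniform on 18-26 years.  TIV (ml) is normal per sex, truncated at
    3 SD; means default to typical adult values (F 1350 / M 1500 ml).
    """

    n_subjects: int = 200
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (18.0, 26.0)
    tiv_mean_by_sex: Mapping[str, float] = field(
        default_factory=lambda: {"F": 1350.0, "M": 1500.0}
    )
    tiv_sd: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise InvalidSpecError("n_subjects must be >= 4")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise InvalidSpecError("sex_ratio must lie in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidSpecError("age_range must satisfy min < max")
        if self.tiv_sd <= 0:
            raise InvalidSpecError("tiv_sd must be positive")
        if set(self.tiv_mean_by_sex) != {"F", "M"}:
            raise InvalidSpecError("tiv_mean_by_sex must have keys F and M")


@dataclass(frozen=True)
class SexEffect:
    """Region-localized standardized sex difference.

    ``d`` is the standardized mean difference (male minus female) of the
    region-mean GMV, on the scale of the between-subject SD of that region
    mean; positive d means male > female.
    """

    region: np.ndarray
    d: float


@dataclass(frozen=True)
class AgeEffect:
    """Region-localized linear age slope in GMV units per year."""

    region: np.ndarray
    slope_per_year: float


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure of the latent maps."""

    sex_effects: tuple[SexEffect, ...] = ()
    age_effects: tuple[AgeEffect, ...] = ()
    subject_sd: float = 0.08
    voxel_noise_sd: float = 0.04

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise InvalidSpecError("subject_sd must be >= 0")
        if self.voxel_noise_sd < 0:
            raise InvalidSpecError("voxel_noise_sd must be >= 0")


@dataclass(frozen=True)
class PipelineTransformSpec:
    """Systematic distortions one pipeline applies to the latent maps.

    Stands in for differences between VBM preprocessing packages
    (segmentation, normalization, modulation choices): a global intensity
    gain, a smooth multiplicative bias field (amplitude = max fractional
    deviation), a rigid sub-voxel displacement, extra Gaussian smoothing,
    and additive voxel noise.
    """

    name: str
    intensity_gain: float = 1.0
    bias_field_amplitude: float = 0.0
    displacement_voxels: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extra_smooth_fwhm: float = 0.0
    noise_sd: float = 0.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.intensity_gain <= 0:
            raise InvalidSpecError("intensity_gain must be positive")
        if self.extra_smooth_fwhm < 0:
            raise InvalidSpecError("extra_smooth_fwhm must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if any(abs(d) >= 2 for d in self.displacement_voxels):
            raise InvalidSpecError("|displacement| must be < 2 voxels per axis")


@dataclass
class SyntheticDataset:
    """A generated multi-pipeline dataset with its ground truth attached."""

    subject_table: pd.DataFrame
    latent: VolumeStack
    per_pipeline: dict[str, VolumeStack]
    effects: EffectSpec
    transforms: tuple[PipelineTransformSpec, ...]
    cohort: CohortSpec

    @property
    def pipeline_names(self) -> list[str]:
        return list(self.per_pipeline)


# ---------------------------------------------------------------------------
# geometry defaults


def default_grid() -> Grid:
    """24 x 28 x 24 voxels at nominal 2 mm spacing (desk-scale brain grid)."""
    return Grid(shape=(24, 28, 24), spacing=(2.0, 2.0, 2.0))


def default_mask(grid: Grid) -> np.ndarray:
    """Centered ellipsoid occupying most of the grid, a brain-mask stand-in."""
    coords = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in grid.shape], indexing="ij"
    )
    r2 = sum((c / 0.88) ** 2 for c in coords)
    return r2 <= 1.0


def box_region(grid: Grid, center: Sequence[int], size: Sequence[int]) -> np.ndarray:
    """Axis-aligned box region mask (voxel units), clipped to the grid."""
    out = np.zeros(grid.shape, dtype=bool)
    sl = tuple(
        slice(max(0, c - s // 2), min(dim, c - s // 2 + s))
        for c, s, dim in zip(center, size, grid.shape)
    )
    out[sl] = True
    return out


def baseline_field(grid: Grid, mask: np.ndarray) -> np.ndarray:
    """Deterministic smooth anatomy-like baseline GMV field (~0.3-0.7)."""
    coords = np.meshgrid(
        *[np.linspace(0.0, 1.0, s) for s in grid.shape], indexing="ij"
    )
    x, y, z = coords[0], coords[1], coords[2]
    f = (
        0.5
        + 0.10 * np.cos(np.pi * x) * np.cos(np.pi * y)
        + 0.06 * np.sin(2 * np.pi * z)
        + 0.05 * np.cos(np.pi * (x + z))
    )
    return np.where(mask, f, 0.0)


def default_effects(grid: Grid, mask: np.ndarray) -> EffectSpec:
    """Realistic default ground truth: two sex regions and one age region.

    Effect sizes are in the range typically reported for GMV sex differences
    (|d| ~ 0.5-0.8); the age slope corresponds to the commonly observed
    fraction-of-a-percent annual GM decline at a baseline of ~0.5.
    """
    def frac_box(fracs: tuple[float, float, float], rel_size: float) -> np.ndarray:
        center = tuple(int(round(f * (s - 1))) for f, s in zip(fracs, grid.shape))
        size = tuple(max(3, int(round(rel_size * s))) for s in grid.shape)
        box = box_region(grid, center, size) & mask
        if not box.any():
            raise InvalidSpecError("default effect region fell outside the mask")
        return box

    sexA = frac_box((0.32, 0.30, 0.50), 0.22)
    sexB = frac_box((0.68, 0.70, 0.50), 0.22)
    ageA = frac_box((0.50, 0.50, 0.68), 0.24)
    return EffectSpec(
        sex_effects=(SexEffect(sexA, d=0.8), SexEffect(sexB, d=-0.5)),
        age_effects=(AgeEffect(ageA, slope_per_year=-0.002),),
        subject_sd=0.08,
        voxel_noise_sd=0.04,
    )


def default_transforms() -> tuple[PipelineTransformSpec, ...]:
    """Four pipeline stand-ins with qualitatively ordered divergence.

    The first ("cat_like") is the least distorted / least noisy, giving it
    the highest within-pipeline homogeneity, as expected for a pipeline with
    aggressive denoising; the others add growing bias, displacement,
    smoothing and noise.
    """
    return (
        PipelineTransformSpec("cat_like", intensity_gain=1.00,
                              bias_field_amplitude=0.02,
                              displacement_voxels=(0.1, 0.0, 0.1),
                              extra_smooth_fwhm=2.0, noise_sd=0.01, seed_offset=0),
        PipelineTransformSpec("fslvbm_like", intensity_gain=0.98,
                              bias_field_amplitude=0.05,
                              displacement_voxels=(0.4, 0.2, 0.3),
                              extra_smooth_fwhm=2.0, noise_sd=0.05, seed_offset=1),
        PipelineTransformSpec("fslanat_like", intensity_gain=1.02,
                              bias_field_amplitude=0.04,
                              displacement_voxels=(0.3, 0.4, 0.2),
                              extra_smooth_fwhm=2.0, noise_sd=0.05, seed_offset=2),
        PipelineTransformSpec("smriprep_like", intensity_gain=0.95,
                              bias_field_amplitude=0.07,
                              displacement_voxels=(0.5, 0.5, 0.4),
                              extra_smooth_fwhm=3.0, noise_sd=0.08, seed_offset=3),
    )


# ---------------------------------------------------------------------------
# operations


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a participants table (subject_id, sex, age, tiv) from a CohortSpec.

    Sexes match ``sex_ratio`` exactly (fractional counts round toward
    female), ages are uniform on ``age_range``, and TIV is normal per sex
    truncated at 3 SD.  Deterministic for a fixed seed.
    """
    rng = _rng(spec.seed, _STREAM_COHORT)
    n = spec.n_subjects
    n_female = min(n, int(math.ceil(round(n * spec.sex_ratio, 9))))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    ages = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    tiv = np.empty(n)
    for i, s in enumerate(sexes):
        mu = spec.tiv_mean_by_sex[s]
        while True:  # truncate at 3 SD by rejection
            v = rng.normal(mu, spec.tiv_sd)
            if abs(v - mu) <= 3 * spec.tiv_sd:
                tiv[i] = v
                break
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "sex": sexes,
            "age": ages,
            "tiv": tiv,
        }
    )
    return validate_table(table)


def region_mean_sd(effects: EffectSpec, region: np.ndarray, mask: np.ndarray) -> float:
    """Between-subject SD of a region-mean under the spec's noise model."""
    m = int((region & mask).sum())
    if m == 0:
        raise InvalidSpecError("effect region has no voxels inside the mask")
    return math.sqrt(effects.subject_sd**2 + effects.voxel_noise_sd**2 / m)


def make_latent_stack(
    table: pd.DataFrame,
    effects: EffectSpec,
    grid: Grid,
    mask: np.ndarray | None = None,
    seed: int = 0,
) -> VolumeStack:
    """Generate the shared latent GMV stack for a cohort.

    Voxel value = baseline + sex offsets (scaled so the standardized region-
    mean difference equals d) + age slopes x (age - mean age) + subject
    random intercept + iid voxel noise.
    """
    table = validate_table(table)
    mask = default_mask(grid) if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidSpecError("mask has no voxels")
    rng = _rng(seed, _STREAM_LATENT)
    n = len(table)
    base = baseline_field(grid, mask)[mask]
    data = np.tile(base, (n, 1))

    male = (table["sex"] == "M").to_numpy()
    for eff in effects.sex_effects:
        region = np.asarray(eff.region, dtype=bool)
        if (region & ~mask).any():
            raise InvalidSpecError("sex effect region extends outside the mask")
        delta = eff.d * region_mean_sd(effects, region, mask)
        cols = region[mask]
        data[np.ix_(male, cols)] += delta / 2.0
        data[np.ix_(~male, cols)] -= delta / 2.0

    ages = table["age"].to_numpy(dtype=float)
    centered_age = ages - ages.mean()
    for eff in effects.age_effects:
        region = np.asarray(eff.region, dtype=bool)
        if (region & ~mask).any():
            raise InvalidSpecError("age effect region extends outside the mask")
        cols = region[mask]
        data[:, cols] += np.outer(centered_age, np.full(cols.sum(), eff.slope_per_year))

    if effects.subject_sd > 0:
        data += rng.normal(0.0, effects.subject_sd, size=n)[:, None]
    if effects.voxel_noise_sd > 0:
        data += rng.normal(0.0, effects.voxel_noise_sd, size=data.shape)
    return VolumeStack(data=data, grid=grid, mask=mask,
                       subject_ids=list(table["subject_id"]))


def _bias_field(grid: Grid, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias from low-order separable cosine components."""
    if amplitude == 0:
        return np.ones(grid.shape)
    coords = np.meshgrid(
        *[np.linspace(0.0, 1.0, s) for s in grid.shape], indexing="ij"
    )
    b = np.zeros(grid.shape)
    orders = [(i, j, k) for i in range(2) for j in range(2) for k in range(2)
              if (i, j, k) != (0, 0, 0)]
    coeffs = rng.normal(size=len(orders))
    for c, (i, j, k) in zip(coeffs, orders):
        b += (
            c
            * np.cos(np.pi * i * coords[0])
            * np.cos(np.pi * j * coords[1])
            * np.cos(np.pi * k * coords[2])
        )
    b /= np.abs(b).max()
    return 1.0 + amplitude * b


def apply_pipeline_transform(
    latent: VolumeStack,
    t: PipelineTransformSpec,
    seed: int = 0,
) -> VolumeStack:
    """Observe the latent stack through one pipeline's systematic distortions.

    output = Gaussian-smooth( shift( latent x gain x bias_field ) ) + noise.
    The bias field and displacement are fixed per pipeline (systematic);
    the additive noise is drawn per subject and voxel.  The identity
    transform returns the latent values unchanged.
    """
    from scipy import ndimage

    rng = _rng(seed, _STREAM_TRANSFORM, offset=t.seed_offset)
    bias = _bias_field(latent.grid, t.bias_field_amplitude, rng)
    shift = tuple(t.displacement_voxels)
    do_shift = any(abs(d) > 0 for d in shift)
    sigma_vox = None
    if t.extra_smooth_fwhm > 0:
        from .volio import GAUSSIAN_FWHM_FACTOR

        sigma_vox = [
            t.extra_smooth_fwhm / GAUSSIAN_FWHM_FACTOR / sp
            for sp in latent.grid.spacing
        ]
    out = np.empty_like(latent.data)
    for i in range(latent.n_subjects):
        vol = latent.unmask(i) * t.intensity_gain * bias
        if do_shift:
            # linear interpolation, clamped at the edges
            vol = ndimage.shift(vol, shift, order=1, mode="nearest")
        if sigma_vox is not None:
            vol = ndimage.gaussian_filter(vol, sigma_vox, mode="constant", cval=0.0)
        out[i] = vol[latent.mask]
    if t.noise_sd > 0:
        out += rng.normal(0.0, t.noise_sd, size=out.shape)
    return latent.with_data(out)


def generate_dataset(
    cohort: CohortSpec,
    effects: EffectSpec | None = None,
    transforms: Sequence[PipelineTransformSpec] | None = None,
    grid: Grid | None = None,
    mask: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a full multi-pipeline dataset (cohort -> latent -> pipelines).

    With ``out_dir`` set, writes per-pipeline 4D NIfTI stacks, the mask,
    the participants TSV, and a ground-truth JSON.
    """
    grid = grid or default_grid()
    mask = default_mask(grid) if mask is None else np.asarray(mask, dtype=bool)
    effects = effects if effects is not None else default_effects(grid, mask)
    transforms = tuple(transforms if transforms is not None else default_transforms())
    if len(transforms) < 2:
        raise InvalidSpecError("need >= 2 pipeline transforms")
    names = [t.name for t in transforms]
    if len(set(names)) != len(names):
        raise InvalidSpecError(f"duplicate transform names: {names}")

    table = make_cohort(cohort)
    latent = make_latent_stack(table, effects, grid, mask, seed=cohort.seed)
    per_pipeline = {
        t.name: apply_pipeline_transform(latent, t, seed=cohort.seed)
        for t in transforms
    }
    ds = SyntheticDataset(
        subject_table=table,
        latent=latent,
        per_pipeline=per_pipeline,
        effects=effects,
        transforms=transforms,
        cohort=cohort,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write NIfTI stacks, mask, participants TSV and truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = next(iter(ds.per_pipeline.values()))
    write_stack(first, out / f"{ds.pipeline_names[0]}_gmv.nii.gz",
                mask_path=out / "mask.nii.gz")
    for name in ds.pipeline_names[1:]:
        write_stack(ds.per_pipeline[name], out / f"{name}_gmv.nii.gz")
    ds.subject_table.to_csv(out / "participants.tsv", sep="\t", index=False)
    truth = {
        "seed": ds.cohort.seed,
        "n_subjects": ds.cohort.n_subjects,
        "sex_ratio": ds.cohort.sex_ratio,
        "age_range": list(ds.cohort.age_range),
        "subject_sd": ds.effects.subject_sd,
        "voxel_noise_sd": ds.effects.voxel_noise_sd,
        "sex_effects": [
            {"d": e.d, "n_voxels": int(np.asarray(e.region).sum())}
            for e in ds.effects.sex_effects
        ],
        "age_effects": [
            {"slope_per_year": e.slope_per_year,
             "n_voxels": int(np.asarray(e.region).sum())}
            for e in ds.effects.age_effects
        ],
        "transforms": [
            {
                "name": t.name,
                "intensity_gain": t.intensity_gain,
                "bias_field_amplitude": t.bias_field_amplitude,
                "displacement_voxels": list(t.displacement_voxels),
                "extra_smooth_fwhm": t.extra_smooth_fwhm,
                "noise_sd": t.noise_sd,
                "seed_offset": t.seed_offset,
            }
            for t in ds.transforms
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
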