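"""End-to-end orchestration: simulate -> similarity -> replicability ->
mass-univariate GLMs -> overlap -> MVPA, with a manifest and summary.

``run_full_analysis`` executes the stages in order on a synthetic
multi-pipeline dataset, writes TSV/JSON artifacts per stage (when an output
directory is configured), and records every stage's status, parameters and
seeds in a manifest.  A failure in one stage is recorded and does not
corrupt the outputs of earlier stages.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .massuni import build_design, fit_glm, permutation_fwe, threshold_voxel, \
    tmap_correlation_matrix
from .mvpa import LinearModelSpec, bootstrap_stability, evaluate_transfer, \
    split_matched, train_predictor, NoStableFeaturesError
from .overlap import overlap_taxonomy, render_overlap_table
from .replicability import pairwise_replicability
from .similarity import pipeline_similarity
from .synthetic import CohortSpec, default_effects, default_grid, default_mask, \
    default_transforms, generate_dataset
from .volio import Grid

log = logging.getLogger("morphdiverge")

__all__ = ["RunConfig", "run_full_analysis", "summarize"]


@dataclass
class RunConfig:
    """Declarative configuration of a full run (YAML-serializable).

    The desk-scale defaults (24x28x24 grid, n=120, n_perm=500, B=500) keep a
    complete four-pipeline run tractable on one CPU; the larger permutation
    and bootstrap counts used in large-cohort studies (5000) are plain
    configuration values.
    """

    seed: int = 0
    n_subjects: int = 120
    sex_ratio: float = 0.5
    age_range: tuple[float, float] = (18.0, 26.0)
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    pipelines: tuple[str, ...] = ()  # empty = all four default transforms
    models: tuple[str, ...] = ("sex", "age")
    regimes: tuple[str, ...] = ("voxel_p", "cluster_fwe", "tfce_fwe")
    voxel_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 500
    mvpa_B: int = 500
    mvpa_q: float = 0.05
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        mv = d.pop("mvpa", {})
        cfg = cls(
            seed=int(d.pop("seed", 0)),
            n_subjects=int(d.pop("n_subjects", 120)),
            sex_ratio=float(d.pop("sex_ratio", 0.5)),
            age_range=tuple(d.pop("age_range", (18.0, 26.0))),
            grid_shape=tuple(d.pop("grid", (24, 28, 24))),
            pipelines=tuple(d.pop("pipelines", ())),
            models=tuple(d.pop("models", ("sex", "age"))),
            regimes=tuple(d.pop("regimes", ("voxel_p", "cluster_fwe", "tfce_fwe"))),
            voxel_p=float(d.pop("voxel_p", 0.001)),
            alpha=float(d.pop("alpha", 0.05)),
            n_perm=int(d.pop("n_perm", 500)),
            mvpa_B=int(mv.get("B", 500)),
            mvpa_q=float(mv.get("q", 0.05)),
            out_dir=d.pop("out_dir", None),
        )
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "sex_ratio": self.sex_ratio,
            "age_range": list(self.age_range),
            "grid": list(self.grid_shape),
            "pipelines": list(self.pipelines),
            "models": list(self.models),
            "regimes": list(self.regimes),
            "voxel_p": self.voxel_p,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "mvpa": {"B": self.mvpa_B, "q": self.mvpa_q},
            "out_dir": self.out_dir,
        }


def _write_manifest(out: Path | None, manifest: dict) -> None:
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline-variability analysis on synthetic data.

    Returns the report bundle (a dict keyed by stage); with
    ``config.out_dir`` set, also writes per-stage TSV/JSON artifacts plus
    ``manifest.json`` and ``summary.txt``.
    """
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "morphdiverge",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stages": {},
    }
    bundle: dict[str, Any] = {"config": config, "manifest": manifest}

    def stage(name: str, fn):
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:  # surfaced with stage name; earlier outputs kept
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "error",
                                        "error": f"{type(exc).__name__}: {exc}"}
            _write_manifest(out, manifest)
            return None
        manifest["stages"][name] = {"status": "ok"}
        _write_manifest(out, manifest)
        log.info("stage %s: done", name)
        return result

    # ---- simulate -------------------------------------------------------
    def do_simulate():
        grid = Grid(shape=config.grid_shape, spacing=(2.0, 2.0, 2.0))
        mask = default_mask(grid)
        transforms = default_transforms()
        if config.pipelines:
            by_name = {t.name: t for t in transforms}
            missing = [p for p in config.pipelines if p not in by_name]
            if missing:
                raise ValueError(f"unknown pipelines {missing}; "
                                 f"known: {sorted(by_name)}")
            transforms = tuple(by_name[p] for p in config.pipelines)
        cohort = CohortSpec(n_subjects=config.n_subjects,
                            sex_ratio=config.sex_ratio,
                            age_range=config.age_range, seed=config.seed)
        ds = generate_dataset(cohort, default_effects(grid, mask), transforms,
                              grid=grid, mask=mask)
        if out is not None:
            ds.subject_table.to_csv(out / "participants.tsv", sep="\t",
                                    index=False)
        return ds

    ds = stage("simulate", do_simulate)
    if ds is None:
        bundle["summary"] = summarize(bundle)
        return bundle
    bundle["dataset"] = ds
    names = ds.pipeline_names

    # ---- similarity -----------------------------------------------------
    def do_similarity():
        sim = pipeline_similarity(ds.per_pipeline)
        if out is not None:
            sim.homogeneity.to_csv(out / "homogeneity.tsv", sep="\t")
            sim.between_same_subject.to_csv(out / "between_pipeline_z.tsv",
                                            sep="\t")
            anova = {"within": sim.within_anova.to_dict()}
            if sim.between_anova is not None:
                anova["between"] = sim.between_anova.to_dict()
            (out / "similarity_anova.json").write_text(
                json.dumps(anova, indent=2))
        return sim

    sim = stage("similarity", do_similarity)
    if sim is not None:
        bundle["similarity"] = sim

    # ---- replicability --------------------------------------------------
    def do_replicability():
        table = pairwise_replicability(ds.per_pipeline)
        if out is not None:
            table.to_csv(out / "replicability.tsv", sep="\t", index=False)
            i2c2_json = {
                f"{r.pipeline_a}|{r.pipeline_b}": {
                    "i2c2": r.i2c2, "category": r.category,
                }
                for r in table.itertuples()
            }
            (out / "i2c2.json").write_text(json.dumps(i2c2_json, indent=2))
        return table

    repl = stage("replicability", do_replicability)
    if repl is not None:
        bundle["replicability"] = repl

    # ---- mass-univariate GLMs -------------------------------------------
    def do_massuni():
        results: dict[str, Any] = {}
        for model in config.models:
            glms = {}
            masks: dict[str, dict[str, dict[str, np.ndarray]]] = {
                r: {"positive": {}, "negative": {}} for r in config.regimes
            }
            for name in names:
                design = build_design(ds.subject_table, model)
                glm = fit_glm(ds.per_pipeline[name], design)
                glms[name] = glm
                if "voxel_p" in config.regimes:
                    tv = threshold_voxel(glm, config.voxel_p)
                    for sign in ("positive", "negative"):
                        masks["voxel_p"][sign][name] = tv[sign].mask
                perm_regimes = tuple(r for r in config.regimes
                                     if r in ("cluster_fwe", "tfce_fwe"))
                if perm_regimes:
                    perm = permutation_fwe(
                        ds.per_pipeline[name], design, regimes=perm_regimes,
                        cluster_forming_p=config.voxel_p, alpha=config.alpha,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    for regime, by_sign in perm.items():
                        for sign in ("positive", "negative"):
                            masks[regime][sign][name] = by_sign[sign].mask
            corr = tmap_correlation_matrix(glms)
            results[model] = {"glms": glms, "masks": masks, "tmap_corr": corr}
            if out is not None:
                corr.to_csv(out / f"tmap_correlation_{model}.tsv", sep="\t")
        return results

    mass = stage("massuni", do_massuni)
    if mass is not None:
        bundle["massuni"] = mass

    # ---- overlap --------------------------------------------------------
    def do_overlap():
        if mass is None:
            raise RuntimeError("massuni stage unavailable")
        taxonomies: dict[str, Any] = {}
        for model, res in mass.items():
            for regime, by_sign in res["masks"].items():
                for sign, mask_dict in by_sign.items():
                    tax = overlap_taxonomy(mask_dict, sign=sign, regime=regime)
                    taxonomies[f"{model}:{regime}:{sign}"] = tax
            cols = {k.split(":", 1)[1]: v for k, v in taxonomies.items()
                    if k.startswith(f"{model}:")}
            table = render_overlap_table(cols)
            if out is not None:
                table.to_csv(out / f"overlap_{model}.tsv", sep="\t")
        return taxonomies

    taxes = stage("overlap", do_overlap)
    if taxes is not None:
        bundle["overlap"] = taxes

    # ---- MVPA -----------------------------------------------------------
    def do_mvpa():
        results: dict[str, Any] = {}
        plan = split_matched(ds.subject_table, seed=config.seed)
        t_index = ds.subject_table.set_index("subject_id")
        for model in config.models:
            task = "classify_sex" if model == "sex" else "regress_age"
            spec = LinearModelSpec(task=task)
            if task == "classify_sex":
                y_train = (t_index.loc[plan.train_ids, "sex"] == "M") \
                    .to_numpy(dtype=int)
                y_test = (t_index.loc[plan.test_ids, "sex"] == "M") \
                    .to_numpy(dtype=int)
            else:
                y_train = t_index.loc[plan.train_ids, "age"].to_numpy(dtype=float)
                y_test = t_index.loc[plan.test_ids, "age"].to_numpy(dtype=float)
            models_by_src = {}
            stability = {}
            for name in names:
                Xtr = ds.per_pipeline[name].select_subjects(plan.train_ids).data
                sel = bootstrap_stability(Xtr, y_train, spec, B=config.mvpa_B,
                                          q_threshold=config.mvpa_q,
                                          seed=config.seed)
                stability[name] = sel
                try:
                    models_by_src[name] = train_predictor(
                        Xtr, y_train, spec,
                        voxel_idx=np.flatnonzero(sel.selected),
                        source=name, seed=config.seed,
                    )
                except NoStableFeaturesError:
                    log.warning("pipeline %s: no stable features for %s",
                                name, model)
            test_stacks = {
                name: ds.per_pipeline[name].select_subjects(plan.test_ids)
                for name in names
            }
            transfer = (evaluate_transfer(models_by_src, test_stacks, y_test)
                        if models_by_src else None)
            results[model] = {"split": plan, "stability": stability,
                              "models": models_by_src, "transfer": transfer}
            if out is not None and transfer is not None:
                transfer.performance.to_csv(out / f"transfer_{model}.tsv",
                                            sep="\t")
                if transfer.effect_size is not None:
                    transfer.effect_size.to_csv(
                        out / f"transfer_{model}_cohens_d.tsv", sep="\t")
        return results

    mv = stage("mvpa", do_mvpa)
    if mv is not None:
        bundle["mvpa"] = mv

    bundle["summary"] = summarize(bundle)
    if out is not None:
        (out / "summary.txt").write_text(bundle["summary"])
    return bundle


def summarize(bundle: dict[str, Any]) -> str:
    """One-page human-readable summary of a report bundle.

    Missing stages are marked absent rather than raising.
    """
    lines: list[str] = ["morphdiverge report", "=" * 19, ""]

    sim = bundle.get("similarity")
    lines.append("Spatial similarity")
    if sim is None:
        lines.append("  [absent]")
    else:
        a = sim.within_anova
        lines.append(
            f"  within-pipeline homogeneity RM-ANOVA: "
            f"F({a.df1},{a.df2}) = {a.F:.3f}, p = {a.p:.3g}"
        )
        means = sim.homogeneity.mean()
        for name, m in means.items():
            lines.append(f"    mean homogeneity z [{name}]: {m:.3f}")
        lines.append(
            "  mean same-subject between-pipeline z: "
            f"{sim.between_same_subject.mean().mean():.3f}"
        )
    lines.append("")

    repl = bundle.get("replicability")
    lines.append("Replicability (I2C2 per pipeline pair)")
    if repl is None:
        lines.append("  [absent]")
    else:
        if (repl["i2c2"] > 0.999999).all():
            lines.append("  full agreement: all pairwise I2C2 = 1")
        for r in repl.itertuples():
            lines.append(
                f"  {r.pipeline_a} vs {r.pipeline_b}: "
                f"I2C2 = {r.i2c2:.3f} ({r.category}), "
                f"mean voxel ICC = {r.mean_icc:.3f}"
            )
    lines.append("")

    taxes = bundle.get("overlap")
    lines.append("Overlap taxonomy (percent of union, exclusive subsets)")
    if taxes is None:
        lines.append("  [absent]")
    else:
        for key, tax in taxes.items():
            if tax.union_size == 0:
                lines.append(f"  {key}: empty union (no significant voxels)")
                continue
            full = frozenset(tax.pipelines)
            if tax.subsets.get(full, (0, 0.0))[1] >= 100.0:
                lines.append(f"  {key}: full agreement (100% in "
                             f"{' ∩ '.join(tax.pipelines)})")
                continue
            top = sorted(tax.subsets.items(), key=lambda kv: -kv[1][1])[:3]
            parts = ", ".join(
                f"{_label(s, tax.pipelines)} {pct:.2f}%" for s, (_, pct) in top
            )
            lines.append(f"  {key} (union {tax.union_size} voxels): {parts}")
    lines.append("")

    mv = bundle.get("mvpa")
    lines.append("MVPA transfer")
    if mv is None:
        lines.append("  [absent]")
    else:
        for model, res in mv.items():
            tm = res["transfer"]
            if tm is None:
                lines.append(f"  {model}: no pipeline produced stable features")
                continue
            metric = "accuracy" if tm.task == "classify_sex" else "r"
            lines.append(f"  {model} ({metric}, source rows x target columns, "
                         f"n_test = {tm.n_test}):")
            for row in tm.performance.index:
                vals = " ".join(
                    f"{tm.performance.loc[row, c]:.2f}"
                    for c in tm.performance.columns
                )
                lines.append(f"    {row:>14}: {vals}")
    lines.append("")
    return "\n".join(lines)


def _label(subset: frozenset, pipelines: tuple[str, ...]) -> str:
    ordered = [p for p in pipelines if p in subset]
    return ordered[0] + " (unique)" if len(ordered) == 1 else " ∩ ".join(ordered)
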