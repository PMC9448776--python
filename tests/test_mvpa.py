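import numpy as np
import pandas as pd
import pytest

from morphdiverge.mvpa import (
    LinearModelSpec,
    NoStableFeaturesError,
    bootstrap_stability,
    cohens_d,
    evaluate_transfer,
    split_matched,
    train_predictor,
)
from morphdiverge.synthetic import CohortSpec, make_cohort
from morphdiverge.volio import Grid, VolumeStack


def _stack(data, ids=None):
    data = np.asarray(data, dtype=float)
    grid = Grid(shape=(data.shape[1], 1, 1))
    return VolumeStack(data=data, grid=grid, mask=np.ones(grid.shape, bool),
                       subject_ids=list(ids) if ids is not None else [])


class TestSplitMatched:
    def test_200_subjects_split_100_100_with_50f_each(self):
        table = make_cohort(CohortSpec(n_subjects=200, sex_ratio=0.5, seed=7))
        plan = split_matched(table, seed=0)
        assert len(plan.train_ids) == 100 and len(plan.test_ids) == 100
        assert plan.report["train_sex_counts"]["F"] == 50
        assert plan.report["test_sex_counts"]["F"] == 50

    def test_smallest_case(self):
        table = pd.DataFrame({
            "subject_id": list("abcd"), "sex": ["F", "F", "M", "M"],
            "age": [20.0, 21, 22, 23], "tiv": [1400.0] * 4,
        })
        plan = split_matched(table, seed=1)
        assert len(plan.train_ids) == 2 and len(plan.test_ids) == 2
        assert plan.report["train_sex_counts"] == {"F": 1, "M": 1}

    def test_age_matching_by_alternation(self):
        """Mean-age gap below half a year at n=200 with uniform ages."""
        gaps = []
        for seed in range(10):
            table = make_cohort(CohortSpec(n_subjects=200, seed=seed))
            plan = split_matched(table, seed=seed)
            gaps.append(abs(plan.report["train_mean_age"]
                            - plan.report["test_mean_age"]))
        assert max(gaps) < 0.5

    def test_single_sex_rejected(self):
        table = pd.DataFrame({
            "subject_id": list("abcd"), "sex": ["F"] * 4,
            "age": [20.0, 21, 22, 23], "tiv": [1400.0] * 4,
        })
        with pytest.raises(ValueError):
            split_matched(table, seed=0)


class TestBootstrapStability:
    def test_same_seed_identical_mask(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.integers(0, 2, 40)
        spec = LinearModelSpec(task="classify_sex")
        a = bootstrap_stability(X, y, spec, B=100, seed=5)
        b = bootstrap_stability(X, y, spec, B=100, seed=5)
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_array_equal(a.z, b.z)

    def test_null_selection_rate_controlled(self, rng):
        """Permuted labels: selected fraction stays near the FDR level."""
        X = rng.normal(size=(60, 80))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        y = rng.permutation(y)
        sel = bootstrap_stability(X, y, LinearModelSpec(task="classify_sex"),
                                  B=500, q_threshold=0.05, seed=2)
        assert sel.n_selected / X.shape[1] <= 2 * 0.05

    def test_planted_feature_recovered(self, rng):
        """One d=3 voxel among 50 noise voxels is selected in >=95% of runs."""
        hits = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            X = r.normal(size=(40, 51))
            X[y == 1, 0] += 3.0
            sel = bootstrap_stability(X, y, LinearModelSpec(task="classify_sex"),
                                      B=100, q_threshold=0.05, seed=rep)
            hits += int(sel.selected[0])
        assert hits >= 48

    def test_too_small_training_set_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_stability(rng.normal(size=(4, 5)),
                                np.array([0, 1, 0, 1]),
                                LinearModelSpec(task="classify_sex"), B=100)


class TestTrainPredictor:
    def test_separable_toy_training_accuracy_one(self):
        X = np.array([[1.0, 0], [2.0, 0], [-1.0, 0], [-2.0, 0]])
        y = np.array([1, 1, 0, 0])
        m = train_predictor(X, y, LinearModelSpec(task="classify_sex", folds=2))
        assert np.array_equal(m.predict(X), y)

    def test_permuted_labels_cv_near_chance(self, rng):
        X = rng.normal(size=(100, 40))
        y = rng.permutation(np.r_[np.zeros(50, int), np.ones(50, int)])
        m = train_predictor(X, y, LinearModelSpec(task="classify_sex"))
        # binomial 95% band around 0.5 at n=100
        assert abs(m.cv_score - 0.5) < 1.96 * np.sqrt(0.25 / 100) + 0.08

    def test_svr_on_exact_linear_response(self, rng):
        X = rng.normal(size=(60, 5))
        w = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ w + 40.0
        m = train_predictor(X, y, LinearModelSpec(task="regress_age"))
        assert m.cv_score > 0.99

    def test_zero_selected_voxels_is_explicit_error(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        with pytest.raises(NoStableFeaturesError):
            train_predictor(X, y, LinearModelSpec(task="classify_sex"),
                            voxel_idx=np.array([], dtype=int))


class TestTransfer:
    def _sex_setup(self, rng, n=60, v=50, d=1.5, region=20):
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(n, v))
        X[y == 1, :region] += d / np.sqrt(region) * np.sqrt(region)  # d per voxel
        return X, y

    def test_within_pipeline_accuracy_strong_signal(self, rng):
        accs = []
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            Xtr, ytr = self._sex_setup(r)
            Xte, yte = self._sex_setup(r)
            m = train_predictor(Xtr, ytr, LinearModelSpec(task="classify_sex"),
                                source="p")
            tm = evaluate_transfer({"p": m}, {"p": _stack(Xte)}, yte)
            accs.append(tm.performance.loc["p", "p"])
        assert np.mean(accs) >= 0.9

    def test_equal_group_means_give_zero_cohens_d(self):
        assert cohens_d(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == 0.0

    def test_positive_gain_scales_margins_exactly(self, rng):
        """A positive gain on the target rescales zero-intercept decisions
        and can flip labels only inside the frozen-center offset band."""
        Xtr, ytr = self._sex_setup(rng)
        Xte, yte = self._sex_setup(rng)
        m = train_predictor(Xtr, ytr, LinearModelSpec(task="classify_sex"),
                            source="p")
        dv1 = m.decision_values(Xte)
        dv2 = m.decision_values(1.1 * Xte)
        offset = 0.1 * float(m.center @ m.weights)
        np.testing.assert_allclose(dv2, 1.1 * dv1 + offset, atol=1e-9)
        base = m.predict(Xte)
        scaled = m.predict(1.1 * Xte)
        flipped = base != scaled
        # any flip must sit inside the offset band |1.1 dv1| <= |offset|
        assert np.all(np.abs(1.1 * dv1[flipped]) <= abs(offset) + 1e-9)

    def test_cross_pipeline_degrades_with_divergence(self, small_grid,
                                                     small_mask):
        """Within-pipeline accuracy >= cross-pipeline accuracy on average
        when the pipelines' transforms differ."""
        from morphdiverge.synthetic import (
            EffectSpec, PipelineTransformSpec, SexEffect, box_region,
            generate_dataset)

        region = box_region(small_grid, (3, 5, 5), (3, 3, 3)) & small_mask
        effects = EffectSpec(sex_effects=(SexEffect(region, d=1.5),),
                             subject_sd=0.03, voxel_noise_sd=0.05)
        transforms = (
            PipelineTransformSpec("clean", noise_sd=0.01, seed_offset=0),
            PipelineTransformSpec("dist", intensity_gain=0.9,
                                  bias_field_amplitude=0.1,
                                  displacement_voxels=(0.5, 0.5, 0.4),
                                  extra_smooth_fwhm=3.0, noise_sd=0.08,
                                  seed_offset=1),
        )
        spec = LinearModelSpec(task="classify_sex")
        within, cross = [], []
        tm = None
        for rep in range(5):
            ds = generate_dataset(CohortSpec(n_subjects=60, seed=500 + rep),
                                  effects, transforms, grid=small_grid,
                                  mask=small_mask)
            plan = split_matched(ds.subject_table, seed=rep)
            t_index = ds.subject_table.set_index("subject_id")
            ytr = (t_index.loc[plan.train_ids, "sex"] == "M").to_numpy(int)
            yte = (t_index.loc[plan.test_ids, "sex"] == "M").to_numpy(int)
            models, test_stacks = {}, {}
            for name, stack in ds.per_pipeline.items():
                Xtr = stack.select_subjects(plan.train_ids).data
                models[name] = train_predictor(Xtr, ytr, spec, source=name)
                test_stacks[name] = stack.select_subjects(plan.test_ids)
            tm = evaluate_transfer(models, test_stacks, yte)
            perf = tm.performance.to_numpy()
            within.append(np.diag(perf).mean())
            cross.append(perf[~np.eye(len(perf), dtype=bool)].mean())
        assert np.mean(within) > np.mean(cross)
        assert tm.effect_size is not None
        assert np.isfinite(tm.effect_size.to_numpy(dtype=float)).all()

    def test_no_leakage_test_mutation_cannot_change_model(self, rng):
        """Centering/weights are frozen before any target data is seen."""
        Xtr, ytr = self._sex_setup(rng)
        m = train_predictor(Xtr, ytr, LinearModelSpec(task="classify_sex"),
                            source="p")
        w_before, c_before = m.weights.copy(), m.center.copy()
        Xte, yte = self._sex_setup(rng)
        evaluate_transfer({"p": m}, {"p": _stack(Xte * 100 + 5)}, yte)
        np.testing.assert_array_equal(m.weights, w_before)
        np.testing.assert_array_equal(m.center, c_before)

    def test_model_round_trip_serialization(self, tmp_path, rng):
        from morphdiverge.mvpa import FittedPredictor

        Xtr, ytr = self._sex_setup(rng)
        m = train_predictor(Xtr, ytr, LinearModelSpec(task="classify_sex"),
                            source="p")
        m.save(tmp_path / "model.json")
        m2 = FittedPredictor.load(tmp_path / "model.json")
        Xte, _ = self._sex_setup(rng)
        np.testing.assert_allclose(m.decision_values(Xte),
                                   m2.decision_values(Xte), atol=1e-12)
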