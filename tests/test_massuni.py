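import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphdiverge.massuni import (
    DesignError,
    DesignMatrix,
    TFCEParams,
    build_design,
    cluster_fwe,
    fit_glm,
    permutation_fwe,
    tfce_transform,
    threshold_voxel,
    tmap_correlation_matrix,
    unthresholded_correlation,
)
from morphdiverge.synthetic import (
    CohortSpec,
    EffectSpec,
    SexEffect,
    box_region,
    make_cohort,
    make_latent_stack,
)
from morphdiverge.volio import Grid, VolumeStack


def _stack(data):
    data = np.asarray(data, dtype=float)
    grid = Grid(shape=(data.shape[1], 1, 1))
    return VolumeStack(data=data, grid=grid, mask=np.ones(grid.shape, bool))


def _group_design(n_per_group):
    g = np.r_[np.zeros(n_per_group), np.ones(n_per_group)]
    X = np.column_stack([np.ones(2 * n_per_group), g])
    return DesignMatrix(X=X, columns=["intercept", "group"],
                        contrast=np.array([0.0, 1.0]))


class TestGLM:
    def test_two_sample_t_closed_form(self):
        """{1,2,3} vs {4,5,6}: pooled-variance t = 3/(1*sqrt(2/3)) = 3.674..."""
        y = np.array([1.0, 2, 3, 4, 5, 6])[:, None]
        glm = fit_glm(_stack(y), _group_design(3))
        expected = 3.0 / np.sqrt(2.0 / 3.0)
        assert glm.t[0] == pytest.approx(expected, abs=1e-10)
        # scipy cross-check
        t_ref, _ = stats.ttest_ind(y[3:, 0], y[:3, 0])
        assert glm.t[0] == pytest.approx(t_ref, abs=1e-10)

    def test_noiseless_regression_beta_exact_t_guarded(self):
        ages = np.array([20.0, 25, 30, 35, 40, 45])
        X = np.column_stack([np.ones(6), ages])
        design = DesignMatrix(X=X, columns=["intercept", "age"],
                              contrast=np.array([0.0, 1.0]))
        glm = fit_glm(_stack((2.0 * ages)[:, None]), design)
        assert glm.beta[1, 0] == pytest.approx(2.0, abs=1e-10)
        # divergence guard: t is well-defined (possibly inf), never NaN
        assert not np.isnan(glm.t[0]) and glm.t[0] > 1e6

    def test_covariate_rescaling_leaves_t_unchanged(self, rng):
        n = 30
        g = rng.integers(0, 2, n).astype(float)
        cov = rng.normal(size=n)
        y = rng.normal(size=(n, 50))
        X1 = np.column_stack([np.ones(n), g, cov])
        X2 = np.column_stack([np.ones(n), g, cov * 1000.0])
        c = np.array([0.0, 1.0, 0.0])
        d1 = DesignMatrix(X=X1, columns=["i", "g", "c"], contrast=c)
        d2 = DesignMatrix(X=X2, columns=["i", "g", "c"], contrast=c)
        np.testing.assert_allclose(fit_glm(_stack(y), d1).t,
                                   fit_glm(_stack(y), d2).t, atol=1e-9)

    def test_constant_response_shift_invariance_and_sign_symmetry(self, rng):
        n = 20
        g = np.r_[np.zeros(10), np.ones(10)]
        X = np.column_stack([np.ones(n), g])
        d = DesignMatrix(X=X, columns=["i", "g"], contrast=np.array([0.0, 1.0]))
        y = rng.normal(size=(n, 40))
        t1 = fit_glm(_stack(y), d).t
        t2 = fit_glm(_stack(y + 5.0), d).t
        np.testing.assert_allclose(t1, t2, atol=1e-9)
        t3 = fit_glm(_stack(-y), d).t
        np.testing.assert_allclose(t3, -t1, atol=1e-9)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10), 2 * np.arange(10)])
        with pytest.raises(DesignError, match="rank deficient"):
            DesignMatrix(X=X, columns=["intercept", "a", "b"],
                         contrast=np.array([0, 1, 0.0]))

    def test_build_design_sex_model(self):
        table = make_cohort(CohortSpec(n_subjects=20, seed=1))
        d = build_design(table, "sex")
        assert d.columns == ["intercept", "sex", "age", "tiv"]
        assert d.contrast[1] == 1.0 and d.contrast.sum() == 1.0


class TestVoxelThreshold:
    def test_zero_map_empty_masks(self):
        glm = fit_glm(_stack(np.zeros((8, 10))), _group_design(4))
        out = threshold_voxel(glm, 0.001)
        assert out["positive"].n_voxels == 0 and out["negative"].n_voxels == 0

    def test_matches_t_cdf_oracle(self, rng):
        y = rng.normal(size=(12, 20))
        glm = fit_glm(_stack(y), _group_design(6))
        out = threshold_voxel(glm, 0.05)
        pvals = stats.t.sf(glm.t, glm.df)
        np.testing.assert_array_equal(out["positive"].mask.ravel()[:20],
                                      pvals < 0.05)
        np.testing.assert_array_equal(out["negative"].mask.ravel()[:20],
                                      stats.t.cdf(glm.t, glm.df) < 0.05)

    def test_far_tail_included(self, rng):
        y = rng.normal(size=(40, 5))
        y[20:, 2] += 10.0  # enormous effect
        glm = fit_glm(_stack(y), _group_design(20))
        out = threshold_voxel(glm, 0.001)
        assert out["positive"].mask.ravel()[2]


class TestTFCE:
    def test_zero_map_maps_to_zero(self):
        assert np.all(tfce_transform(np.zeros((5, 5, 5))) == 0)

    def test_scaling_law(self, rng):
        """TFCE of c*map equals c^(H+1) * TFCE(map) with the relative dh rule."""
        vol = np.abs(rng.normal(size=(8, 8, 8)))
        params = TFCEParams(E=0.5, H=2.0, n_steps=1000)
        a = tfce_transform(vol, params)
        b = tfce_transform(3.0 * vol, params)
        nz = a > 0
        np.testing.assert_allclose(b[nz] / a[nz], 3.0 ** 3.0, rtol=0.01)

    def test_1d_plateau_matches_integral_oracle(self):
        """Three-voxel plateau of height 2: TFCE = int_0^2 3^E h^H dh."""
        x = np.zeros(9)
        x[3:6] = 2.0
        params = TFCEParams(E=0.5, H=2.0, n_steps=20000)
        out = tfce_transform(x, params)
        # oracle: numeric integral of e(h)^0.5 * h^2 with e(h)=3 for h<=2
        hs = np.linspace(1e-6, 2.0, 200001)
        expected = np.trapezoid(np.sqrt(3.0) * hs**2, hs)
        assert out[4] == pytest.approx(expected, rel=0.01)
        assert np.all(out[3:6] == out[4])
        assert np.all(out[x == 0] == 0)

    def test_monotone_in_pointwise_order(self, rng):
        small = np.abs(rng.normal(size=(6, 6, 6)))
        big = small + np.abs(rng.normal(size=(6, 6, 6)))
        params = TFCEParams(n_steps=200)
        a = tfce_transform(small * (big.max() / small.max()), params)
        # compare on a common dh grid: scale both to the same max first
        b = tfce_transform(big, params)
        assert np.all(b + 1e-12 >= a * 0)  # non-negativity
        # direct monotonicity with a shared absolute grid: raise one voxel
        bumped = small.copy()
        bumped[3, 3, 3] = small.max()  # keeps hmax (and dh) unchanged
        a0 = tfce_transform(small, params)
        a1 = tfce_transform(bumped, params)
        assert np.all(a1 + 1e-12 >= a0)

    def test_connectivity_changes_extent(self):
        vol = np.zeros((5, 5, 5))
        vol[1, 1, 1] = vol[2, 2, 2] = 1.0  # diagonal neighbors
        t26 = tfce_transform(vol, TFCEParams(connectivity=26, n_steps=50))
        t6 = tfce_transform(vol, TFCEParams(connectivity=6, n_steps=50))
        assert t26[1, 1, 1] > t6[1, 1, 1]  # joined under 26, split under 6


def _null_stack_and_design(n=16, seed=0):
    grid = Grid(shape=(12, 12, 12))
    mask = np.ones(grid.shape, bool)
    table = make_cohort(CohortSpec(n_subjects=n, seed=seed))
    stack = make_latent_stack(table, EffectSpec(subject_sd=0.0,
                                                voxel_noise_sd=0.05),
                              grid, mask, seed=seed)
    return stack, build_design(table, "sex")


class TestPermutationFWE:
    def test_p_lower_bound_is_one_over_nperm_plus_one(self):
        stack, design = _null_stack_and_design()
        res = permutation_fwe(stack, design, n_perm=100, seed=1,
                              signs=("positive",))
        cl = res["cluster_fwe"]["positive"].clusters
        if cl is not None and len(cl):
            assert (cl["p_fwe"] >= 1.0 / 101.0).all()
        assert res["cluster_fwe"]["positive"].params["n_perm"] == 100

    def test_planted_block_recovered_by_both_regimes(self):
        """Strong planted effect: surviving cluster covers >=90% of the block."""
        grid = Grid(shape=(12, 12, 12))
        mask = np.ones(grid.shape, bool)
        region = box_region(grid, (6, 6, 6), (4, 4, 4))
        table = make_cohort(CohortSpec(n_subjects=40, seed=3))
        effects = EffectSpec(sex_effects=(SexEffect(region, d=2.0),),
                             subject_sd=0.0, voxel_noise_sd=0.05)
        # d applies to the region mean; make per-voxel effect d=2 directly
        stack = make_latent_stack(table, effects, grid, mask, seed=3)
        male = (table["sex"] == "M").to_numpy()
        delta = 2.0 * 0.05  # per-voxel standardized d = 2
        boost = np.where(region[mask], delta, 0.0)
        data = stack.data.copy()
        data[male] += boost / 2
        data[~male] -= boost / 2
        stack = stack.with_data(data)
        design = build_design(table, "sex")
        res = permutation_fwe(stack, design, n_perm=200, seed=4,
                              signs=("positive",))
        for regime in ("cluster_fwe", "tfce_fwe"):
            hit = res[regime]["positive"].mask & region
            assert hit.sum() >= 0.9 * region.sum(), regime

    def test_sign_symmetry_of_masks(self):
        stack, design = _null_stack_and_design(n=20, seed=7)
        res_pos = cluster_fwe(stack, design, n_perm=100, seed=5)
        neg = stack.with_data(-stack.data)
        res_neg = cluster_fwe(neg, design, n_perm=100, seed=5)
        np.testing.assert_array_equal(res_pos["positive"].mask,
                                      res_neg["negative"].mask)
        np.testing.assert_array_equal(res_pos["negative"].mask,
                                      res_neg["positive"].mask)


class TestUnthresholdedCorrelation:
    def test_self_and_negation(self, rng):
        y = rng.normal(size=(12, 30))
        glm = fit_glm(_stack(y), _group_design(6))
        assert unthresholded_correlation(glm, glm) == pytest.approx(1.0)
        glm_neg = fit_glm(_stack(-y), _group_design(6))
        assert unthresholded_correlation(glm, glm_neg) == pytest.approx(-1.0)

    def test_matches_direct_oracle_and_matrix(self, rng):
        ya, yb = rng.normal(size=(2, 12, 30))
        ga = fit_glm(_stack(ya), _group_design(6))
        gb = fit_glm(_stack(yb), _group_design(6))
        expected = np.corrcoef(ga.t, gb.t)[0, 1]
        assert unthresholded_correlation(ga, gb) == pytest.approx(expected,
                                                                  abs=1e-12)
        mat = tmap_correlation_matrix({"a": ga, "b": gb})
        assert mat.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert mat.loc["a", "a"] == 1.0
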