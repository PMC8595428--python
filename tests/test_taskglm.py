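"""Block-design GLM: regressors, HRF, OLS fit, paired and unpaired contrasts."""

import numpy as np
import pytest
from scipy import stats

from hyperbold.taskglm import (
    BlockDesign,
    block_regressor,
    build_design,
    convolve_regressor,
    fit_glm,
    hrf_kernel,
    paired_contrast,
    t_to_z,
    unpaired_contrast,
)

from conftest import make_series


@pytest.fixture
def study_design():
    """17 alternating blocks, 18 s opaque / 12 s transparent, TR 1.5 s."""
    return BlockDesign.alternating()


class TestBlockDesign:
    def test_study_design_spans_172_volumes(self, study_design):
        assert study_design.n_volumes == 172
        assert study_design.n_blocks == 17

    def test_stimulus_indicator_sums_to_64(self, study_design):
        """8 transparent blocks x (12 s / 1.5 s) = 64 stimulus volumes."""
        ind = block_regressor(study_design, "transparent")
        assert ind.sum() == 64
        assert len(ind) == 172

    def test_single_block_all_ones(self):
        design = BlockDesign(blocks=[("on", 12.0)], tr_s=1.5)
        np.testing.assert_array_equal(block_regressor(design, "on"), np.ones(8))

    def test_non_commensurate_duration_rejected(self):
        with pytest.raises(ValueError, match="multiple of TR"):
            BlockDesign(blocks=[("on", 10.0)], tr_s=1.5)

    def test_unknown_condition_rejected(self, study_design):
        with pytest.raises(ValueError, match="unknown condition"):
            block_regressor(study_design, "nope")


class TestHrf:
    def test_unit_peak_at_four_seconds(self):
        h = hrf_kernel(tr_s=0.5)
        t = np.arange(len(h)) * 0.5
        assert h[t == 4.0][0] == pytest.approx(1.0)
        assert h.max() == pytest.approx(1.0)

    def test_zero_at_onset(self):
        assert hrf_kernel(1.5)[0] == 0.0

    def test_truncated_at_small_amplitude(self):
        h = hrf_kernel(1.5)
        assert h[-1] >= 1e-4
        # the next sample would fall below the cutoff
        t_next = len(h) * 1.5
        assert (t_next**4) * np.exp(-t_next) / (4**4 * np.exp(-4)) < 1e-4

    def test_boxcar_convolution_matches_brute_force(self):
        """12-s boxcar convolved with the kernel vs an explicit double sum."""
        tr = 1.5
        box = np.zeros(40)
        box[5:13] = 1.0  # 8 volumes = 12 s
        h = hrf_kernel(tr)
        result = convolve_regressor(box, tr)
        oracle = np.array(
            [sum(box[k] * h[i - k] for k in range(len(box)) if 0 <= i - k < len(h))
             for i in range(len(box))]
        )
        np.testing.assert_allclose(result, oracle, rtol=1e-12)


class TestBuildDesign:
    def test_study_design_composition(self, study_design, rng):
        motion = rng.normal(0, 0.01, size=(172, 6))
        X = build_design(study_design, motion=motion, detrend_order=5)
        # 2 conditions + 6 polynomials + k drift cosines + 6 motion
        n_drift = sum(1 for lab in X.labels if lab.startswith("drift"))
        assert len(X.labels) == 2 + 6 + n_drift + 6
        assert np.linalg.matrix_rank(X.matrix) == len(X.labels)
        assert X.df_residual == 172 - len(X.labels)
        assert X.condition_columns == ["cond_opaque", "cond_transparent"]

    def test_zero_motion_columns_dropped_with_warning(self, study_design):
        motion = np.zeros((172, 6))
        with pytest.warns(UserWarning, match="constant"):
            X = build_design(study_design, motion=motion)
        assert not any(lab.startswith("motion") for lab in X.labels)
        assert np.linalg.matrix_rank(X.matrix) == len(X.labels)

    def test_column_permutation_leaves_condition_effects_unchanged(self, study_design, rng):
        X = build_design(study_design, detrend_order=3)
        n = study_design.n_volumes
        y = rng.normal(size=n) + 2.0 * X.column("cond_transparent")
        series = make_series(y.reshape(1, 1, 1, n))
        fit1 = fit_glm(series, X)
        perm = rng.permutation(len(X.labels))
        from hyperbold.taskglm import DesignMatrix

        Xp = DesignMatrix(
            matrix=X.matrix[:, perm],
            labels=[X.labels[i] for i in perm],
            condition_columns=X.condition_columns,
            df_residual=X.df_residual,
        )
        fit2 = fit_glm(series, Xp)
        assert fit1.coefficients["cond_transparent"][0, 0, 0] == pytest.approx(
            fit2.coefficients["cond_transparent"][0, 0, 0], rel=1e-10
        )

    def test_motion_wrong_shape_rejected(self, study_design):
        with pytest.raises(ValueError, match="6 columns"):
            build_design(study_design, motion=np.zeros((172, 4)))


class TestFitGlm:
    def test_noise_free_beta_recovered_exactly(self, study_design):
        X = build_design(study_design, detrend_order=2)
        y = 2.0 * X.column("cond_transparent") + 50.0
        series = make_series(np.broadcast_to(y, (2, 2, 1, 172)).copy())
        fit = fit_glm(series, X)
        np.testing.assert_allclose(fit.coefficients["cond_transparent"], 2.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        """10-timepoint single-voxel fit vs the explicit (X'X)^-1 X'y solve."""
        from hyperbold.taskglm import DesignMatrix

        n = 10
        mat = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        X = DesignMatrix(matrix=mat, labels=["c0", "c1", "c2"],
                         condition_columns=["c1"], df_residual=n - 3)
        y = rng.normal(size=n)
        fit = fit_glm(make_series(y.reshape(1, 1, 1, n)), X)
        beta_oracle = np.linalg.solve(mat.T @ mat, mat.T @ y)
        for j, lab in enumerate(X.labels):
            assert fit.coefficients[lab][0, 0, 0] == pytest.approx(beta_oracle[j], rel=1e-10)
        resid = y - mat @ beta_oracle
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(mat.T @ mat)[1, 1])
        assert fit.t_values["c1"][0, 0, 0] == pytest.approx(beta_oracle[1] / se, rel=1e-10)

    def test_null_t_values_follow_student_t(self, rng, study_design):
        """On pure noise the condition t-statistic is Student t(df_residual)."""
        X = build_design(study_design, detrend_order=5)
        n_vox = 4000
        data = rng.normal(size=(n_vox, 1, 1, 172))
        fit = fit_glm(make_series(data), X)
        tvals = fit.t_values["cond_transparent"].ravel()
        _, p = stats.kstest(tvals, "t", args=(fit.df_residual,))
        assert p > 0.01

    def test_nuisance_signal_leaves_condition_t_unchanged(self, rng, study_design):
        """Adding any combination of nuisance columns does not move condition t."""
        X = build_design(study_design, detrend_order=4)
        n = study_design.n_volumes
        y = rng.normal(size=n)
        nuisance = 3.0 * X.column("poly2") - 1.5 * X.column("drift_cos1")
        f1 = fit_glm(make_series(y.reshape(1, 1, 1, n)), X)
        f2 = fit_glm(make_series((y + nuisance).reshape(1, 1, 1, n)), X)
        assert f1.t_values["cond_transparent"][0, 0, 0] == pytest.approx(
            f2.t_values["cond_transparent"][0, 0, 0], rel=1e-8
        )


class TestPairedContrast:
    def test_df_and_critical_value_for_ten_runs(self, rng):
        maps = [rng.normal(size=(3, 3, 2)) for _ in range(20)]
        res = paired_contrast(maps[:10], maps[10:])
        assert res.df == 9
        assert stats.t.ppf(0.975, 9) == pytest.approx(2.2622, abs=1e-4)

    def test_identical_maps_give_zero_t(self, rng):
        maps = [rng.normal(size=(2, 2, 2)) for _ in range(5)]
        res = paired_contrast(maps, [m.copy() for m in maps])
        # zero difference everywhere: t is 0/0, reported as NaN, effect 0
        np.testing.assert_allclose(res.effect_map, 0.0, atol=1e-12)

    def test_matches_scipy_paired_oracle(self, rng):
        stim = [np.full((1, 1, 1), v) for v in rng.normal(1.0, 0.5, 10)]
        base = [np.full((1, 1, 1), v) for v in rng.normal(0.0, 0.5, 10)]
        res = paired_contrast(stim, base)
        s = np.array([m.item() for m in stim])
        b = np.array([m.item() for m in base])
        t_oracle = stats.ttest_rel(s, b).statistic
        assert res.t_map.item() == pytest.approx(t_oracle, rel=1e-10)

    def test_equals_one_sample_t_on_differences(self, rng):
        stim = [rng.normal(size=(2, 2, 1)) for _ in range(6)]
        base = [rng.normal(size=(2, 2, 1)) for _ in range(6)]
        res = paired_contrast(stim, base)
        d = np.stack(stim) - np.stack(base)
        t_one = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(6))
        np.testing.assert_allclose(res.t_map, t_one, rtol=1e-10)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError, match="2 runs"):
            paired_contrast([np.zeros((2, 2, 2))], [np.zeros((2, 2, 2))])


class TestUnpairedContrast:
    def test_matches_scipy_pooled_oracle(self, rng):
        a = [np.full((1, 1, 1), v) for v in rng.normal(1.0, 1.0, 5)]
        b = [np.full((1, 1, 1), v) for v in rng.normal(0.0, 1.0, 5)]
        res = unpaired_contrast(a, b)
        av = np.array([m.item() for m in a])
        bv = np.array([m.item() for m in b])
        t_oracle = stats.ttest_ind(av, bv, equal_var=True).statistic
        assert res.t_map.item() == pytest.approx(t_oracle, rel=1e-10)
        assert res.df == 8

    def test_null_rejection_rate_near_nominal(self, rng):
        """Equal-mean paradigms: ~5% of voxels exceed |z| = 1.96."""
        n_vox = 20000
        a = [rng.normal(size=(n_vox, 1, 1)) for _ in range(10)]
        b = [rng.normal(size=(n_vox, 1, 1)) for _ in range(10)]
        res = unpaired_contrast(a, b, threshold=1.96)
        frac = res.supra_mask.mean()
        tol = 3.0 * np.sqrt(0.05 * 0.95 / n_vox)
        assert frac == pytest.approx(0.05, abs=tol)

    def test_shifted_effect_detected(self, rng):
        a = [2.0 + rng.normal(size=(50, 1, 1), scale=0.5) for _ in range(5)]
        b = [rng.normal(size=(50, 1, 1), scale=0.5) for _ in range(5)]
        res = unpaired_contrast(a, b)
        assert res.supra_mask.mean() > 0.9

    def test_welch_flag(self, rng):
        a = [rng.normal(size=(4, 1, 1)) for _ in range(5)]
        b = [rng.normal(size=(4, 1, 1), scale=3.0) for _ in range(7)]
        res = unpaired_contrast(a, b, welch=True)
        assert res.df < 10  # Welch df shrinks under variance imbalance


class TestTToZ:
    def test_zero_preserved(self):
        assert t_to_z(0.0, 9) == 0.0

    def test_large_df_asymptotic_identity(self):
        assert t_to_z(1.96, 10**6) == pytest.approx(1.96, abs=1e-3)

    def test_df9_quantile_match(self):
        """t = 2.2622 at df 9 and z = 1.96 share the two-sided 5% tail."""
        assert t_to_z(2.2622, 9) == pytest.approx(1.96, abs=0.001)

    def test_tail_symmetry(self):
        assert t_to_z(-3.0, 5) == pytest.approx(-t_to_z(3.0, 5), rel=1e-12)

    def test_extreme_t_finite(self):
        assert np.isfinite(t_to_z(500.0, 50))
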