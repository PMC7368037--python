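import numpy as np
import pandas as pd
import pytest

from neuromodes.connectome import RoiTimeSeries, compute_connectome
from neuromodes.simulate import (
    MDES_ITEMS,
    SimulationConfig,
    generate_cohort,
    generate_null_cohort,
)


def test_identical_seed_reproduces_cohort_exactly():
    config = SimulationConfig(n_subjects=25, n_rois=12, seed=9)
    a = generate_cohort(config)
    b = generate_cohort(SimulationConfig(n_subjects=25, n_rois=12, seed=9))
    pd.testing.assert_frame_equal(a.connectivity, b.connectivity)
    pd.testing.assert_frame_equal(a.raw_task_table, b.raw_task_table)
    pd.testing.assert_frame_equal(a.mdes_strata, b.mdes_strata)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    np.testing.assert_array_equal(a.ground_truth.z_true, b.ground_truth.z_true)


def test_full_grid_has_4950_features():
    cohort = generate_cohort(SimulationConfig(n_subjects=5, n_rois=100, seed=0))
    assert cohort.connectivity.shape == (5, 4950)
    assert len(cohort.pair_index) == 4950


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(mode_strengths=(1.2, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(u_sparsity=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(generation_mode="magic")


def test_ground_truth_vectors_unit_norm_exact_support():
    config = SimulationConfig(
        n_subjects=20, n_rois=20, n_modes=2, mode_strengths=(0.5, 0.6),
        u_sparsity=0.1, v_sparsity=0.3, seed=3,
    )
    gt = generate_cohort(config).ground_truth
    p = 20 * 19 // 2
    for u in gt.u_true:
        assert np.linalg.norm(u) == pytest.approx(1.0)
        assert np.count_nonzero(u) == int(0.1 * p)
    for v in gt.v_true:
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.count_nonzero(v) == int(0.3 * 13)
    # disjoint supports across modes
    assert not set(np.flatnonzero(gt.u_true[0])) & set(np.flatnonzero(gt.u_true[1]))


def test_noiseless_rank_one_mode_is_perfectly_correlated():
    config = SimulationConfig(
        n_subjects=50, n_rois=15, n_modes=1, mode_strengths=(0.6,),
        noise_sd=0.0, v_sparsity=1.0, confound_effect_sd=0.0, seed=5,
    )
    c = generate_cohort(config)
    xu = c.connectivity.to_numpy() @ c.ground_truth.u_true[0]
    yv = c.ground_truth.y_raw @ c.ground_truth.v_true[0]
    assert np.corrcoef(xu, yv)[0, 1] == pytest.approx(1.0, abs=1e-10)


def test_planted_correlation_calibration_large_n():
    """At n=5000 the sample correlation of the planted variates stays within
    +/- 0.03 of the configured canonical correlation."""
    config = SimulationConfig(
        n_subjects=5000, n_features=60, n_rois=100, n_modes=2,
        mode_strengths=(0.57, 0.59), u_sparsity=0.1, v_sparsity=0.4,
        confound_effect_sd=0.0, seed=11,
    )
    c = generate_cohort(config)
    X = c.connectivity.to_numpy()
    for k, rho in enumerate((0.57, 0.59)):
        xu = X @ c.ground_truth.u_true[k]
        yv = c.ground_truth.y_raw @ c.ground_truth.v_true[k]
        assert np.corrcoef(xu, yv)[0, 1] == pytest.approx(rho, abs=0.03)


def test_cross_covariance_svd_aligns_with_planted_vectors():
    config = SimulationConfig(
        n_subjects=2000, n_features=60, n_rois=100, n_modes=1,
        mode_strengths=(0.6,), u_sparsity=0.5, v_sparsity=0.5,
        weight_values="equal", confound_effect_sd=0.0, seed=1,
    )
    c = generate_cohort(config)
    X = c.connectivity.to_numpy()
    Y = c.ground_truth.y_raw
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    U, _, Vt = np.linalg.svd(Xs.T @ Ys / 2000, full_matrices=False)
    assert abs(U[:, 0] @ c.ground_truth.u_true[0]) >= 0.95
    assert abs(Vt[0] @ c.ground_truth.v_true[0]) >= 0.95


def test_confound_effects_recovered_by_regression():
    config = SimulationConfig(
        n_subjects=1000, n_features=6, n_rois=100, n_modes=1,
        mode_strengths=(0.5,), u_sparsity=0.5, confound_effect_sd=0.3,
        dispersion="homogeneous", seed=21,
    )
    c = generate_cohort(config)
    X = c.connectivity.to_numpy()
    C = c.covariates.to_numpy()
    C_std = (C - C.mean(0)) / C.std(0, ddof=1)
    design = np.column_stack([np.ones(1000), C_std])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sigma2 = (resid**2).sum(axis=0) / (1000 - 4)
    G = np.linalg.inv(design.T @ design)
    truth = c.ground_truth.confound_betas["connectivity"]
    for j in range(1, 4):
        se = np.sqrt(sigma2 * G[j, j])
        assert np.all(np.abs(beta[j] - truth[j - 1]) <= 2.5 * se)


class TestNullCohort:
    def test_ground_truth_empty(self):
        c = generate_null_cohort(SimulationConfig(n_subjects=10, n_rois=10, seed=2))
        assert c.ground_truth.u_true == []
        assert c.ground_truth.z_true.shape == (10, 0)

    def test_reproducible(self):
        cfg = SimulationConfig(n_subjects=15, n_rois=10, seed=8)
        a = generate_null_cohort(cfg)
        b = generate_null_cohort(cfg)
        pd.testing.assert_frame_equal(a.connectivity, b.connectivity)

    def test_random_projections_uncorrelated_on_average(self):
        """Mean |corr| of fixed random projections over 200 null cohorts
        stays below 0.12 at n=178."""
        rng = np.random.default_rng(0)
        w_x = rng.standard_normal(45)
        w_y = rng.standard_normal(13)
        rs = []
        for rep in range(200):
            c = generate_null_cohort(SimulationConfig(
                n_subjects=178, n_features=45, n_rois=100,
                confound_effect_sd=0.0, seed=10_000 + rep,
            ))
            r = np.corrcoef(
                c.connectivity.to_numpy() @ w_x,
                c.task_scores.to_numpy() @ w_y,
            )[0, 1]
            rs.append(abs(r))
        assert np.mean(rs) < 0.12


def test_covariate_marginals_plausible():
    c = generate_cohort(SimulationConfig(n_subjects=400, n_rois=10, seed=4))
    cov = c.covariates
    assert cov["age"].between(18, 31).all()
    assert set(cov["sex"].unique()) <= {0.0, 1.0}
    assert (cov["mean_fd"] > 0).all()


def test_mdes_tables_consistent():
    c = generate_cohort(SimulationConfig(n_subjects=40, n_rois=10, seed=6))
    assert list(c.mdes_table.columns) == list(MDES_ITEMS)
    assert c.mdes_table.shape == (40, 13)
    assert set(c.mdes_strata["condition"]) == {"0-back", "1-back"}
    assert set(c.mdes_strata["day"]) == {1, 2, 3}
    # day 1 has everyone
    day1 = c.mdes_strata[c.mdes_strata["day"] == 1]
    assert day1["subject_id"].nunique() == 40


def test_timeseries_mode_roundtrip():
    config = SimulationConfig(
        n_subjects=4, n_rois=20, n_timepoints=150, n_modes=1,
        mode_strengths=(0.6,), u_sparsity=0.1, generation_mode="timeseries",
        seed=13,
    )
    c = generate_cohort(config)
    assert c.roi_timeseries is not None
    sid = c.subject_ids[0]
    series = c.roi_timeseries[sid]
    assert series.shape == (150, 20)
    cv = compute_connectome(RoiTimeSeries(sid, series))
    planted = c.connectivity.loc[sid].to_numpy()
    # finite-length sampling noise allows only approximate agreement
    assert np.corrcoef(cv.z_values, planted)[0, 1] > 0.8


def test_write_creates_manifest_and_tables(tmp_path):
    c = generate_cohort(SimulationConfig(n_subjects=8, n_rois=8, seed=1))
    manifest = c.write(tmp_path / "cohort")
    for path in manifest["paths"].values():
        assert (pd.io.common.os.path.getsize(path)) > 0
    assert manifest["seed"] == 1
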