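"""Censoring, FD, aCompCor and projection cleaning against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netrai.preprocess import (
    CensorPlan,
    NuisanceSet,
    acompcor_components,
    build_censor_mask,
    check_temporal_dof,
    compute_framewise_displacement,
    project_clean,
    spectral_stopband_regressors,
)


class TestFramewiseDisplacement:
    def test_constant_parameters_give_zero_fd(self):
        fd = compute_framewise_displacement(np.ones((50, 6)) * 3.3)
        assert np.all(fd.fd == 0) and fd.mean_fd == 0

    def test_translation_step_appears_at_step_volume_only(self):
        m = np.zeros((100, 6))
        m[40:, 0] = 0.35
        fd = compute_framewise_displacement(m, head_radius=50)
        assert fd.fd[40] == pytest.approx(0.35)
        assert np.count_nonzero(fd.fd) == 1

    def test_rotation_converted_at_head_radius(self):
        # 0.01 rad about one axis at radius 50 mm -> 0.5 mm displacement
        m = np.zeros((10, 6))
        m[5:, 4] = 0.01
        fd = compute_framewise_displacement(m, head_radius=50)
        assert fd.fd[5] == pytest.approx(0.5)

    def test_mean_fd_over_all_volumes(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 1.0
        fd = compute_framewise_displacement(m)
        assert fd.mean_fd == pytest.approx(0.1)

    def test_nonfinite_parameters_rejected(self):
        m = np.zeros((10, 6))
        m[3, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            compute_framewise_displacement(m)


def brute_force_censor(fd, threshold, n_nonsteady):
    """Literal set-union reading of the censoring rule."""
    T = len(fd)
    censored = set(range(n_nonsteady))
    for t in range(T):
        if fd[t] > threshold:
            censored |= {t - 1, t, t + 1}
    return {t for t in censored if 0 <= t < T}


class TestCensorMask:
    def test_quiet_run_fully_retained(self):
        plan = build_censor_mask(np.full(100, 0.1), 0.35, 0)
        assert plan.n_retained == 100 and not plan.reasons

    def test_single_spike_censors_neighbors(self):
        plan = build_censor_mask(np.array([0, 0.1, 0.4, 0.1, 0.1]), 0.35, 0)
        assert sorted(plan.censored.tolist()) == [1, 2, 3]
        assert plan.n_retained == 2
        assert plan.reasons[2] == ("fd_spike",)
        assert plan.reasons[1] == ("fd_neighbor",)

    def test_adjacent_spikes_union_without_double_count(self):
        fd = np.zeros(10)
        fd[5] = fd[6] = 0.5
        plan = build_censor_mask(fd, 0.35, 0)
        assert sorted(plan.censored.tolist()) == [4, 5, 6, 7]
        assert plan.reasons[5] == ("fd_spike",)

    def test_matches_brute_force_on_random_traces(self, rng):
        for _ in range(1000):
            T = int(rng.integers(5, 60))
            fd = rng.gamma(1.2, 0.15, size=T)
            fd[0] = 0.0
            n_ns = int(rng.integers(0, 3))
            plan = build_censor_mask(fd, 0.35, n_ns)
            assert set(plan.censored.tolist()) == brute_force_censor(fd, 0.35, n_ns)
            assert plan.n_retained == T - len(plan.censored)

    def test_nonsteady_exceeding_run_rejected(self):
        with pytest.raises(ValueError):
            build_censor_mask(np.zeros(5), 0.35, 5)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariants_hold_for_arbitrary_traces(self, seed):
        r = np.random.default_rng(seed)
        fd = r.gamma(1.0, 0.2, size=int(r.integers(4, 40)))
        plan = build_censor_mask(fd, 0.35, 0)
        for t, codes in plan.reasons.items():
            if "fd_spike" in codes:
                assert fd[t] > 0.35
                for nb in (t - 1, t + 1):
                    if 0 <= nb < len(fd):
                        assert not plan.keep[nb]
        assert plan.n_retained == int(plan.keep.sum())


class TestACompCor:
    def test_rank_one_data_recovers_the_shared_signal(self, rng):
        sig = rng.standard_normal(80)
        weights = rng.uniform(0.5, 2.0, size=12)
        x = np.outer(sig, weights)
        with pytest.warns(UserWarning, match="rank"):
            comps = acompcor_components(x, k=3)
        r = np.corrcoef(comps[:, 0], sig - np.polyval(np.polyfit(np.arange(80), sig, 1), np.arange(80)))[0, 1]
        assert abs(r) > 0.999

    def test_components_mutually_orthogonal_unit_norm(self, rng):
        x = rng.standard_normal((100, 30))
        comps = acompcor_components(x, k=3)
        gram = comps.T @ comps
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_matches_direct_svd_oracle_up_to_sign(self, rng):
        from scipy.signal import detrend

        x = rng.standard_normal((200, 50))
        comps = acompcor_components(x, k=3)
        xd = detrend(x - x.mean(axis=0), axis=0)
        xd = xd / xd.std(axis=0)
        u = np.linalg.svd(xd, full_matrices=False)[0][:, :3]
        for j in range(3):
            sign = np.sign(u[:, j] @ comps[:, j])
            np.testing.assert_allclose(comps[:, j], sign * u[:, j], atol=1e-8)


class TestProjectClean:
    def test_nuisance_column_removed_exactly(self, rng):
        nuis = rng.standard_normal((245, 4))
        out = project_clean(nuis[:, 2].copy(), nuis)
        assert np.abs(out).max() < 1e-10

    def test_out_of_band_slow_cosine_suppressed(self):
        tt = np.arange(245) * 2.0
        y = np.cos(2 * np.pi * 0.005 * tt)
        resid = project_clean(y, None, (0.01, 0.1), 2.0)
        assert resid.var() / y.var() < 0.01

    def test_in_band_cosine_retained(self):
        tt = np.arange(245) * 2.0
        y = np.cos(2 * np.pi * 0.05 * tt)
        resid = project_clean(y, None, (0.01, 0.1), 2.0)
        assert resid.var() / y.var() >= 0.95

    def test_residuals_orthogonal_to_retained_regressors(self, rng):
        nuis = rng.standard_normal((245, 6))
        y = rng.standard_normal((245, 3))
        plan = build_censor_mask(rng.gamma(1.0, 0.15, 245), 0.35, 2)
        resid = project_clean(y, nuis, plan=plan)
        X = np.column_stack([nuis, spectral_stopband_regressors(245, 2.0)])[plan.keep]
        dots = X.T @ resid
        scale = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert np.abs(dots / np.maximum(scale, 1e-30)).max() < 1e-8

    def test_projection_idempotent(self, rng):
        y = rng.standard_normal((245, 2))
        nuis = rng.standard_normal((245, 3))
        once = project_clean(y, nuis)
        # re-cleaning retained data against the same retained-row regressors
        twice_beta, *_ = np.linalg.lstsq(
            np.column_stack([nuis, spectral_stopband_regressors(245, 2.0)]), once, rcond=None
        )
        twice = once - np.column_stack(
            [nuis, spectral_stopband_regressors(245, 2.0)]
        ) @ twice_beta
        assert np.abs(twice - once).max() < 1e-10

    def test_commutes_with_column_scaling(self, rng):
        y = rng.standard_normal((245, 3))
        nuis = rng.standard_normal((245, 4))
        plan = build_censor_mask(rng.gamma(1.0, 0.15, 245))
        a = project_clean(y * np.array([2.0, -3.0, 0.5]), nuis, plan=plan)
        b = project_clean(y, nuis, plan=plan) * np.array([2.0, -3.0, 0.5])
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_all_censored_rejected(self):
        plan = CensorPlan(keep=np.zeros(20, dtype=bool), reasons={}, n_retained=0)
        with pytest.raises(ValueError, match="censored"):
            project_clean(np.ones((20, 1)), None, plan=plan)

    def test_cleaning_recovers_in_band_latent_signals(self, rng):
        # latent = in-band mixture, nuisance = slow drift mixed into voxels
        T, tr = 245, 2.0
        tt = np.arange(T) * tr
        freqs = rng.uniform(0.02, 0.09, 8)
        latent = sum(np.cos(2 * np.pi * f * tt + p) for f, p in zip(freqs, rng.uniform(0, 6, 8)))
        drift = np.cos(2 * np.pi * 0.004 * tt + 0.3)
        voxels = latent[:, None] + np.outer(drift, rng.uniform(0.5, 2.0, 20))
        voxels += rng.normal(0, 0.3, voxels.shape)
        cleaned = project_clean(voxels, drift[:, None])
        r = np.corrcoef(cleaned.mean(axis=1), latent)[0, 1]
        assert r > 0.95


class TestTemporalDof:
    @pytest.mark.parametrize(
        "n_ret, n_reg, expect",
        [(230, 150, True), (100, 100, False), (100, 101, False), (2, 1, True)],
    )
    def test_violation_iff_regressors_reach_retained(self, n_ret, n_reg, expect):
        assert check_temporal_dof(n_ret, n_reg) is expect

    def test_heavy_motion_subject_flagged_in_cohort(self, rng):
        # one subject with 60% of volumes censored fails; quiet subjects pass
        from netrai.synthetic import MotionSpec

        T = 245
        n_reg = 18 + spectral_stopband_regressors(T, 2.0).shape[1]
        spiky, _ = MotionSpec(spike_rate=0.45).draw_motion(T, rng)
        quiet, _ = MotionSpec(spike_rate=0.01).draw_motion(T, rng)
        results = []
        for motion in (spiky, quiet):
            fd = compute_framewise_displacement(motion)
            plan = build_censor_mask(fd)
            results.append(check_temporal_dof(plan.n_retained, n_reg))
        assert results == [False, True]


class TestNuisanceSet:
    def test_matrix_assembly_and_derivative_convention(self, rng):
        motion = rng.standard_normal((60, 6))
        csf = rng.standard_normal((60, 12))
        wm = rng.standard_normal((60, 12))
        ns = NuisanceSet.build(motion, csf, wm, k=3, n_nonsteady=2)
        X = ns.as_matrix()
        assert X.shape == (60, 3 + 3 + 6 + 6 + 2)
        assert np.all(ns.motion_deriv[0] == 0)
        np.testing.assert_allclose(ns.motion_deriv[1:], np.diff(motion, axis=0))
        assert X[0, -2] == 1.0 and X[1, -1] == 1.0
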