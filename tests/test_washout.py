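import numpy as np
import pytest

from pulmopet import (
    DynamicScan,
    FrameSchedule,
    PhantomSpec,
    ScalarVolume,
    TracerSimConfig,
    VolumeGrid,
    WashoutModel,
    estimate_perfusion,
    estimate_specific_ventilation,
    generate_phantom,
    mean_normalize,
    simulate_nn13,
    smooth_moving_average,
)
from pulmopet.washout import box_kernel_sizes


def make_scan(frame_values, durations=None):
    """Scan whose frames hold the given per-frame voxel arrays."""
    frames = np.asarray(frame_values, dtype=float)
    if durations is None:
        durations = [5.0] * frames.shape[0]
    sched = FrameSchedule.from_durations(durations)
    grid = VolumeGrid(frames.shape[1:], (1, 1, 1))
    return DynamicScan(grid, sched, frames)


class TestKernelSizes:
    def test_study_geometry(self):
        # 10.125 mm target: 1 voxel in-plane (5.3456 mm), 5 axially (2.025 mm)
        assert box_kernel_sizes((5.3456, 5.3456, 2.025), 10.125) == (1, 1, 5)

    def test_target_below_spacing_rejected(self):
        with pytest.raises(ValueError, match="below"):
            box_kernel_sizes((5.0, 5.0, 5.0), 2.0)


class TestSmoothing:
    def test_uniform_volume_unchanged(self):
        grid = VolumeGrid((6, 6, 6), (1, 1, 1))
        v = ScalarVolume(grid, np.full((6, 6, 6), 3.5), "activity")
        out = smooth_moving_average(v, 3.0, mask=np.ones((6, 6, 6), bool))
        np.testing.assert_allclose(out.values, 3.5)

    def test_impulse_total_conserved(self):
        grid = VolumeGrid((9, 9, 9), (1, 1, 1))
        values = np.zeros((9, 9, 9))
        values[4, 4, 4] = 27.0
        out = smooth_moving_average(ScalarVolume(grid, values, "activity"), 3.0)
        assert out.values.sum() == pytest.approx(27.0)
        assert out.values[4, 4, 4] == pytest.approx(1.0)

    def test_matches_brute_force_box_average(self, rng):
        values = rng.normal(size=(8, 8, 8))
        grid = VolumeGrid((8, 8, 8), (1, 1, 1))
        out = smooth_moving_average(ScalarVolume(grid, values, "activity"), 3.0)
        # independent nested-loop oracle with zero padding
        expected = np.zeros_like(values)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    acc = 0.0
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            for dk in (-1, 0, 1):
                                a, b, c = i + di, j + dj, k + dk
                                if 0 <= a < 8 and 0 <= b < 8 and 0 <= c < 8:
                                    acc += values[a, b, c]
                    expected[i, j, k] = acc / 27.0
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_mask_aware_renormalization(self):
        grid = VolumeGrid((5, 1, 1), (1, 1, 1))
        values = np.array([1.0, 1.0, 1.0, 0.0, 0.0]).reshape(5, 1, 1)
        mask = values.astype(bool)
        out = smooth_moving_average(ScalarVolume(grid, values, "activity"), 3.0, mask=mask)
        # inside the mask, averages only run over masked neighbours
        np.testing.assert_allclose(out.values[:3, 0, 0], 1.0)
        np.testing.assert_allclose(out.values[3:, 0, 0], 0.0)


class TestMeanNormalize:
    def test_two_voxel_hand_case(self):
        grid = VolumeGrid((2, 1, 1), (1, 1, 1))
        v = ScalarVolume(grid, np.array([2.0, 4.0]).reshape(2, 1, 1), "q_rel")
        out = mean_normalize(v, np.ones((2, 1, 1), bool))
        np.testing.assert_allclose(out.values.ravel(), [2 / 3, 4 / 3])

    def test_lung_mean_is_one_and_idempotent(self, rng):
        grid = VolumeGrid((4, 4, 4), (1, 1, 1))
        mask = rng.random((4, 4, 4)) > 0.3
        v = ScalarVolume(grid, rng.uniform(0.5, 2.0, (4, 4, 4)), "q_rel")
        out = mean_normalize(v, mask)
        assert out.values[mask].mean() == pytest.approx(1.0)
        again = mean_normalize(out, mask)
        np.testing.assert_allclose(again.values, out.values)

    def test_zero_mean_rejected(self):
        grid = VolumeGrid((2, 1, 1), (1, 1, 1))
        v = ScalarVolume(grid, np.zeros((2, 1, 1)), "q_rel")
        with pytest.raises(ValueError, match="zero"):
            mean_normalize(v, np.ones((2, 1, 1), bool))


class TestEstimatePerfusion:
    def test_proportional_to_truth(self, phantom, nn13_noise_free):
        _, _, mask, truth = phantom
        q = estimate_perfusion(nn13_noise_free)
        lung = mask.lung_mask
        ratio = q.values[lung] / truth.q_rel[lung]
        np.testing.assert_allclose(ratio, ratio.mean(), rtol=1e-12)

    def test_window_outside_schedule_rejected(self, nn13_noise_free):
        with pytest.raises(ValueError, match="window"):
            estimate_perfusion(nn13_noise_free, (500.0, 600.0))

    def test_scaling_equivariance(self, nn13_noise_free):
        scaled = DynamicScan(
            nn13_noise_free.grid, nn13_noise_free.schedule, nn13_noise_free.frames * 7.0
        )
        a = estimate_perfusion(nn13_noise_free).values
        b = estimate_perfusion(scaled).values
        np.testing.assert_allclose(b, 7.0 * a)


class TestEstimateSpecificVentilation:
    def test_exact_exponential_recovered(self):
        sv = 0.5  # min^-1
        sched = FrameSchedule.from_durations([5.0] * 8 + [10.0] * 3 + [30.0] * 5)
        t_mid = sched.mid_times
        values = 100.0 * np.exp(-sv / 60.0 * (t_mid - 30.0))
        frames = values.reshape(-1, 1, 1, 1) * np.ones((1, 2, 1, 1))
        scan = DynamicScan(VolumeGrid((2, 1, 1), (1, 1, 1)), sched, frames)
        fit = estimate_specific_ventilation(scan, (30.0, 220.0))
        np.testing.assert_allclose(fit.sv.values, sv, rtol=1e-9)
        np.testing.assert_allclose(fit.r_squared, 1.0, atol=1e-12)

    def test_constant_activity_gives_zero_sv(self):
        scan = make_scan(np.full((5, 2, 1, 1), 50.0))
        fit = estimate_specific_ventilation(scan, (0, 5), window_in_seconds=False)
        np.testing.assert_allclose(fit.sv.values, 0.0)

    def test_scale_invariance(self, nn13_noise_free):
        fit1 = estimate_specific_ventilation(nn13_noise_free)
        scaled = DynamicScan(
            nn13_noise_free.grid, nn13_noise_free.schedule, nn13_noise_free.frames * 13.0
        )
        fit2 = estimate_specific_ventilation(scaled)
        np.testing.assert_allclose(fit2.sv.values, fit1.sv.values, rtol=1e-9)

    def test_all_zero_scan_flags_everything(self):
        scan = make_scan(np.zeros((5, 3, 1, 1)))
        fit = estimate_specific_ventilation(scan, (0, 5), window_in_seconds=False)
        assert fit.low_signal.all()
        assert np.isnan(fit.sv_values()).all()

    def test_too_few_frames_rejected(self, nn13_noise_free):
        with pytest.raises(ValueError, match="3"):
            estimate_specific_ventilation(nn13_noise_free, (160.0, 220.0))


class TestRoundTrips:
    def test_noise_free_voxelwise_recovery(self, phantom, nn13_noise_free):
        _, _, mask, truth = phantom
        res = WashoutModel(nn13_noise_free, mask).fit()
        lung = mask.lung_mask
        sv_err = np.abs(res.specific_ventilation.values[lung] - truth.sv_per_min[lung])
        assert (sv_err / truth.sv_per_min[lung]).max() < 1e-2
        qn = truth.q_rel_normalized()
        q_err = np.abs(res.perfusion.values[lung] - qn[lung]) / qn[lung]
        assert q_err.max() < 1e-9

    def test_noisy_lobe_means_within_5pct(self, phantom):
        _, _, mask, truth = phantom
        scan = simulate_nn13(truth, TracerSimConfig(noise="gaussian", noise_level=2.0), seed=5)
        res = WashoutModel(scan, mask).fit()
        qn = truth.q_rel_normalized()
        for role in ("baseline", "diluent", "allergen"):
            m = mask.role_mask(role)
            usable = m & ~res.low_signal
            assert res.perfusion.values[usable].mean() == pytest.approx(
                qn[m].mean(), rel=0.05
            )
            assert res.specific_ventilation.values[usable].mean() == pytest.approx(
                truth.sv_per_min[m].mean(), rel=0.05
            )

    def test_smoothing_then_normalizing_preserves_unit_mean(self, phantom):
        _, _, mask, truth = phantom
        scan = simulate_nn13(truth, TracerSimConfig(noise="gaussian", noise_level=2.0), seed=6)
        res = WashoutModel(scan, mask, smoothing_mm=10.125).fit()
        lung = mask.lung_mask
        assert res.perfusion.values[lung].mean() == pytest.approx(1.0, abs=1e-9)

    def test_allergen_contrast_direction_all_seeds(self):
        # the constructed allergen deficit survives analysis for every seed
        spec = PhantomSpec()
        for seed in range(10):
            _, mask, truth = generate_phantom(spec, seed=seed)
            scan = simulate_nn13(
                truth, TracerSimConfig(noise="gaussian", noise_level=2.0), seed=seed
            )
            res = WashoutModel(scan, mask).fit()
            means = res.lobe_means().set_index("lobe")
            assert means.loc["allergen", "q_rel"] < means.loc["baseline", "q_rel"]
            assert means.loc["allergen", "q_rel"] < means.loc["diluent", "q_rel"]
            assert means.loc["allergen", "sv_norm"] < means.loc["baseline", "sv_norm"]
            assert means.loc["allergen", "sv_norm"] < means.loc["diluent", "sv_norm"]
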