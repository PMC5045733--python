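"""Steady-state detection, smoothing and the integral baseline correction."""

import numpy as np
import pytest

from secsaxs.baseline import (
    apply_integral_baseline,
    blank_reference,
    find_best_region,
    gaussian_smooth,
    integral_baseline,
    linear_baseline,
    steady_state_average,
    SteadyStateRegion,
)
from secsaxs.core_data import Chromatogram, SECSAXSDataset
from secsaxs.peak_shapes import eval_gaussian


def forward_fouling(signal, gamma):
    """The generating recursion: each frame deposits gamma x previous signal."""
    B = np.zeros_like(signal)
    for k in range(1, signal.size):
        B[k] = B[k - 1] + gamma * signal[k - 1]
    return B


def _chrom(intensity):
    n = len(intensity)
    return Chromatogram(0.01, np.arange(n), np.asarray(intensity, float),
                        np.ones(n))


class TestSteadyStateAverage:
    def _ds(self, I):
        I = np.atleast_2d(I)
        q = np.linspace(0.01, 0.01 * I.shape[0], I.shape[0])
        return SECSAXSDataset(q=q, frames=np.arange(I.shape[1]), I=I,
                              S=np.ones_like(I))

    def test_constant_tail(self):
        ds = self._ds(np.full((1, 30), 5.0))
        assert steady_state_average(ds, 10, 29)[0] == 5.0

    def test_linear_tail_mean(self):
        ds = self._ds(np.arange(1.0, 11.0)[None, :])
        assert steady_state_average(ds, 0, 9)[0] == pytest.approx(5.5)

    def test_short_region_warns(self):
        ds = self._ds(np.ones((1, 30)))
        with pytest.warns(UserWarning, match="at least 10"):
            steady_state_average(ds, 25, 29)

    def test_region_outside_errors(self):
        ds = self._ds(np.ones((1, 10)))
        with pytest.raises(ValueError):
            steady_state_average(ds, 50, 60)


class TestGaussianSmooth:
    def test_constant_series_unchanged(self):
        c = _chrom(np.full(30, 3.0))
        assert np.allclose(gaussian_smooth(c).intensity, 3.0)

    def test_interior_bump_sum_preserved(self):
        y = np.zeros(41)
        y[18:23] = [1, 2, 5, 2, 1]
        sm = gaussian_smooth(_chrom(y))
        assert sm.intensity.sum() == pytest.approx(y.sum())

    def test_impulse_gives_kernel(self):
        y = np.zeros(31)
        y[15] = 1.0
        sm = gaussian_smooth(_chrom(y), points=7)
        sigma = 1.0  # (points-1)/6
        x = np.arange(7) - 3
        w = np.exp(-0.5 * (x / sigma) ** 2)
        w /= w.sum()
        assert np.allclose(sm.intensity[12:19], w)

    def test_sigma_untouched(self):
        c = _chrom(np.arange(20.0))
        assert np.array_equal(gaussian_smooth(c).sigma, c.sigma)

    def test_invalid_kernel(self):
        with pytest.raises(ValueError):
            gaussian_smooth(_chrom(np.ones(20)), points=4)
        with pytest.raises(ValueError):
            gaussian_smooth(_chrom(np.ones(5)), points=7)


class TestIntegralBaseline:
    def test_zero_level_no_correction(self):
        y = np.ones(50)
        B, gamma, iters, skipped = integral_baseline(y, 0.0, 40)
        assert np.all(B == 0) and iters == 0 and not skipped

    @pytest.mark.parametrize("gamma", [1e-4, 1e-3, 1e-2])
    @pytest.mark.parametrize("n_peaks", [1, 2, 3])
    def test_recovers_forward_simulation(self, gamma, n_peaks):
        """Noiseless fouled data: the iteration's fixed point is the truth."""
        n = 500
        t = np.arange(n, dtype=float)
        centers = [150.0, 220.0, 280.0][:n_peaks]
        heights = [100.0, 60.0, 30.0][:n_peaks]
        s = sum(eval_gaussian(t, h * 50.0, c, 20.0)
                for h, c in zip(heights, centers))
        B_true = forward_fouling(s, gamma)
        y = s + B_true
        B, g, iters, skipped = integral_baseline(
            y, B_true[-1], region_end_pos=430, max_iter=50
        )
        peak = s.max()
        assert not skipped
        assert np.sqrt(np.mean((B - B_true) ** 2)) / peak < 1e-6
        assert abs(g - gamma) / gamma < 1e-2
        assert np.all(np.diff(B) >= -1e-12)  # monotone accumulation

    def test_negative_integral_guard(self):
        y = -np.ones(50)
        B, gamma, iters, skipped = integral_baseline(y, 1.0, 40)
        assert skipped and np.all(B == 0)

    def test_baseline_starts_at_zero_and_ends_at_level(self):
        t = np.arange(300, dtype=float)
        s = eval_gaussian(t, 1000.0, 100.0, 15.0)
        B_true = forward_fouling(s, 1e-3)
        B, *_ = integral_baseline(s + B_true, B_true[-1], 250, max_iter=30)
        assert B[0] == 0.0
        assert B[-1] == pytest.approx(B_true[-1], rel=1e-8)


class TestApplyBaseline:
    def test_zero_fouling_is_identity(self, demo_data):
        ds, _ = demo_data
        region = SteadyStateRegion(t_s1=770, t_sm=799)
        corrected, result = apply_integral_baseline(ds, region, max_iter=10)
        # demo data has no fouling: I_BL is pure noise, tiny corrections only
        assert np.max(np.abs(corrected.I - ds.I)) < 0.01 * np.abs(ds.I).max()

    def test_fouled_dataset_corrected(self, fouled_single_species):
        spec, ds, truth, _ = fouled_single_species
        region = SteadyStateRegion(t_s1=360, t_sm=399)
        corrected, result = apply_integral_baseline(ds, region, max_iter=40)
        assert not result.skipped.any()
        # recovered per-q gamma close to the generator's
        assert np.allclose(result.gamma, truth.gamma, rtol=0.05)
        # corrected tail returns to zero within the noise level
        tail = corrected.I[:, 380:].mean(axis=1)
        assert np.max(np.abs(tail)) < 3 * truth.sigma[:, 380:].mean()

    def test_trailing_edges_superimpose_after_correction(self, fouled_single_species):
        """Scaled chromatograms at different q must coincide on the peak's
        trailing side once the fouling baseline is removed (single species:
        all chromatograms are proportional)."""
        spec, ds, truth, _ = fouled_single_species
        region = SteadyStateRegion(t_s1=360, t_sm=399)
        corrected, _ = apply_integral_baseline(ds, region, max_iter=40)
        # trailing half-height region of the Gaussian peak (center 150, sd 20)
        window = slice(170, 195)
        ref = truth.clean[0, window] / truth.clean[0, window].max()
        spreads = []
        for i in range(0, ds.n_q, 10):
            seg = corrected.I[i, window]
            seg = seg / seg.max()
            spreads.append(np.max(np.abs(seg - ref)))
        assert max(spreads) < 0.05  # percent-level superposition
        # without correction the fouled tails do NOT superimpose
        raw_spreads = []
        for i in range(0, ds.n_q, 10):
            seg = ds.I[i, window]
            seg = seg / seg.max()
            raw_spreads.append(np.max(np.abs(seg - ref)))
        assert max(raw_spreads) > max(spreads)

    def test_idempotence(self, fouled_single_species):
        spec, ds, truth, _ = fouled_single_species
        region = SteadyStateRegion(t_s1=360, t_sm=399)
        corrected, _ = apply_integral_baseline(ds, region, max_iter=40)
        twice, result2 = apply_integral_baseline(corrected, region, max_iter=40)
        # already-corrected data: I_BL ~ 0, second pass is a near no-op
        assert np.max(np.abs(twice.I - corrected.I)) < 5e-3 * ds.I.max()


class TestFindBestRegion:
    def test_fouled_tail_found_with_integral_suggestion(self, fouled_single_species):
        spec, ds, truth, blanks = fouled_single_species
        bref = blank_reference(blanks, window=20)
        region = find_best_region(ds, bref, window=20, scan_range=(250, 399))
        # the chosen window holds no residual elution signal
        window = slice(region.t_s1, region.t_sm + 1)
        assert truth.clean[:, window].max() < 1e-3 * truth.clean.max()
        assert region.suggestion == "integral baseline"
        assert region.t_sm - region.t_s1 + 1 == 20

    def test_no_fouling_suggests_none(self, fouled_single_species):
        spec, ds, truth, blanks = fouled_single_species
        # strip the baseline and the signal: pure noise tail sums to ~0
        clean = ds.copy()
        clean.I = ds.I - truth.baseline - truth.clean
        bref = blank_reference(blanks, window=20)
        region = find_best_region(clean, bref, window=20, scan_range=(250, 399))
        assert region.suggestion == "none/linear"

    def test_window_mismatch_rejected(self, fouled_single_species):
        spec, ds, truth, blanks = fouled_single_species
        bref = blank_reference(blanks, window=20)
        with pytest.raises(ValueError, match="window"):
            find_best_region(ds, bref, window=10)


class TestLinearBaseline:
    def test_flat_offset_removed(self):
        c = _chrom(np.full(60, 3.0))
        out = linear_baseline(c, (0, 9), (50, 59))
        assert np.allclose(out.intensity, 0.0)

    def test_pure_ramp_removed(self):
        c = _chrom(0.5 * np.arange(60.0) + 2.0)
        out = linear_baseline(c, (0, 9), (50, 59))
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_peak_preserved_anchors_zeroed(self):
        t = np.arange(100, dtype=float)
        ramp = 0.2 * t + 1.0
        peak = eval_gaussian(t, 100.0, 50.0, 5.0)
        c = _chrom(ramp + peak)
        out = linear_baseline(c, (0, 9), (90, 99))
        assert np.allclose(out.intensity, peak, atol=1e-10)

    def test_identical_anchor_times_rejected(self):
        c = _chrom(np.ones(20))
        with pytest.raises(ValueError):
            linear_baseline(c, (0, 5), (0, 5))
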