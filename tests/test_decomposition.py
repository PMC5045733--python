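"""SVD rank, single/global fits, back-generation and model persistence."""

import numpy as np
import pytest

from secsaxs import decomposition as dc
from secsaxs.core_data import SECSAXSDataset
from secsaxs.cormap import cormap_pvalue, PairwiseOptions
from secsaxs.peak_shapes import PeakKind, PeakModel
from secsaxs.synthetic import generate


class TestSVDRank:
    def test_rank2_noiseless(self, rng):
        q = np.linspace(0.01, 0.2, 30)
        t = np.arange(100)
        u1, u2 = np.exp(-q * 5), np.exp(-q * 20)
        v1 = np.exp(-0.5 * ((t - 30) / 8.0) ** 2)
        v2 = np.exp(-0.5 * ((t - 60) / 8.0) ** 2)
        I = np.outer(u1, v1) + np.outer(u2, v2)
        ds = SECSAXSDataset(q=q, frames=t, I=I, S=np.ones_like(I))
        s, n = dc.svd_rank(ds)
        assert np.sum(s > 1e-10 * s[0]) == 2
        assert n == 2

    def test_rank4_with_noise(self, rng):
        """Four comparable outer products plus 1% noise: four singular
        values stand above the noise floor."""
        q = np.linspace(0.01, 0.2, 50)
        t = np.arange(200)
        # four orthonormal q profiles with comparable time-peak amplitudes
        U, _ = np.linalg.qr(rng.standard_normal((50, 4)))
        I = np.zeros((50, 200))
        for k, (amp, center) in enumerate(
            [(10, 40), (8, 80), (6, 120), (4, 160)]
        ):
            I += amp * np.outer(U[:, k], np.exp(-0.5 * ((t - center) / 12.0) ** 2))
        sigma = 0.01 * np.abs(I) + 1e-3
        ds = SECSAXSDataset(q=q, frames=t, I=I + rng.standard_normal(I.shape) * sigma,
                            S=sigma)
        s, n = dc.svd_rank(ds)
        floor = np.median(s[s.size // 2 :])
        assert np.sum(s > 5 * floor) == 4

    def test_demo_surface_suggestion_is_advisory(self, demo_data):
        # the faintest of the four species sits near the noise floor at 1%
        # noise; the knee heuristic may report 3 or 4 — the spectrum itself
        # is what the user decides from
        ds, _ = demo_data
        s, n = dc.svd_rank(ds)
        assert n in (3, 4)
        assert s[2] > 20 * np.median(s[s.size // 2 :])

    def test_frame_permutation_invariance(self, rng):
        q = np.linspace(0.01, 0.2, 20)
        I = rng.standard_normal((20, 15))
        ds = SECSAXSDataset(q=q, frames=np.arange(15), I=I,
                            S=np.ones_like(I))
        s1, _ = dc.svd_rank(ds)
        perm = rng.permutation(15)
        ds2 = SECSAXSDataset(q=q, frames=np.arange(15), I=I[:, perm],
                             S=np.ones_like(I))
        s2, _ = dc.svd_rank(ds2)
        assert np.allclose(s1, s2)


class TestFitSingle:
    def test_single_gaussian_recovery(self, rng):
        t = np.arange(200)
        true = PeakModel(PeakKind.GAUSS, 500.0, 90.0, 12.0)
        sigma = 0.005 * true(t).max() * np.ones(200)
        y = true(t) + rng.standard_normal(200) * sigma
        from secsaxs.core_data import Chromatogram

        c = Chromatogram(0.01, t, y, sigma)
        peaks, rep = dc.fit_single(c, 1, PeakKind.GAUSS, [85.0])
        assert rep["success"]
        p = peaks[0]
        assert p.a1 == pytest.approx(90.0, abs=0.5)
        assert p.a2 == pytest.approx(12.0, rel=0.05)
        assert p.a0 == pytest.approx(500.0, rel=0.05)

    def test_symmetric_fit_to_skewed_truth_leaves_structured_residuals(
        self, demo_data
    ):
        """Fitting plain Gaussians to strongly tailed peaks must fail the
        run test under the main peak."""
        ds, _ = demo_data
        c = ds.chromatogram(2)
        peaks, _ = dc.fit_single(c, 4, PeakKind.GAUSS,
                                 [260.0, 340.0, 420.0, 530.0])
        lo, hi = dc.default_fit_limits(ds.n_frames)
        t = c.t[lo : hi + 1].astype(float)
        fit = sum(p(t) for p in peaks)
        p = cormap_pvalue(c.intensity[lo : hi + 1], fit,
                          opts=PairwiseOptions(q_max_cutoff=np.inf))
        assert p < 0.01

    def test_skewed_fit_to_skewed_truth_is_acceptable(self, fitted_demo_model,
                                                      demo_data):
        ds, _ = demo_data
        model, full, report = fitted_demo_model
        assert np.mean(report.pvalues >= 0.01) > 0.9


class TestInitGlobal:
    def test_noiseless_amplitudes_exact(self):
        """With the true shapes fixed, the linear amplitude solve is exact."""
        from secsaxs.synthetic import aldolase_like_spec

        spec = aldolase_like_spec(seed=0, noise_fraction=0.0)
        spec.noise_floor = 0.0
        ds, truth = generate(spec)
        ds.S[:] = 1.0  # noiseless: unit weights
        peaks = [sp.peak for sp in spec.species]
        model = dc.init_global(peaks, ds, fit_limits=(0, ds.n_frames - 1))
        expected = truth.form_factors.T * np.array(
            [sp.peak.a0 for sp in spec.species]
        )
        assert np.allclose(model.amplitudes, expected, rtol=1e-8)

    def test_amplitudes_nonnegative(self, fitted_demo_model):
        _, full, _ = fitted_demo_model
        assert np.all(full.amplitudes >= 0)

    def test_subset_selection_honoured(self, demo_data):
        ds, _ = demo_data
        peaks = [PeakModel(PeakKind.GAUSS, 1.0, c, 20.0)
                 for c in (250.0, 330.0, 410.0, 520.0)]
        q_idx = np.arange(0, ds.n_q, 4)
        model = dc.init_global(peaks, ds, q_indices=q_idx)
        assert model.amplitudes.shape[0] == q_idx.size
        assert np.array_equal(model.meta["q_indices"], q_idx)


class TestGlobalFit:
    TRUE_CENTERS = np.array([240.0, 316.0, 392.0, 496.0])
    TRUE_WIDTHS = np.array([22.0, 24.0, 26.0, 30.0])
    TRUE_DIST = (50.0, 40.0)

    def test_shared_parameter_recovery(self, fitted_demo_model):
        model, _, _ = fitted_demo_model
        sh = model.shapes
        assert np.all(np.abs(sh.centers - self.TRUE_CENTERS)
                      / self.TRUE_CENTERS < 0.02)
        assert np.all(np.abs(sh.widths - self.TRUE_WIDTHS)
                      / self.TRUE_WIDTHS < 0.02)
        assert abs(sh.dist1[0] - self.TRUE_DIST[0]) / self.TRUE_DIST[0] < 0.02
        assert abs(sh.dist2[0] - self.TRUE_DIST[1]) / self.TRUE_DIST[1] < 0.02

    def test_amplitude_correlation_with_truth(self, fitted_demo_model,
                                              demo_data, demo_spec):
        ds, truth = demo_data
        _, full, _ = fitted_demo_model
        expected = truth.form_factors.T * np.array(
            [sp.peak.a0 for sp in demo_spec.species]
        )
        for k in range(4):
            r = np.corrcoef(full.amplitudes[:, k], expected[:, k])[0, 1]
            assert r > 0.999

    def test_never_worse_than_initialisation(self, demo_data):
        ds, _ = demo_data
        peaks, _ = dc.fit_single(
            ds.chromatogram(2), 4, PeakKind.EMG_GMG,
            [245.0, 320.0, 395.0, 500.0], init_distortion=30.0,
        )
        q_idx = np.arange(0, ds.n_q, 6)
        model0 = dc.init_global(peaks, ds, q_indices=q_idx)
        lo, hi = model0.fit_limits
        r0, _ = dc._stack_residuals(model0.shapes, ds, q_idx, lo, hi)
        model, report = dc.global_fit(model0, ds)
        assert report.cost <= 0.5 * float(r0 @ r0) + 1e-9

    def test_scale_invariance(self, demo_data):
        """Multiplying I and sigma jointly leaves the fitted shapes unchanged."""
        ds, _ = demo_data
        scaled = ds.copy()
        scaled.I *= 7.0
        scaled.S *= 7.0
        peaks = [PeakModel(PeakKind.EMG_GMG, 1.0, c, w, 45.0, 35.0)
                 for c, w in zip(self.TRUE_CENTERS, self.TRUE_WIDTHS)]
        q_idx = np.arange(0, ds.n_q, 10)
        m1, _ = dc.global_fit(dc.init_global(peaks, ds, q_indices=q_idx), ds,
                              max_nfev=50)
        m2, _ = dc.global_fit(
            dc.init_global(peaks, scaled, q_indices=q_idx), scaled, max_nfev=50
        )
        assert np.allclose(m1.shapes.centers, m2.shapes.centers, rtol=1e-6)
        assert np.allclose(m1.amplitudes * 7.0, m2.amplitudes, rtol=1e-6)


class TestBackGenerate:
    def test_reconstruction_identity(self, fitted_demo_model, demo_data):
        """Sum of family surfaces equals the model surface exactly."""
        ds, _ = demo_data
        _, full, _ = fitted_demo_model
        t = ds.frames.astype(float)
        total = full.surface(t)
        partial = np.zeros_like(total)
        for k in range(full.n_families):
            frames = dc.back_generate_frames(full, ds, k)
            partial += np.column_stack([fr.intensity for fr in frames])
        assert np.allclose(partial, total, rtol=1e-10, atol=1e-12)

    def test_zero_fit_error_keeps_original_sigma(self, fitted_demo_model,
                                                 demo_data):
        ds, _ = demo_data
        _, full, _ = fitted_demo_model
        frames = dc.back_generate_frames(full, ds, 0, frame_range=(200, 210),
                                         fit_error_fraction=0.0)
        sel = (ds.frames >= 200) & (ds.frames <= 210)
        assert np.array_equal(
            np.column_stack([fr.sigma for fr in frames]), ds.S[:, sel]
        )

    def test_fit_error_shares(self, fitted_demo_model, demo_data):
        ds, _ = demo_data
        _, full, _ = fitted_demo_model
        f0 = dc.back_generate_frames(full, ds, 0, frame_range=(300, 300),
                                     fit_error_fraction=0.5)[0]
        assert np.all(f0.sigma >= ds.S[:, ds.frames == 300].ravel() - 1e-15)

    def test_requires_full_q_model(self, fitted_demo_model, demo_data):
        ds, _ = demo_data
        model, _, _ = fitted_demo_model  # subset-q model
        with pytest.raises(ValueError, match="every q"):
            dc.back_generate_frames(model, ds, 0)


class TestPersistence:
    def test_round_trip(self, fitted_demo_model, tmp_path):
        _, full, _ = fitted_demo_model
        path = tmp_path / "model.json"
        dc.save_model(full, path)
        loaded = dc.load_model(path)
        assert loaded.kind == full.kind
        assert np.allclose(loaded.shapes.centers, full.shapes.centers)
        assert np.allclose(loaded.amplitudes, full.amplitudes)
        assert loaded.fit_limits == full.fit_limits

    def test_unknown_kind_rejected(self, fitted_demo_model, tmp_path):
        import json

        _, full, _ = fitted_demo_model
        path = tmp_path / "model.json"
        dc.save_model(full, path)
        doc = json.loads(path.read_text())
        doc["kind"] = "LOGNORM"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="unknown peak kind"):
            dc.load_model(path)

    def test_version_mismatch_rejected(self, fitted_demo_model, tmp_path):
        import json

        _, full, _ = fitted_demo_model
        path = tmp_path / "model.json"
        dc.save_model(full, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            dc.load_model(path)
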