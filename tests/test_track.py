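"""Sub-pixel bar tracking: row fits, robust reads, detection, differentials."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from cgmr.layout import Rect, SensorPairGeom, make_default_layout
from cgmr.simulate import (
    BindingScenario,
    NoiseModel,
    _bar_profile,
    render_frame,
    simulate_stack,
    simulate_sweep,
)
from cgmr.stack import FrameStack
from cgmr.track import (
    DetectionError,
    ResonanceRead,
    detect_rois,
    differential_shift,
    fit_row_gaussian,
    read_roi,
    track_stack,
)

from conftest import QUIET, gaussian_profile


class TestRowFit:
    def test_noiseless_recovery_to_machine_precision(self):
        y = gaussian_profile(80, amplitude=100, centre=37.40, width=5, offset=10)
        fit = fit_row_gaussian(y)
        assert fit.converged
        assert fit.centre_px == pytest.approx(37.40, abs=1e-6)
        assert fit.amplitude == pytest.approx(100, rel=1e-6)
        assert fit.width_px == pytest.approx(5, rel=1e-6)
        assert fit.offset == pytest.approx(10, abs=1e-5)

    def test_matches_scipy_curve_fit_on_noisy_profile(self):
        """Independent oracle: the batched LM solver lands on the same least-
        squares optimum as scipy's curve_fit."""
        rng = np.random.default_rng(42)
        y = gaussian_profile(90, 80, 41.2, 6, 20, noise_sd=2.0, rng=rng)
        ours = fit_row_gaussian(y)
        x = np.arange(90.0)

        def g(x, a, x0, w, b):
            return a * np.exp(-0.5 * ((x - x0) / w) ** 2) + b

        popt, _ = curve_fit(g, x, y, p0=[y.max() - y.min(), np.argmax(y), 4, y.min()])
        assert ours.centre_px == pytest.approx(popt[1], abs=1e-6)
        assert ours.rss == pytest.approx(np.sum((y - g(x, *popt)) ** 2), rel=1e-8)

    def test_flat_profile_not_converged(self):
        fit = fit_row_gaussian(np.full(50, 7.0))
        assert not fit.converged
        noisy_flat = np.random.default_rng(1).normal(100, 3, 60)
        assert not fit_row_gaussian(noisy_flat).converged

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_row_gaussian(np.arange(5.0))

    def test_fano_lineshape_static_bias_shrinks_with_q(self):
        """Gaussian-fitting an asymmetric Fano bar leaves a static offset that
        decreases with the asymmetry parameter q (< 0.5 px for a nearly
        symmetric q=20 bar at 12 px FWHM)."""
        x = np.arange(120, dtype=float)
        biases = []
        for q in (3.0, 5.0, 10.0, 20.0):
            fit = fit_row_gaussian(10.0 + 500.0 * _bar_profile(x, 57.3, 12.0, fano_q=q))
            assert fit.converged
            biases.append(abs(fit.centre_px - 57.3))
        assert biases == sorted(biases, reverse=True)
        assert biases[-1] < 0.5

    @pytest.mark.parametrize("q", [5.0, 10.0, 20.0])
    def test_fano_bias_is_static_so_shifts_track_true(self, q):
        """The Fano-vs-Gaussian offset is constant under bar motion, so the
        baseline-referenced *shift* (the tracked quantity) stays accurate."""
        x = np.arange(120, dtype=float)
        centres = [45.0, 52.7, 61.3]
        fitted = [
            fit_row_gaussian(10.0 + 500.0 * _bar_profile(x, c, 12.0, fano_q=q)).centre_px
            for c in centres
        ]
        err = np.abs(np.diff(fitted) - np.diff(centres))
        assert err.max() < 0.05


class TestReadRoi:
    def _roi_image(self, height=150, width=182, centre=91.0, noise_sd=0.0, rng=None):
        x = np.arange(width, dtype=float)
        row = 300.0 + 500.0 * np.exp(-0.5 * ((x - centre) / 5.1) ** 2)
        img = np.tile(row, (height, 1))
        if noise_sd:
            img = img + (rng or np.random.default_rng(0)).normal(0, noise_sd, img.shape)
        return img

    def test_all_rows_used_noiseless(self):
        img = self._roi_image()
        r = read_roi(img, Rect(0, 0, 150, 182))
        assert r.n_rows_used == 150
        assert r.qc_pass
        assert r.iqr_px < 0.01
        assert r.x_med == pytest.approx(91.0, abs=1e-3)

    def test_median_robust_to_corrupted_rows(self):
        rng = np.random.default_rng(2)
        img = self._roi_image(noise_sd=5.0, rng=rng)
        clean = read_roi(img, Rect(0, 0, 150, 182)).x_med
        bad = img.copy()
        idx = rng.choice(150, size=45, replace=False)  # 30% saturated streaks
        bad[idx] = 65535.0
        corrupted = read_roi(bad, Rect(0, 0, 150, 182)).x_med
        assert abs(corrupted - clean) < 0.1

    @pytest.mark.parametrize("frac", [0.1, 0.25, 0.39])
    def test_median_robustness_property(self, frac):
        """< 40% outlier rows shift the median by < 0.1 px."""
        rng = np.random.default_rng(int(frac * 100))
        img = self._roi_image(noise_sd=3.0, rng=rng)
        clean = read_roi(img, Rect(0, 0, 150, 182)).x_med
        bad = img.copy()
        n_bad = int(frac * 150)
        idx = rng.choice(150, size=n_bad, replace=False)
        # outlier bars at a wrong position
        x = np.arange(182.0)
        bad[idx] = 300.0 + 500.0 * np.exp(-0.5 * ((x - 30.0) / 5.1) ** 2)
        assert abs(read_roi(bad, Rect(0, 0, 150, 182)).x_med - clean) < 0.1

    def test_flat_roi_fails_qc(self):
        r = read_roi(np.full((150, 182), 300.0), Rect(0, 0, 150, 182))
        assert not r.qc_pass
        assert r.n_rows_used == 0
        assert np.isnan(r.x_med)

    def test_few_converged_rows_reported_but_flagged(self):
        img = np.full((60, 182), 300.0)
        x = np.arange(182.0)
        img[:10] = 300.0 + 500.0 * np.exp(-0.5 * ((x - 91.0) / 5.1) ** 2)
        r = read_roi(img, Rect(0, 0, 60, 182), min_rows=50)
        assert not r.qc_pass
        assert 3 <= r.n_rows_used < 50
        assert r.x_med == pytest.approx(91.0, abs=0.01)

    @pytest.mark.parametrize("fwhm,snr", [(6, 5), (12, 20), (24, 50), (24, 5), (6, 50)])
    def test_recovery_across_bar_widths_and_snr(self, fwhm, snr):
        """Tracking works over FWHM 6-24 px and amplitude SNR 5-50."""
        rng = np.random.default_rng(fwhm * snr)
        read_noise = 25.0
        x = np.arange(182.0)
        row = 300.0 + snr * read_noise * np.exp(-0.5 * ((x - 77.7) / (fwhm / 2.3548)) ** 2)
        img = np.tile(row, (150, 1)) + rng.normal(0, read_noise, (150, 182))
        r = read_roi(img, Rect(0, 0, 150, 182))
        assert r.qc_pass
        assert r.x_med == pytest.approx(77.7, abs=0.5)


class TestDifferentialShift:
    geom = SensorPairGeom("p", Rect(0, 0, 10, 50), Rect(0, 60, 10, 50), 1, -1)

    @staticmethod
    def _read(x):
        return ResonanceRead(x_med=x, iqr_px=0.1, n_rows_used=150, qc_pass=True)

    def test_rigid_translation_cancels(self):
        d = differential_shift(self._read(23.0), self._read(83.0), self.geom, 20.0, 80.0)
        assert d == pytest.approx((3.0 - 3.0) / 2)
        assert d == 0.0

    def test_single_member_shift_halves(self):
        d = differential_shift(self._read(22.0), self._read(80.0), self.geom, 20.0, 80.0)
        assert d == pytest.approx(1.0)

    def test_spectral_shift_adds(self):
        # +s px on A, -s px on B (signs +1/-1) -> differential = +s
        s = 9.2
        d = differential_shift(self._read(20.0 + s), self._read(80.0 - s), self.geom, 20.0, 80.0)
        assert d == pytest.approx(s)

    def test_missing_read_gives_nan(self):
        bad = ResonanceRead(x_med=float("nan"), iqr_px=float("nan"), n_rows_used=0, qc_pass=False)
        assert np.isnan(differential_shift(bad, self._read(80.0), self.geom, 20.0, 80.0))


class TestDetectRois:
    def test_small_chip_detected(self, setup1):
        layout = make_default_layout(setup1, 6)
        img, _ = render_frame(layout, 647.1, setup1, NoiseModel(), seed=4)
        det = detect_rois(img)
        assert det.n_pairs == 6
        assert det.n_rois == 12
        for truth, found in zip(layout.pairs, det.pairs):
            for r, f in zip(truth.rois, found.rois):
                inter = max(0, min(r.row1, f.row1) - max(r.row0, f.row0)) * max(
                    0, min(r.col1, f.col1) - max(r.col0, f.col0)
                )
                assert inter >= 0.9 * r.height * r.width

    def test_translation_recovered_with_hint(self, setup1):
        layout = make_default_layout(setup1, 4)
        img, _ = render_frame(layout, 647.1, setup1)
        shifted = np.full_like(img, 200)
        shifted[7:, :] = img[:-7, :]
        det = detect_rois(shifted, layout_hint=layout)
        assert det.meta["registered_shift"] == [7, 0]
        assert det.pairs[0].roi_a.row0 == layout.pairs[0].roi_a.row0 + 7

    def test_blank_image_raises(self):
        with pytest.raises(DetectionError):
            detect_rois(np.full((200, 200), 131, dtype=np.uint16))


class TestTrackStack:
    def test_noiseless_oracle_equivalence(self, setup1):
        """On a noiseless stack the tracked differential equals the generator
        ground truth to < 0.05 px for every pair and frame."""
        layout = make_default_layout(setup1, 2)
        sc = BindingScenario.single_step(4.16e-3, 0.0374, baseline_s=15, duration_s=120)
        stack = simulate_stack(layout, sc, setup1, QUIET, frame_period_s=5.0, seed=0)
        traces = track_stack(stack, layout, setup1)
        gt = stack.ground_truth
        for tr in traces:
            truth = gt[gt.pair_id == tr.pair_id].shift_px.to_numpy()
            assert np.max(np.abs(tr.shift_px - truth)) < 0.05
            assert tr.qc.all()

    def test_sweep_oracle_equivalence(self, setup1, tiny_layout):
        lam = np.arange(647.0, 649.01, 0.4)
        stack = simulate_sweep(tiny_layout, lam, 36.8, setup1, QUIET, seed=0)
        traces = track_stack(stack, tiny_layout, setup1)
        gt = stack.ground_truth
        for tr in traces:
            truth = gt[gt.pair_id == tr.pair_id].shift_px.to_numpy()
            assert np.max(np.abs(tr.shift_px - truth)) < 0.05

    def test_common_mode_rejection(self, setup1):
        """Pure jitter: differential variance < 1% of single-grating variance,
        and the RIU trace SD is reduced >= 10x."""
        layout = make_default_layout(setup1, 1)
        noise = NoiseModel(read_noise_sd=0.0, shot_noise=False, jitter_sd_px=1.5)
        sc = BindingScenario(baseline_s=40.0, duration_s=40.0)
        stack = simulate_stack(layout, sc, setup1, noise, seed=9)
        (tr,) = track_stack(stack, layout, setup1)
        single = tr.raw_a - tr.raw_a.mean()
        assert np.var(tr.shift_px) < 0.01 * np.var(single)
        assert np.std(single) / max(np.std(tr.shift_px), 1e-12) >= 10

    def test_zero_length_stack_gives_empty_traces(self, setup1, tiny_layout):
        stack = FrameStack(
            frames=np.empty((0, *tiny_layout.image_shape), dtype=np.uint16),
            kind="timeseries",
            t_s=np.empty(0),
        )
        traces = track_stack(stack, tiny_layout, setup1)
        assert len(traces) == tiny_layout.n_pairs
        assert all(len(tr.shift_px) == 0 for tr in traces)

    def test_pair_order_invariance(self, setup1):
        """Row fits and pair reads are independent: permuting the layout's
        pair list permutes, but never changes, the per-pair results."""
        from cgmr.layout import ArrayLayout

        layout = make_default_layout(setup1, 3)
        lam = np.arange(647.0, 648.01, 0.2)
        stack = simulate_sweep(layout, lam, 36.8, setup1, NoiseModel(), seed=5)
        fwd = {tr.pair_id: tr for tr in track_stack(stack, layout, setup1)}
        shuffled = ArrayLayout(
            pairs=[layout.pairs[i] for i in (2, 0, 1)],
            image_shape=layout.image_shape,
            setup_name=layout.setup_name,
        )
        for tr in track_stack(stack, shuffled, setup1):
            np.testing.assert_array_equal(tr.shift_px, fwd[tr.pair_id].shift_px)

    def test_layout_stack_mismatch_rejected(self, setup1, tiny_layout):
        stack = FrameStack(
            frames=np.zeros((1, 10, 10), dtype=np.uint16), kind="timeseries", t_s=[0.0]
        )
        with pytest.raises(ValueError):
            track_stack(stack, tiny_layout, setup1)
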