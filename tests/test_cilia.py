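"""Per-pixel FFT CBF pipeline: spectra, smoothing, thresholding, CBF."""

import numpy as np
import pytest

from ciliashift.cilia import (
    CBFParams,
    PeakMap,
    SpectrumField,
    classify_signal_noise,
    noise_reference_spectrum,
    pixel_power_spectra,
    preprocess_stack,
    primary_peak_map,
    run_cbf,
    signal_spectrum_cbf,
    smooth_spectra,
    temporal_color_projection,
)


def brute_force_power(series, acq):
    """O(T^2) DFT oracle for one pixel's time series."""
    T = len(series)
    ks = np.arange(T // 2 + 1)
    power = np.empty(len(ks))
    for i, k in enumerate(ks):
        coeff = sum(
            series[t] * np.exp(-2j * np.pi * k * t / T) for t in range(T)
        )
        power[i] = abs(coeff) ** 2
    return ks * acq / T, power


def single_pixel_field(power, acq=250.0, T=None):
    T = T if T is not None else 2 * (len(power) - 1)
    freqs = np.fft.rfftfreq(T, d=1.0 / acq)[: len(power)]
    return SpectrumField(freqs=freqs, power=np.asarray(power, float)[:, None, None])


class TestSpectra:
    def test_constant_series_has_only_dc_power(self):
        stack = np.full((16, 2, 2), 37, dtype=np.uint8)
        field = pixel_power_spectra(stack, 250.0)
        assert np.allclose(field.power[1:], 0.0, atol=1e-6)
        assert field.power[0].min() > 0

    def test_exact_bin_sinusoid_concentrates_in_one_bin(self):
        T, acq, f = 250, 250.0, 20.0
        t = np.arange(T) / acq
        series = 100 + 30 * np.sin(2 * np.pi * f * t)
        stack = np.tile(series[:, None, None], (1, 2, 2))
        field = pixel_power_spectra(stack, acq)
        k = int(f * T / acq)
        nondc = field.power[1:, 0, 0].copy()
        assert np.argmax(nondc) == k - 1
        nondc[k - 1] = 0
        assert nondc.max() < 1e-12 * field.power[k, 0, 0]

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(7)
        series = rng.uniform(0, 255, 16)
        stack = series[:, None, None]
        field = pixel_power_spectra(stack, 250.0)
        freqs, expected = brute_force_power(series, 250.0)
        assert np.allclose(field.freqs, freqs)
        assert np.allclose(field.power[:, 0, 0], expected, rtol=1e-9, atol=1e-9)

    def test_bin_spacing(self):
        stack = np.zeros((512, 1, 1), dtype=np.uint8)
        field = pixel_power_spectra(stack, 250.0)
        assert field.bin_spacing == pytest.approx(250.0 / 512)


class TestSmoothing:
    def test_flat_spectrum_unchanged(self):
        field = single_pixel_field(np.ones(64))
        sm = smooth_spectra(field, 5 * field.bin_spacing)
        assert np.allclose(sm.power, 1.0)

    def test_interior_impulse_spreads_evenly(self):
        power = np.zeros(64)
        power[30] = 1.0
        field = single_pixel_field(power)
        sm = smooth_spectra(field, 5 * field.bin_spacing)
        out = sm.power[:, 0, 0]
        assert np.allclose(out[28:33], 0.2)
        assert np.allclose(np.delete(out, range(28, 33)), 0.0)

    def test_interior_power_conserved(self):
        rng = np.random.default_rng(3)
        power = np.zeros(64)
        power[10:50] = rng.uniform(0, 5, 40)
        field = single_pixel_field(power)
        sm = smooth_spectra(field, 5 * field.bin_spacing)
        assert sm.power.sum() == pytest.approx(power.sum(), rel=1e-12)

    def test_subbin_window_rejected(self):
        field = single_pixel_field(np.ones(64))
        with pytest.raises(ValueError):
            smooth_spectra(field, 0.1 * field.bin_spacing)


class TestPrimaryPeak:
    def test_out_of_range_peak_excluded(self):
        T, acq = 250, 250.0
        power = np.zeros(T // 2 + 1)
        power[2] = 10.0  # 2 Hz, below f_min
        power[20] = 5.0  # 20 Hz
        field = single_pixel_field(power, acq, T)
        peaks = primary_peak_map(field, CBFParams(), acq)
        assert peaks.frequency[0, 0] == pytest.approx(20.0)

    def test_all_zero_ties_to_lowest_in_band_frequency(self):
        T, acq = 250, 250.0
        field = single_pixel_field(np.zeros(T // 2 + 1), acq, T)
        peaks = primary_peak_map(field, CBFParams(), acq)
        assert peaks.frequency[0, 0] == pytest.approx(3.0)
        assert peaks.power[0, 0] == 0.0

    def test_sinusoid_pixel_recovers_frequency(self):
        T, acq, f = 250, 250.0, 20.0
        t = np.arange(T) / acq
        stack = (100 + 30 * np.sin(2 * np.pi * f * t))[:, None, None]
        field = pixel_power_spectra(stack, acq)
        peaks = primary_peak_map(field, CBFParams(), acq)
        assert peaks.frequency[0, 0] == pytest.approx(f)


class TestClassification:
    def test_identical_powers_give_no_signal(self):
        peaks = PeakMap(frequency=np.full((10, 10), 20.0), power=np.full((10, 10), 7.0))
        mask, threshold = classify_signal_noise(peaks, CBFParams())
        assert threshold == pytest.approx(7.0)
        assert mask.sum() == 0  # strictly-above rule

    def test_hand_computed_threshold(self):
        power = np.concatenate([np.zeros(4), np.full(96, 100.0)]).reshape(10, 10)
        peaks = PeakMap(frequency=np.full((10, 10), 20.0), power=power)
        mask, threshold = classify_signal_noise(peaks, CBFParams())
        # bottom 20 pixels: 4 zeros + 16 hundreds -> mean 80, sd 40 -> 140
        assert threshold == pytest.approx(80 + 1.5 * 40)
        assert mask.sum() == 0
        # with all-zero bottom quintile the threshold collapses to 0
        power2 = np.concatenate([np.zeros(20), np.full(80, 100.0)]).reshape(10, 10)
        mask2, thr2 = classify_signal_noise(
            PeakMap(frequency=np.full((10, 10), 20.0), power=power2), CBFParams()
        )
        assert thr2 == pytest.approx(0.0)
        assert mask2.sum() == 80

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        power = rng.uniform(0, 10, (8, 8))
        peaks = PeakMap(frequency=np.full((8, 8), 20.0), power=power)
        mask1, thr1 = classify_signal_noise(peaks, CBFParams())
        doubled = PeakMap(frequency=peaks.frequency, power=2 * power)
        mask2, thr2 = classify_signal_noise(doubled, CBFParams())
        assert thr2 == pytest.approx(2 * thr1)
        assert np.array_equal(mask1, mask2)

    def test_too_few_pixels_rejected(self):
        peaks = PeakMap(frequency=np.zeros((2, 2)), power=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            classify_signal_noise(peaks, CBFParams())


class TestNoiseSpectrum:
    def test_identical_noise_pixels_reproduce_spectrum(self):
        power = np.tile(np.arange(5.0)[:, None, None], (1, 2, 2))
        field = SpectrumField(freqs=np.arange(5.0), power=power)
        out = noise_reference_spectrum(field, np.ones((2, 2), bool), CBFParams())
        assert np.allclose(out, np.arange(5.0))

    def test_two_pixel_hand_computation(self):
        power = np.stack([np.array([[0.0, 2.0]])] * 3)  # 3 bins, powers 0 and 2
        field = SpectrumField(freqs=np.arange(3.0), power=power)
        out = noise_reference_spectrum(field, np.ones((1, 2), bool), CBFParams())
        assert np.allclose(out, 2.5)  # mean 1 + 1.5 * population SD 1

    def test_dominates_per_bin_mean(self):
        rng = np.random.default_rng(2)
        power = rng.uniform(0, 5, (6, 4, 4))
        field = SpectrumField(freqs=np.arange(6.0), power=power)
        out = noise_reference_spectrum(field, np.ones((4, 4), bool), CBFParams())
        assert (out >= power.mean(axis=(1, 2)) - 1e-12).all()

    def test_empty_noise_set_rejected(self):
        field = SpectrumField(freqs=np.arange(3.0), power=np.zeros((3, 2, 2)))
        with pytest.raises(ValueError):
            noise_reference_spectrum(field, np.zeros((2, 2), bool), CBFParams())


class TestCellSpectrum:
    def test_noise_dominates_everywhere_undefined_cbf(self):
        T, acq = 250, 250.0
        power = np.ones((T // 2 + 1, 1, 1))
        field = SpectrumField(freqs=np.fft.rfftfreq(T, 1 / acq), power=power)
        report = signal_spectrum_cbf(
            field, np.ones((1, 1), bool), np.full(T // 2 + 1, 5.0), CBFParams(), acq
        )
        assert not report.defined
        assert np.isnan(report.cbf_hz)
        assert np.allclose(report.cell_spectrum, 0.0)

    def test_single_pixel_peak_sets_cbf(self):
        T, acq = 250, 250.0
        power = np.zeros((T // 2 + 1, 1, 1))
        power[22] = 10.0  # 22 Hz bin
        field = SpectrumField(freqs=np.fft.rfftfreq(T, 1 / acq), power=power)
        report = signal_spectrum_cbf(
            field, np.ones((1, 1), bool), np.zeros(T // 2 + 1), CBFParams(), acq
        )
        assert report.defined
        assert report.cbf_hz == pytest.approx(22.0)


class TestRunCbf:
    def test_recovers_planted_frequency(self, beating_stack):
        stack, truth = beating_stack
        report = run_cbf(stack, truth.config.acquisition_frequency)[0]
        bin_width = truth.config.acquisition_frequency / truth.config.n_frames
        assert report.defined
        assert abs(report.cbf_hz - 22.0) <= bin_width

    def test_deterministic(self, beating_stack):
        stack, truth = beating_stack
        r1 = run_cbf(stack, 250.0)[0]
        r2 = run_cbf(stack, 250.0)[0]
        assert r1.cbf_hz == r2.cbf_hz
        assert np.array_equal(r1.signal_mask, r2.signal_mask)

    def test_two_rois_recover_their_own_frequencies(self):
        from ciliashift.simulate import CiliaRegion, CiliaSimConfig, generate_cilia_stack

        m1 = np.zeros((64, 64), bool)
        m1[8:28, 8:28] = True
        m2 = np.zeros((64, 64), bool)
        m2[36:56, 36:56] = True
        config = CiliaSimConfig(
            height=64, width=64, n_frames=256, acquisition_frequency=250.0,
            regions=(
                CiliaRegion(mask=m1, frequency=12.0, amplitude=30.0),
                CiliaRegion(mask=m2, frequency=25.0, amplitude=30.0),
            ),
            noise_sd=10.0, seed=5,
        )
        stack, _ = generate_cilia_stack(config)
        # each ROI covers one region plus surrounding background
        roi1 = np.zeros((64, 64), bool)
        roi1[:, :32] = True
        roi2 = ~roi1
        reports = run_cbf(stack, 250.0, rois=[roi1, roi2])
        bin_width = 250.0 / 256
        assert abs(reports[0].cbf_hz - 12.0) <= bin_width
        assert abs(reports[1].cbf_hz - 25.0) <= bin_width

    def test_dc_offset_invariance(self, beating_stack):
        stack, _ = beating_stack
        base = run_cbf(stack, 250.0)[0]
        shifted = np.clip(stack.astype(np.int64) + 40, 0, 255).astype(np.uint8)
        moved = run_cbf(shifted, 250.0)[0]
        assert moved.cbf_hz == pytest.approx(base.cbf_hz, abs=250.0 / 256)

    def test_constant_stack_has_no_signal(self):
        stack = np.full((64, 16, 16), 120, dtype=np.uint8)
        report = run_cbf(stack, 250.0)[0]
        assert report.n_signal_pixels == 0
        assert not report.defined

    def test_amplitude_monotonicity_of_signal_pixels(self, square_region_mask):
        from ciliashift.simulate import CiliaRegion, CiliaSimConfig, generate_cilia_stack

        counts = []
        for amplitude in (10.0, 20.0, 40.0):
            config = CiliaSimConfig(
                height=64, width=64, n_frames=256,
                regions=(CiliaRegion(mask=square_region_mask, frequency=22.0,
                                     amplitude=amplitude),),
                noise_sd=5.0, seed=9,
            )
            stack, _ = generate_cilia_stack(config)
            counts.append(run_cbf(stack, 250.0)[0].n_signal_pixels)
        assert counts[0] <= counts[1] <= counts[2]

    def test_signal_pixel_recall_at_high_snr(self, beating_stack):
        stack, truth = beating_stack
        report = run_cbf(stack, truth.config.acquisition_frequency)[0]
        oscillating = truth.frequency_map > 0
        recall = (report.signal_mask & oscillating).sum() / oscillating.sum()
        assert recall >= 0.90


class TestPreprocessing:
    def test_inversion_and_static_stack(self):
        # a time-constant stack collapses to zero after median subtraction
        rng = np.random.default_rng(4)
        frame = rng.integers(0, 255, (16, 16), dtype=np.uint8)
        stack = np.tile(frame, (8, 1, 1))
        out = preprocess_stack(stack)
        assert out.dtype == np.uint8
        assert out.max() == 0

    def test_moving_pixel_survives_static_pixel_removed(self):
        T = 8
        stack = np.full((T, 16, 16), 255, dtype=np.uint8)
        stack[:, 4, 4] = 0  # static dark spot (bright after inversion)
        for t in range(T):
            stack[t, 10, 2 + t] = 0  # moving dark spot
        out = preprocess_stack(stack).astype(float)
        moving_energy = sum(out[t, 10, 2 + t] for t in range(T))
        assert out[:, 4, 4].max() == 0
        assert moving_energy > 0

    def test_color_projection_assigns_frame_colors(self):
        stack = np.zeros((2, 8, 8), dtype=np.uint8)
        stack[0, 2, 2] = 255
        stack[1, 5, 5] = 255
        rgb = temporal_color_projection(stack, lut_name="jet")
        import matplotlib.pyplot as plt

        cmap = plt.get_cmap("jet")
        assert np.allclose(rgb[2, 2], cmap(0.0)[:3], atol=1e-6)
        assert np.allclose(rgb[5, 5], cmap(1.0)[:3], atol=1e-6)
        assert np.allclose(rgb[0, 0], 0.0)

    def test_single_frame_projection_is_monochrome_tint(self):
        stack = np.zeros((3, 4, 4), dtype=np.uint8)
        stack[1, 1, 1] = 200
        rgb = temporal_color_projection(stack, start_frame=1, end_frame=2)
        import matplotlib.pyplot as plt

        tint = np.array(plt.get_cmap("jet")(0.0)[:3])
        assert np.allclose(rgb[1, 1], (200 / 255) * tint, atol=1e-6)

    def test_empty_range_rejected(self):
        stack = np.zeros((3, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            temporal_color_projection(stack, start_frame=2, end_frame=2)
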