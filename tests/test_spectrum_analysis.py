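import numpy as np
import pytest

from eedn.image_io import GeometrySpec, ImageFrame
from eedn.noise_sim import NoiseSpec, add_poisson_noise
from eedn.phantom import dataset_specs, default_template, generate_phantom
from eedn.spectrum_analysis import (
    Band,
    average_transfer_ratio,
    band_consensus,
    bandpass_filter,
    nyquist_cycles_per_mm,
    radial_profile,
    transfer_ratio,
)

UNIT_GEO = GeometrySpec(0.5, 1000.0, 1000.0)  # magnification 1, Nyquist 1.0


def brute_force_profile(arr):
    """Direct double-loop evaluation of the radially averaged magnitude."""
    mag = np.abs(np.fft.fftshift(np.fft.fft2(arr)))
    rows, cols = arr.shape
    sums, counts = {}, {}
    for i in range(rows):
        for j in range(cols):
            u, v = i - rows // 2, j - cols // 2
            r = int(np.floor(np.hypot(u, v)))
            sums[r] = sums.get(r, 0.0) + mag[i, j]
            counts[r] = counts.get(r, 0) + 1
    rmax = max(sums)
    return np.array([sums[r] / counts[r] for r in range(rmax + 1)])


class TestRadialProfile:
    def test_constant_frame_has_only_dc_energy(self):
        profile = radial_profile(np.full((32, 32), 50.0))
        assert profile.s_of_r[0] > 0
        np.testing.assert_allclose(profile.s_of_r[1:], 0.0, atol=1e-8)

    def test_pure_cosine_peaks_at_its_annulus(self):
        x = np.arange(64)
        frame = 100.0 + 50.0 * np.cos(2 * np.pi * 8 * x / 64)
        arr = np.tile(frame, (64, 1))
        profile = radial_profile(arr)
        assert int(np.argmax(profile.s_of_r[1:])) + 1 == 8

    def test_conservation_identity_on_random_frames(self, rng):
        for _ in range(10):
            arr = rng.normal(size=(24, 24)) * 50 + 100
            profile = radial_profile(arr)
            total = np.abs(np.fft.fft2(arr)).sum()
            assert profile.total_magnitude() == pytest.approx(total, rel=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            arr = rng.normal(size=(16, 16)) * 30 + 80
            profile = radial_profile(arr)
            np.testing.assert_allclose(profile.s_of_r, brute_force_profile(arr), rtol=1e-9)

    def test_frequency_axis_reaches_nyquist(self):
        frame = ImageFrame(np.zeros((64, 64)) + 10, 8, pixel_spacing_mm=0.5)
        profile = radial_profile(frame)
        assert profile.nyquist_cpmm == pytest.approx(1.0)
        assert profile.cycles_per_mm[profile.nyquist_index] == pytest.approx(1.0)

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.zeros((4, 4)))


class TestNyquist:
    def test_unit_magnification(self):
        assert nyquist_cycles_per_mm(GeometrySpec(0.5, 1000.0, 1000.0)) == pytest.approx(1.0)

    def test_magnification_correction(self):
        # 0.4 mm detector spacing demagnified by 800/1000 -> 0.32 mm
        assert nyquist_cycles_per_mm(GeometrySpec(0.4, 1000.0, 800.0)) == pytest.approx(1.5625)

    def test_decreasing_in_detector_spacing(self):
        values = [nyquist_cycles_per_mm(GeometrySpec(s, 1000.0, 800.0)) for s in (0.2, 0.4, 0.8)]
        assert values[0] > values[1] > values[2]

    def test_increasing_in_sid_at_fixed_sed(self):
        values = [nyquist_cycles_per_mm(GeometrySpec(0.4, sid, 800.0)) for sid in (900.0, 1200.0, 1500.0)]
        assert values[0] < values[1] < values[2]


class TestTransferRatio:
    def test_profile_against_itself_is_unity(self, rng):
        p = radial_profile(rng.normal(size=(32, 32)) + 100)
        ratio = transfer_ratio(p, p)
        defined = ~np.isnan(ratio)
        np.testing.assert_allclose(ratio[defined], 1.0, rtol=1e-12)

    def test_scalar_multiplication_scales_ratio(self, rng):
        arr = rng.normal(size=(32, 32)) + 100
        ratio = transfer_ratio(radial_profile(0.5 * arr), radial_profile(arr))
        defined = ~np.isnan(ratio)
        np.testing.assert_allclose(ratio[defined], 0.5, rtol=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        a = radial_profile(rng.normal(size=(16, 16)))
        b = radial_profile(rng.normal(size=(32, 32)))
        with pytest.raises(ValueError):
            transfer_ratio(a, b)

    def test_noise_raises_high_frequency_magnitude(self):
        # on 20 phantom pairs the noisy/clean mean ratio exceeds 1 in the
        # top quartile of annuli inside the Nyquist range
        specs = dataset_specs(default_template(size=(96, 96)), 20, seed=31)
        nums, dens = [], []
        for i, spec in enumerate(specs):
            clean = generate_phantom(spec)
            noisy = add_poisson_noise(clean, NoiseSpec(mu_percent=60.0, seed=400 + i))
            nums.append(radial_profile(noisy, UNIT_GEO))
            dens.append(radial_profile(clean, UNIT_GEO))
        mean, _ = average_transfer_ratio(nums, dens)
        within = nums[0].up_to_nyquist()
        top = mean[within][int(np.ceil(0.75 * within.sum())):]
        assert np.nanmean(top) > 1.0


class TestBandpass:
    def make_frame(self, arr):
        return ImageFrame(arr, 8, pixel_spacing_mm=0.5)

    def test_full_band_is_identity(self, rng):
        frame = self.make_frame(rng.normal(size=(64, 64)) * 20 + 100)
        out = bandpass_filter(frame, Band(0.0, 1.0))
        np.testing.assert_allclose(out.pixels, frame.pixels, rtol=1e-6, atol=1e-6)

    def test_two_tone_selectivity(self):
        # tones at 8 and 40 cycles across a 128-px frame at 0.5 mm spacing:
        # 0.125 and 0.625 cycles/mm; the band keeps the first only
        x = np.arange(128)
        in_band = 20.0 * np.cos(2 * np.pi * 8 * x / 128)
        out_band = 20.0 * np.cos(2 * np.pi * 40 * x / 128)
        frame = self.make_frame(np.tile(100.0 + in_band + out_band, (128, 1)))
        filtered = bandpass_filter(frame, Band(0.05, 0.3))
        spec = np.abs(np.fft.fft2(filtered.pixels))
        original = np.abs(np.fft.fft2(frame.pixels))
        assert spec[0, 40] < original[0, 40] / 100.0
        assert spec[0, 8] == pytest.approx(original[0, 8], rel=0.01)

    def test_dc_removed_when_lower_edge_positive(self, rng):
        frame = self.make_frame(rng.normal(size=(32, 32)) + 120)
        out = bandpass_filter(frame, Band(0.1, 0.5))
        assert abs(out.pixels.mean()) < 1e-8

    def test_idempotent(self, rng):
        frame = self.make_frame(rng.normal(size=(32, 32)) * 10 + 100)
        band = Band(0.1, 0.6)
        once = bandpass_filter(frame, band)
        twice = bandpass_filter(once, band)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-9)

    def test_band_beyond_nyquist_rejected(self, rng):
        frame = self.make_frame(rng.normal(size=(32, 32)) + 100)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(frame, Band(0.1, 1.5))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            Band(0.3, 0.2)


class TestBandConsensus:
    def test_single_selection_is_its_own_consensus(self):
        overall, consensus = band_consensus([(0.05, 0.25)])
        assert overall == Band(0.05, 0.25) and consensus == Band(0.05, 0.25)

    def test_overall_spans_and_consensus_intersects(self):
        overall, consensus = band_consensus([(0.02, 0.39), (0.10, 0.23)])
        assert overall == Band(0.02, 0.39)
        assert consensus == Band(0.10, 0.23)

    def test_disjoint_selections_have_empty_consensus(self):
        overall, consensus = band_consensus([(0.1, 0.2), (0.3, 0.4)])
        assert overall == Band(0.1, 0.4) and consensus is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            band_consensus([])
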