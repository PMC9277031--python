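"""SD-OCT reconstruction: closed-form figures of merit and Fourier round trips."""

import numpy as np
import pytest

from seedoct.phantom import synthesize_spectral_frame
from seedoct.reconstruction import (AScan, BScan, SourceSpec, SpectralFrame,
                                    assemble_bscan, average_ascans,
                                    axial_resolution, max_imaging_depth,
                                    read_bscan_tiff, read_spectral_stack,
                                    reconstruct_ascan, write_bscan_tiff,
                                    write_spectral_stack)

SRC = SourceSpec()


class TestFiguresOfMerit:
    def test_axial_resolution_closed_form(self):
        # (2 ln2/pi) * 840^2 / 50 nm = 6.23 um in air
        assert axial_resolution(SRC, 1.0) == pytest.approx(6.227, abs=0.005)

    def test_axial_resolution_scalings(self):
        wide = SourceSpec(bandwidth_fwhm_nm=100.0)
        assert axial_resolution(wide) == pytest.approx(axial_resolution(SRC) / 2)
        assert axial_resolution(SRC, 2.0) == pytest.approx(axial_resolution(SRC, 1.0) / 2)

    def test_axial_resolution_rejects_subunity_index(self):
        with pytest.raises(ValueError):
            axial_resolution(SRC, 0.5)

    def test_max_imaging_depth_closed_form(self):
        # 840^2 / (4 * 0.09) nm = 1.96 mm
        assert max_imaging_depth(SRC) == pytest.approx(1.96, abs=0.005)

    def test_max_imaging_depth_scalings(self):
        fine = SourceSpec(spectrometer_resolution_nm=0.045)
        assert max_imaging_depth(fine) == pytest.approx(2 * max_imaging_depth(SRC))
        degenerate = SourceSpec(center_wavelength_nm=0.0)
        assert max_imaging_depth(degenerate) == 0.0


def lockin_depth_oracle(frame: SpectralFrame, z_grid_um: np.ndarray) -> float:
    """Independent localization: lock-in correlation with cos(2kz) on the raw grid."""
    k = 2 * np.pi / frame.wavelengths_nm          # rad/nm
    spec = frame.intensities - frame.intensities.mean()
    amps = [abs(np.sum(spec * np.exp(2j * k * z * 1e3))) for z in z_grid_um]
    return float(z_grid_um[int(np.argmax(amps))])


class TestReconstruction:
    @pytest.mark.parametrize("depth_um", [200.0, 500.0, 1000.0, 1500.0])
    def test_single_reflector_localized_within_one_pixel(self, depth_um):
        frame = synthesize_spectral_frame(None, [(depth_um, 0.01)], SRC)
        a = reconstruct_ascan(frame, SRC)
        peak = a.optical_depths_um[np.argmax(a.log_magnitude_db)]
        assert abs(peak - depth_um) <= a.depth_pixel_um

    def test_peak_bin_matches_lockin_oracle(self):
        frame = synthesize_spectral_frame(None, [(1000.0, 0.01)], SRC)
        a = reconstruct_ascan(frame, SRC)
        grid = np.arange(900.0, 1100.0, 0.25)
        oracle = lockin_depth_oracle(frame, grid)
        peak = a.optical_depths_um[np.argmax(a.log_magnitude_db)]
        assert abs(peak - oracle) <= a.depth_pixel_um

    def test_dc_only_frame_reconstructs_to_floor(self):
        frame = SpectralFrame(SRC.wavelength_grid_nm(), np.ones(SRC.n_spectral_pixels))
        a = reconstruct_ascan(frame, SRC)
        # background removal annihilates the constant term: flat floor, no structure
        assert np.ptp(a.log_magnitude_db) == 0.0

    def test_zero_reflectors_gives_noise_floor_only(self, rng):
        frame = synthesize_spectral_frame(None, [], SRC, rng, noise_scale=1e-4)
        a = reconstruct_ascan(frame, SRC)
        signal = synthesize_spectral_frame(None, [(800.0, 0.01)], SRC)
        b = reconstruct_ascan(signal, SRC)
        # no dominant echo: the strongest bin sits an order of magnitude below
        # the equivalent reflector peak
        assert a.linear_magnitude().max() < b.linear_magnitude().max() / 10

    def test_resolution_limit_straddled(self):
        """3 um separation merges into one peak; 20 um resolves into two."""
        from scipy.signal import find_peaks

        def n_peaks(sep_um):
            frame = synthesize_spectral_frame(None, [(500.0, 0.01), (500.0 + sep_um, 0.01)], SRC)
            a = reconstruct_ascan(frame, SRC)
            region = (a.optical_depths_um > 450) & (a.optical_depths_um < 570)
            idx, _ = find_peaks(a.log_magnitude_db[region], prominence=20.0)
            return len(idx)

        assert n_peaks(3.0) == 1
        assert n_peaks(20.0) == 2

    def test_depth_axis_calibration_slope_one(self):
        """Reported peak depth is linear in planted depth: slope 1, intercept < 1 px."""
        planted = np.linspace(100, 1800, 10)
        found = []
        for z in planted:
            frame = synthesize_spectral_frame(None, [(z, 0.01)], SRC)
            a = reconstruct_ascan(frame, SRC)
            found.append(a.optical_depths_um[np.argmax(a.log_magnitude_db)])
        slope, intercept = np.polyfit(planted, found, 1)
        assert slope == pytest.approx(1.0, abs=5e-3)
        assert abs(intercept) < a.depth_pixel_um

    def test_energy_grows_with_reflectivity(self):
        energies = []
        for refl in (0.001, 0.01, 0.1):
            frame = synthesize_spectral_frame(None, [(700.0, refl)], SRC)
            a = reconstruct_ascan(frame, SRC)
            energies.append(np.sum(a.linear_magnitude() ** 2))
        assert energies[0] < energies[1] < energies[2]

    def test_invalid_frames_rejected(self):
        lam = SRC.wavelength_grid_nm()
        with pytest.raises(ValueError):
            SpectralFrame(lam**1.01, np.ones_like(lam))  # non-uniform
        bad = np.ones_like(lam)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            reconstruct_ascan(SpectralFrame(lam, bad), SRC)

    def test_reflector_beyond_max_depth_names_alias(self):
        with pytest.raises(ValueError, match="alias"):
            synthesize_spectral_frame(None, [(3000.0, 0.01)], SRC)


class TestBScanAssembly:
    def test_column_count_and_equality(self):
        frames = [synthesize_spectral_frame(None, [(300.0 + 10 * i, 0.01)], SRC)
                  for i in range(5)]
        b = assemble_bscan(frames, SRC)
        assert b.n_lateral == 5
        col2 = reconstruct_ascan(frames[2], SRC)
        np.testing.assert_allclose(b.image[:, 2], col2.log_magnitude_db)

    def test_single_frame_width_one(self):
        b = assemble_bscan([synthesize_spectral_frame(None, [(300.0, 0.01)], SRC)], SRC)
        assert b.n_lateral == 1

    def test_mixed_grid_lengths_rejected(self):
        f1 = synthesize_spectral_frame(None, [(300.0, 0.01)], SRC)
        small = SourceSpec(n_spectral_pixels=512)
        f2 = synthesize_spectral_frame(None, [(300.0, 0.01)], small)
        with pytest.raises(ValueError, match="mixed"):
            assemble_bscan([f1, f2], SRC)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_bscan([], SRC)


class TestAveraging:
    def _bscan_from_columns(self, cols):
        return BScan(np.stack(cols, axis=1), lateral_extent_mm=6.0, depth_extent_mm=2.2)

    def test_window_one_returns_column(self):
        cols = [np.linspace(-60, 0, 64) + i for i in range(5)]
        b = self._bscan_from_columns(cols)
        out = average_ascans(b, 3, window=1)
        np.testing.assert_allclose(out.log_magnitude_db, cols[3])

    def test_identical_columns_unchanged(self):
        col = np.linspace(-60, 0, 64)
        b = self._bscan_from_columns([col] * 25)
        out = average_ascans(b, 12, window=20)
        np.testing.assert_allclose(out.log_magnitude_db, col, atol=1e-9)

    def test_speckle_averaging_reduces_peak_variance(self, rng):
        """20-column averaging tightens the peak-height distribution (Monte Carlo)."""
        profile = np.exp(-((np.arange(128) - 64.0) ** 2) / 8.0)
        single, averaged = [], []
        for _ in range(150):
            speckled = profile[:, None] * rng.exponential(size=(128, 20))
            img = 20 * np.log10(np.maximum(speckled, 1e-8))
            b = BScan(img, lateral_extent_mm=1.0, depth_extent_mm=2.2)
            single.append(b.image[:, 0].max())
            averaged.append(average_ascans(b, 10, window=20).log_magnitude_db.max())
        assert np.var(averaged) < np.var(single)

    def test_center_outside_image_rejected(self):
        b = self._bscan_from_columns([np.zeros(8)] * 4)
        with pytest.raises(ValueError):
            average_ascans(b, 10, window=2)


class TestFileInterchange:
    def test_bscan_tiff_round_trip(self, tmp_path):
        img = np.random.default_rng(0).uniform(-80, 0, size=(64, 32))
        b = BScan(img, lateral_extent_mm=6.0, depth_extent_mm=2.2, timestamp_h=3.0)
        path = write_bscan_tiff(b, tmp_path / "b.tiff")
        back = read_bscan_tiff(path)[0]
        assert back.timestamp_h == 3.0
        np.testing.assert_allclose(back.image, img, atol=80 / 65535 * 1.01)

    def test_spectral_stack_round_trip(self, tmp_path):
        frames = [synthesize_spectral_frame(None, [(300.0 * (i + 1), 0.01)], SRC)
                  for i in range(3)]
        path = write_spectral_stack(frames, tmp_path / "spec.tiff")
        back = read_spectral_stack(path)
        assert len(back) == 3
        np.testing.assert_allclose(back[1].wavelengths_nm, frames[1].wavelengths_nm)
        scale = frames[1].intensities.max() - frames[1].intensities.min()
        np.testing.assert_allclose(back[1].intensities, frames[1].intensities,
                                   atol=scale / 65535 * 2)
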