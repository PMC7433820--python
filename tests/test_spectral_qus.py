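"""Window grid, spectra, normalization, band selection and the QUS estimators."""

import numpy as np
import pytest

from qusrad.rf_core import RFFrame, ROIContour, ROIMask, ValidationError, rasterize_contour
from qusrad.spectral_qus import (
    NormalizedSpectrum,
    RawSpectrum,
    WindowSpec,
    build_parametric_maps,
    build_window_grid,
    determine_band,
    estimate_ace,
    estimate_asd_aac,
    estimate_sas,
    fit_spectral_line,
    normalize_spectrum,
    phantom_depth_spectra,
    window_power_spectrum,
)
from qusrad.synthetic_rf import GAUSSIAN_FORM_FACTOR_COEF, ScattererMedium

from conftest import (
    extract_test_roi,
    make_test_medium,
    rect_contour,
    simulate_test_frame,
    TEST_WINDOW,
)

_DB10 = 10.0 / np.log(10.0)


def frame_with_rect_roi(axial_extent_mm, lateral_extent_mm=6.0, fs=40e6,
                        pitch=2e-4):
    """Noise frame whose mask is an exact rectangle of the given extent."""
    c = 1540.0
    n_ax = int(np.ceil(axial_extent_mm * 1e-3 * 2 / c * fs)) + 200
    n_ln = max(8, int(lateral_extent_mm / (pitch * 1e3)) + 10)
    rng = np.random.default_rng(0)
    fr = RFFrame(samples=rng.standard_normal((n_ax, n_ln)), sampling_rate=fs,
                 lateral_pitch=pitch)
    grid = np.zeros((n_ax, n_ln), dtype=bool)
    rows = int(round(axial_extent_mm / fr.axial_sample_mm))
    cols = int(round(lateral_extent_mm / (pitch * 1e3)))
    grid[10 : 10 + rows, 2 : 2 + cols] = True
    return fr, ROIMask(grid=grid)


class TestWindowGrid:
    def test_axial_position_count_at_92_percent_overlap(self):
        fr, mask = frame_with_rect_roi(40.0)
        grid = build_window_grid(mask, fr, WindowSpec(2.0, 2.0, 0.92))
        # floor((40 - 2) / 0.16) + 1 = 238
        assert len(grid.axial_start_mm) == 238
        assert grid.spec.step_axial_mm == pytest.approx(0.16)

    def test_zero_overlap_step_equals_window(self):
        fr, mask = frame_with_rect_roi(40.0)
        grid = build_window_grid(mask, fr, WindowSpec(2.0, 2.0, 0.0))
        assert len(grid.axial_start_mm) == 20

    def test_roi_smaller_than_window_rejected(self):
        fr, mask = frame_with_rect_roi(1.5, lateral_extent_mm=6.0)
        with pytest.raises(ValidationError, match="smaller than analysis window"):
            build_window_grid(mask, fr, WindowSpec(2.0, 2.0, 0.92))

    def test_included_windows_lie_inside_mask(self):
        fr, mask = frame_with_rect_roi(10.0, 5.0)
        # notch a corner out of the ROI
        mask.grid[10:200, 2:12] = False
        grid = build_window_grid(mask, fr, WindowSpec(2.0, 2.0, 0.5))
        for k in range(grid.shape[0]):
            for l in range(grid.shape[1]):
                if grid.include[k, l]:
                    i0, j0 = grid.axial_i0[k], grid.lateral_j0[l]
                    assert mask.grid[i0:i0 + grid.win_samples,
                                     j0:j0 + grid.win_lines].all()

    def test_grid_step_conserves_roi_extent(self):
        fr, mask = frame_with_rect_roi(23.0)
        ws = WindowSpec(2.0, 2.0, 0.92)
        grid = build_window_grid(mask, fr, ws)
        n = len(grid.axial_start_mm)
        covered = (n - 1) * ws.step_axial_mm + ws.size_axial_mm
        assert abs(covered - 23.0) <= ws.step_axial_mm + fr.axial_sample_mm


class TestWindowSpectrum:
    def test_tone_peak_at_tone_frequency(self):
        fs = 40e6
        t = np.arange(2048) / fs
        line = np.sin(2 * np.pi * 5e6 * t)
        fr = RFFrame(samples=np.tile(line[:, None], (1, 16)), sampling_rate=fs)
        sp = window_power_spectrum(fr, 100, 0, 512, 8, nfft=2048)
        peak = sp.freq_mhz[np.argmax(sp.power)]
        assert abs(peak - 5.0) <= fs / 2048 / 1e6

    def test_parseval_consistency(self):
        from scipy.signal import get_window

        rng = np.random.default_rng(1)
        fr = RFFrame(samples=rng.standard_normal((512, 16)), sampling_rate=40e6)
        n_s, n_l = 256, 8
        sp = window_power_spectrum(fr, 10, 2, n_s, n_l, nfft=2048)
        df = (sp.freq_mhz[1] - sp.freq_mhz[0]) * 1e6
        w = get_window("hann", n_s)
        seg = fr.samples[10:10 + n_s, 2:2 + n_l]
        tapered_power = np.mean(
            [(w * seg[:, j]) ** 2 for j in range(n_l)], axis=0
        ).sum() / (w**2).sum()
        assert np.sum(sp.power) * df == pytest.approx(tapered_power, rel=0.01)

    def test_white_noise_spectrum_is_flat(self):
        # Monte-Carlo: dB line fit over the band should have slope ~0
        rng = np.random.default_rng(2)
        slopes = []
        for _ in range(100):
            fr = RFFrame(samples=rng.standard_normal((512, 16)), sampling_rate=40e6)
            sp = window_power_spectrum(fr, 0, 0, 512, 16, nfft=1024)
            sel = (sp.freq_mhz >= 3) & (sp.freq_mhz <= 8.5)
            slopes.append(
                np.polyfit(sp.freq_mhz[sel], 10 * np.log10(sp.power[sel]), 1)[0]
            )
        ci = 3 * np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < ci + 0.02


class TestNormalizeAndBand:
    def _raw(self, power):
        f = np.linspace(0, 20, 201)
        return RawSpectrum(freq_mhz=f, power=power(f), depth_mm=15.0)

    def test_identity_gives_zero_db(self):
        sp = self._raw(lambda f: np.ones_like(f))
        ns = normalize_spectrum(sp, np.ones_like(sp.power))
        assert np.allclose(ns.power_db, 0.0)

    def test_tenfold_gives_plus_ten_db(self):
        sp = self._raw(lambda f: 10.0 * np.ones_like(f))
        ns = normalize_spectrum(sp, np.ones_like(sp.power))
        assert np.allclose(ns.power_db, 10.0)

    def test_grid_mismatch_rejected(self):
        sp = self._raw(lambda f: np.ones_like(f))
        with pytest.raises(ValidationError, match="grids differ"):
            normalize_spectrum(sp, np.ones(7))

    def test_nonpositive_phantom_rejected(self):
        sp = self._raw(lambda f: np.ones_like(f))
        ph = np.ones_like(sp.power)
        ph[50] = 0.0
        with pytest.raises(ValidationError, match="nonpositive"):
            normalize_spectrum(sp, ph, band_mhz=(3.0, 8.5))

    def test_six_db_band_of_gaussian_spectrum(self, pulse_model):
        f = np.linspace(0, 20, 2001)
        ph = pulse_model.amplitude_spectrum(f * 1e6) ** 2
        lo, hi = determine_band(f, ph, (3.0, 8.5))
        # -6 dB half-width is 0.85*6.5/2 = 2.76 MHz: [3.74, 9.26] n [3, 8.5]
        assert lo == pytest.approx(6.5 - 0.85 * 6.5 / 2, abs=0.05)
        assert hi == pytest.approx(8.5)

    def test_flat_spectrum_gives_metadata_band(self):
        f = np.linspace(0, 20, 201)
        lo, hi = determine_band(f, np.ones_like(f), (3.0, 8.5))
        assert (lo, hi) == (3.0, 8.5)

    def test_zero_spectrum_rejected(self):
        f = np.linspace(0, 20, 201)
        with pytest.raises(ValidationError):
            determine_band(f, np.zeros_like(f), (3.0, 8.5))


class TestSpectralLineFit:
    def _ns(self, f, db):
        return NormalizedSpectrum(freq_mhz=f, power_db=db, depth_mm=15.0)

    def test_exact_linear_spectrum_recovered(self):
        f = np.linspace(3, 8.5, 56)
        ss, si, mbf = fit_spectral_line(self._ns(f, 2.0 * f - 10.0), (3.0, 8.5))
        assert ss == pytest.approx(2.0, abs=1e-9)
        assert si == pytest.approx(-10.0, abs=1e-9)
        assert mbf == pytest.approx(2.0 * 5.75 - 10.0, abs=1e-9)

    def test_constant_zero_spectrum(self):
        f = np.linspace(3, 8.5, 56)
        ss, si, mbf = fit_spectral_line(self._ns(f, np.zeros_like(f)), (3.0, 8.5))
        assert (ss, si, mbf) == (0.0, 0.0, 0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        f = np.linspace(3, 8.5, 80)
        for _ in range(100):
            y = rng.normal(0, 5, f.size)
            ss, si, _ = fit_spectral_line(self._ns(f, y), (3.0, 8.5))
            X = np.column_stack([f, np.ones_like(f)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert ss == pytest.approx(beta[0], abs=1e-9)
            assert si == pytest.approx(beta[1], abs=1e-9)

    def test_too_few_bins_rejected(self):
        f = np.array([3.0, 4.0])
        with pytest.raises(ValidationError):
            fit_spectral_line(self._ns(f, f), (3.0, 8.5))

    def test_larger_scatterers_give_lower_slope(self, pulse_model, phantoms):
        # paired media differing only in scatterer diameter
        wins = []
        for diam, seed in ((60.0, 31), (140.0, 31)):
            med = make_test_medium(seed=seed, diameter_um=diam)
            roi = extract_test_roi(med, pulse_model, phantoms, seed=32)
            wins.append(np.mean(roi.maps["SS"].masked_values()))
        assert wins[1] < wins[0]


class TestAsdAac:
    def _model_ns(self, a_um, e_db=3.0, band=(3.75, 8.5)):
        f = np.linspace(band[0], band[1], 120)
        k2 = (2 * np.pi * f * 1e6 / 1540.0) ** 2
        db = e_db - GAUSSIAN_FORM_FACTOR_COEF * k2 * (a_um * 1e-6) ** 2 * _DB10
        return NormalizedSpectrum(freq_mhz=f, power_db=db, depth_mm=15.0), (band)

    def test_noise_free_inversion_of_forward_model(self):
        ns, band = self._model_ns(a_um=50.0)
        res = estimate_asd_aac(ns, band, phantom_attenuation=0.5, depth_cm=1.5)
        assert res.asd_um == pytest.approx(100.0, rel=0.01)
        assert res.aac_db == pytest.approx(3.0, abs=0.01)
        assert not res.flagged

    def test_flat_spectrum_hits_lower_bound_flagged(self):
        f = np.linspace(3.75, 8.5, 120)
        ns = NormalizedSpectrum(freq_mhz=f, power_db=np.zeros_like(f), depth_mm=15.0)
        res = estimate_asd_aac(ns, (3.75, 8.5), 0.5, 1.5)
        assert res.flagged
        assert res.asd_um == pytest.approx(10.0)

    def test_concentration_shift_moves_aac_not_asd(self, pulse_model, phantoms):
        med1 = make_test_medium(seed=17, diameter_um=90.0, concentration=1.0)
        med2 = ScattererMedium(
            positions=med1.positions, amplitudes=med1.amplitudes * np.sqrt(10.0),
            extent=med1.extent, true_diameter=90.0, true_concentration=10.0,
            attenuation=med1.attenuation,
        )
        r1 = extract_test_roi(med1, pulse_model, phantoms, seed=18)
        r2 = extract_test_roi(med2, pulse_model, phantoms, seed=18)
        d_aac = (np.mean(r2.maps["AAC"].masked_values())
                 - np.mean(r1.maps["AAC"].masked_values()))
        assert d_aac == pytest.approx(10.0, abs=0.5)
        asd1 = np.median(r1.maps["ASD"].masked_values())
        asd2 = np.median(r2.maps["ASD"].masked_values())
        assert asd2 == pytest.approx(asd1, rel=0.10)


class TestSas:
    def test_constructed_ripple_recovered(self):
        # ripple period 0.77 MHz over a smooth baseline: SAS = c/(2 df) = 1 mm
        f = np.linspace(3.0, 8.5, 283)
        db = -0.5 * f + 0.1 * f**2 + 3.0 * np.cos(2 * np.pi * f / 0.77)
        raw = RawSpectrum(freq_mhz=f, power=10 ** (db / 10), depth_mm=15.0)
        res = estimate_sas(raw, (3.0, 8.5))
        assert not res.absent
        assert res.sas_mm == pytest.approx(1.0, rel=0.02)

    def test_lattice_medium_recovered(self, lattice_roi):
        sas = lattice_roi.maps["SAS"]
        assert np.median(sas.masked_values()) == pytest.approx(1.0, rel=0.10)
        assert not sas.flagged

    def test_random_medium_mostly_absent(self, pulse_model, phantoms):
        from qusrad.spectral_qus import build_window_grid, phantom_depth_spectra

        med = make_test_medium(seed=3, spacing_mode="random")
        fr = simulate_test_frame(med, pulse_model, seed=4)
        mask = rasterize_contour(rect_contour(), fr)
        grid = build_window_grid(mask, fr, TEST_WINDOW)
        freq, ph = phantom_depth_spectra(phantoms, grid)
        band = determine_band(freq, ph.mean(axis=0), (3.0, 8.5))
        absent = []
        for k in range(grid.shape[0]):
            for l in range(grid.shape[1]):
                if grid.include[k, l]:
                    sp = window_power_spectrum(
                        fr, int(grid.axial_i0[k]), int(grid.lateral_j0[l]),
                        grid.win_samples, grid.win_lines,
                    )
                    absent.append(estimate_sas(sp, band).absent)
        assert np.mean(absent) > 0.5

    def test_narrow_band_rejected(self):
        f = np.linspace(3.0, 3.3, 31)
        raw = RawSpectrum(freq_mhz=f, power=np.ones_like(f), depth_mm=15.0)
        with pytest.raises(ValidationError, match="two ripple periods"):
            estimate_sas(raw, (3.0, 3.3))


class TestAce:
    def _spectra(self, dalpha, depths_cm, band=(3.0, 8.5), n=80):
        f = np.linspace(band[0], band[1], n)
        out = []
        for z in depths_cm:
            db = 1.0 - 2.0 * dalpha * z * f
            out.append(NormalizedSpectrum(freq_mhz=f, power_db=db, depth_mm=z * 10))
        return out

    def test_matched_attenuation_returns_phantom_value(self):
        ns = self._spectra(0.0, [1.2, 1.7, 2.2])
        res = estimate_ace(ns, (3.0, 8.5), phantom_attenuation=0.5)
        assert res.ace_db_cm_mhz == pytest.approx(0.5, abs=0.1)

    def test_synthetic_offset_recovered_exactly(self):
        ns = self._spectra(0.5, [1.2, 1.7, 2.2])
        res = estimate_ace(ns, (3.0, 8.5), phantom_attenuation=0.5)
        assert res.ace_db_cm_mhz == pytest.approx(1.0, abs=1e-6)
        assert not res.flagged

    def test_simulated_tissue_attenuation_recovered(self, diffuse_roi):
        # diffuse fixture medium has attenuation 0.7 vs phantom 0.5
        assert diffuse_roi.ace.ace_db_cm_mhz == pytest.approx(0.7, rel=0.2)

    def test_two_depths_flagged(self):
        ns = self._spectra(0.2, [1.2, 1.6])
        res = estimate_ace(ns, (3.0, 8.5), 0.5)
        assert res.flagged

    def test_single_depth_rejected(self):
        ns = self._spectra(0.2, [1.5])
        with pytest.raises(ValidationError):
            estimate_ace(ns, (3.0, 8.5), 0.5)

    def test_shallow_span_flagged(self):
        ns = self._spectra(0.2, [1.50, 1.55, 1.60])
        assert estimate_ace(ns, (3.0, 8.5), 0.5).flagged


class TestParametricMaps:
    def test_map_shapes_match_grid(self, diffuse_roi):
        for m in diffuse_roi.maps.values():
            assert m.values.shape == diffuse_roi.grid.shape
            assert np.all(np.isfinite(m.values[m.mask]))

    def test_mbf_identity_holds_per_window(self, diffuse_roi):
        f_mid = 0.5 * (diffuse_roi.band_mhz[0] + diffuse_roi.band_mhz[1])
        mbf = diffuse_roi.maps["MBF"].values
        ss = diffuse_roi.maps["SS"].values
        si = diffuse_roi.maps["SI"].values
        mask = diffuse_roi.maps["MBF"].mask
        np.testing.assert_allclose(mbf[mask], ss[mask] * f_mid + si[mask],
                                   atol=1e-9)

    def test_homogeneous_medium_gives_homogeneous_maps(self, diffuse_roi):
        # speckle-limited spatial variation: MBF SD bounded in dB, ASD in
        # relative terms
        mbf = diffuse_roi.maps["MBF"].masked_values()
        asd = diffuse_roi.maps["ASD"].masked_values()
        assert np.std(mbf) < 2.0
        assert np.std(asd) / np.mean(asd) < 0.10

    def test_two_region_concentration_contrast_sign(self, pulse_model, phantoms):
        from conftest import EXTENT_AX_MM, EXTENT_LAT_MM
        from qusrad.synthetic_rf import make_medium

        hits = 0
        n_seeds = 5
        for s in range(n_seeds):
            med = make_medium(EXTENT_AX_MM, EXTENT_LAT_MM, diameter_um=80,
                              attenuation=0.7, seed=60 + s)
            # top half at 4x the acoustic concentration
            top = med.positions[:, 0] < EXTENT_AX_MM * 1e-3 / 2
            amps = med.amplitudes.copy()
            amps[top] *= 2.0
            med = ScattererMedium(positions=med.positions, amplitudes=amps,
                                  extent=med.extent, true_diameter=80,
                                  attenuation=0.7)
            roi = extract_test_roi(med, pulse_model, phantoms, seed=70 + s)
            aac = roi.maps["AAC"]
            centers = roi.grid.axial_center_mm
            top_rows = centers < 10.0 + EXTENT_AX_MM / 2
            top_vals = aac.values[top_rows][aac.mask[top_rows]]
            bot_vals = aac.values[~top_rows][aac.mask[~top_rows]]
            hits += np.mean(top_vals) > np.mean(bot_vals)
        assert hits == n_seeds

    def test_sas_fill_flags_when_majority_absent(self, pulse_model, phantoms):
        med = make_test_medium(seed=3, spacing_mode="random")
        roi = extract_test_roi(med, pulse_model, phantoms, seed=4)
        sas = roi.maps["SAS"]
        assert sas.flagged  # diffuse medium: most windows have no spacing
        assert np.all(np.isfinite(sas.values[sas.mask]))  # but map is filled
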