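"""FTIR pipeline: baseline, smoothing, derivative, band areas, assignments."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from corneaionto.ftir import (
    BandDefinition,
    IRSpectrum,
    PipelineOrderError,
    amide_peak_position,
    area_percentages,
    assign_secondary_structure,
    average_group,
    baseline_correct,
    integrate_band,
    load_band_definitions,
    savgol_smooth,
    second_derivative,
    water_combination_check,
)
from corneaionto.synth import (
    FTIR_GRID_CM1,
    GaussianBand,
    analytic_area_fractions,
    analytic_band_area_abs_d2,
    gen_ftir_spectrum,
    load_ftir_presets,
)

GRID = FTIR_GRID_CM1


def spectrum_from(values, stage="raw"):
    return IRSpectrum(GRID.copy(), np.asarray(values, dtype=float), stage=stage)


def processed_group(group, seed, n=10, **kw):
    reps = [gen_ftir_spectrum(group, seed=seed * 1000 + i, **kw) for i in range(n)]
    return second_derivative(
        average_group([savgol_smooth(baseline_correct(sp)) for sp in reps])
    )


class TestBaseline:
    def test_constant_offset_removed(self):
        sp = spectrum_from(np.full(GRID.size, 0.7))
        out = baseline_correct(sp)
        assert np.max(np.abs(out.absorbance)) < 1e-8

    def test_linear_ramp_removed(self):
        ramp = 0.1 + 3e-5 * (GRID - GRID[0])
        out = baseline_correct(spectrum_from(ramp))
        assert np.max(np.abs(out.absorbance)) < 1e-8

    def test_band_areas_survive_curved_baseline(self):
        """Bands on a curved drift: after baseline correction the window
        areas match a baseline-free twin processed identically, to 2 %."""
        with_drift = gen_ftir_spectrum("control", noise_sd=0.0, with_baseline=True)
        no_drift = gen_ftir_spectrum("control", noise_sd=0.0, with_baseline=False)
        d2 = second_derivative(savgol_smooth(baseline_correct(with_drift)))
        d2_ref = second_derivative(savgol_smooth(baseline_correct(no_drift)))
        for name in ("strOH", "amide_I", "CH_stretch"):
            window = next(b for b in load_band_definitions() if b.name == name)
            got = integrate_band(d2, window)
            ref = integrate_band(d2_ref, window)
            assert got == pytest.approx(ref, rel=0.02)

    def test_anchor_outside_range_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(spectrum_from(np.zeros(GRID.size)),
                             anchor_regions=((5000.0, 5100.0),))


class TestSavgol:
    def test_exact_on_quadratic(self):
        quad = 1.0 + 0.002 * (GRID - 2000) + 1e-6 * (GRID - 2000) ** 2
        out = savgol_smooth(spectrum_from(quad, stage="baselined"))
        assert np.max(np.abs(out.absorbance - quad)) < 1e-8

    def test_constant_unchanged(self):
        out = savgol_smooth(spectrum_from(np.full(GRID.size, 2.5), stage="baselined"))
        assert np.max(np.abs(out.absorbance - 2.5)) < 1e-12

    def test_white_noise_attenuation_matches_kernel_norm(self):
        """Smoothed white noise has SD ~ sigma * ||w||_2 of the SG kernel."""
        rng = np.random.default_rng(42)
        sigma = 0.01
        noise = sigma * rng.standard_normal(GRID.size)
        out = savgol_smooth(spectrum_from(noise, stage="baselined"))
        expected = sigma * np.linalg.norm(savgol_coeffs(9, 2))
        assert np.std(out.absorbance[10:-10]) == pytest.approx(expected, rel=0.05)

    def test_window_validation(self):
        sp = spectrum_from(np.zeros(GRID.size), stage="baselined")
        with pytest.raises(ValueError):
            savgol_smooth(sp, window=8)
        with pytest.raises(ValueError):
            savgol_smooth(sp, window=9, order=9)
        short = IRSpectrum(GRID[:5], np.zeros(5), stage="baselined")
        with pytest.raises(ValueError):
            savgol_smooth(short)


class TestAverage:
    def test_identical_spectra_average_to_themselves(self):
        sp = savgol_smooth(baseline_correct(gen_ftir_spectrum("control", seed=1)))
        avg = average_group([sp, sp, sp])
        assert np.allclose(avg.absorbance, sp.absorbance)
        assert avg.n_averaged == 3

    def test_two_spectra_pointwise_mean(self):
        a = spectrum_from(np.ones(GRID.size), stage="smoothed")
        b = spectrum_from(np.full(GRID.size, 3.0), stage="smoothed")
        assert np.allclose(average_group([a, b]).absorbance, 2.0)

    def test_noise_shrinks_as_sqrt_n(self):
        """Residual of a 10-replicate mean has SD ~ sigma/sqrt(10)."""
        rng = np.random.default_rng(0)
        sigma = 0.01
        reps = [spectrum_from(sigma * rng.standard_normal(GRID.size),
                              stage="smoothed") for _ in range(10)]
        avg = average_group(reps)
        assert np.std(avg.absorbance) == pytest.approx(sigma / np.sqrt(10), rel=0.1)

    def test_grid_mismatch_rejected(self):
        a = spectrum_from(np.ones(GRID.size), stage="smoothed")
        b = IRSpectrum(GRID[:-1] + 1.0, np.ones(GRID.size - 1), stage="smoothed")
        with pytest.raises(ValueError, match="grids differ"):
            average_group([a, b])


class TestSecondDerivative:
    def test_gaussian_minimum_at_centre(self):
        band = 0.5 * np.exp(-0.5 * ((GRID - 1666.0) / 13.0) ** 2)
        d2 = second_derivative(spectrum_from(band, stage="smoothed"))
        pos = GRID[np.argmin(d2.absorbance)]
        assert abs(pos - 1666.0) <= 2.0  # within one grid step

    def test_linear_signal_vanishes(self):
        lin = 0.1 + 1e-4 * GRID
        d2 = second_derivative(spectrum_from(lin, stage="smoothed"))
        assert np.max(np.abs(d2.absorbance)) < 1e-10

    def test_overlapping_gaussians_resolved(self):
        """Two bands > 1.5 FWHM apart give two negative minima at the
        generator centres within 2 cm⁻¹."""
        c1, c2, fwhm = 1630.0, 1678.0, 30.0
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        band = (np.exp(-0.5 * ((GRID - c1) / sig) ** 2)
                + np.exp(-0.5 * ((GRID - c2) / sig) ** 2))
        d2 = second_derivative(spectrum_from(band, stage="smoothed")).absorbance
        interior = (d2 < 0) & (np.r_[True, d2[1:] < d2[:-1]] &
                               np.r_[d2[:-1] < d2[1:], True])
        minima = GRID[interior]
        assert any(abs(m - c1) <= 2.0 for m in minima)
        assert any(abs(m - c2) <= 2.0 for m in minima)

    def test_linearity_of_derivative_and_average(self):
        """d2(mean of spectra) == mean of d2(spectra) to 1e-10."""
        sps = [savgol_smooth(baseline_correct(gen_ftir_spectrum("control", seed=i)))
               for i in range(3)]
        d2_of_avg = second_derivative(average_group(sps)).absorbance
        avg_of_d2 = np.mean([second_derivative(s).absorbance for s in sps], axis=0)
        assert np.max(np.abs(d2_of_avg - avg_of_d2)) < 1e-10


class TestIntegration:
    def test_zero_spectrum(self):
        d2 = spectrum_from(np.zeros(GRID.size), stage="second_derivative")
        assert integrate_band(d2, BandDefinition("x", 1000.0, 1100.0)) == 0.0

    def test_unit_rectangle_area(self):
        vals = np.where((GRID >= 1000) & (GRID <= 1100), 1.0, 0.0)
        sp = spectrum_from(vals)
        area = integrate_band(sp, BandDefinition("r", 1000.0, 1100.0),
                              mode="absorbance")
        assert area == pytest.approx(100.0)

    def test_gaussian_analytic_area_absorbance(self):
        A, c, sig = 0.8, 2129.0, 17.0
        sp = spectrum_from(A * np.exp(-0.5 * ((GRID - c) / sig) ** 2))
        area = integrate_band(sp, BandDefinition("g", c - 8 * sig, c + 8 * sig),
                              mode="absorbance")
        assert area == pytest.approx(A * sig * np.sqrt(2 * np.pi), rel=0.01)

    def test_band_outside_range_rejected(self):
        d2 = spectrum_from(np.zeros(GRID.size), stage="second_derivative")
        with pytest.raises(ValueError):
            integrate_band(d2, BandDefinition("x", 100.0, 200.0))

    def test_single_band_is_100_percent_of_itself(self):
        vals = -np.exp(-0.5 * ((GRID - 1666.0) / 10.0) ** 2)
        d2 = spectrum_from(vals, stage="second_derivative")
        band = BandDefinition("only", 1400.0, 1900.0)
        rep = area_percentages(d2, [band], reference="bands", noise_floor=None)
        assert rep.table.area_pct.iloc[0] == pytest.approx(100.0)

    def test_two_equal_bands_split_50_50(self):
        vals = -(np.exp(-0.5 * ((GRID - 1000.0) / 10.0) ** 2)
                 + np.exp(-0.5 * ((GRID - 3000.0) / 10.0) ** 2))
        d2 = spectrum_from(vals, stage="second_derivative")
        bands = [BandDefinition("a", 900.0, 1100.0), BandDefinition("b", 2900.0, 3100.0)]
        rep = area_percentages(d2, bands, reference="bands", noise_floor=None)
        assert rep.table.area_pct.to_numpy() == pytest.approx([50.0, 50.0], abs=1e-6)

    def test_degenerate_reference_rejected(self):
        d2 = spectrum_from(np.zeros(GRID.size), stage="second_derivative")
        with pytest.raises(ValueError, match="degenerate"):
            area_percentages(d2, [BandDefinition("x", 1000.0, 1100.0)])


class TestFullChainRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_generator_parameters_recovered(self, seed):
        """Across 20 seeded replicate sets: window area fractions within
        2 % absolute of the generator model and amide-I centre within
        2 cm⁻¹."""
        presets = load_ftir_presets()
        windows = load_band_definitions()
        truth = analytic_area_fractions(presets["control"], windows)
        d2 = processed_group("control", seed)
        rep = area_percentages(d2, windows).table.set_index("band").area_pct
        for name, expected in truth.items():
            assert abs(rep[name] - expected) < 2.0, name
        assert abs(amide_peak_position(d2) - 1666.0) <= 2.0

    def test_control_hydroxyl_fractions_anchor(self):
        """Control OH decomposition lands at the reference percentages
        (strOH 31.1, asyOH 4.7, syOH 2.2, total 38.1) within 2 % absolute."""
        d2 = processed_group("control", seed=5)
        rep = area_percentages(d2, load_band_definitions()).table.set_index("band")
        assert rep.area_pct["strOH"] == pytest.approx(31.1, abs=2.0)
        assert rep.area_pct["asyOH"] == pytest.approx(4.7, abs=2.0)
        assert rep.area_pct["syOH"] == pytest.approx(2.2, abs=2.0)
        assert rep.area_pct["OH_total"] == pytest.approx(38.1, abs=2.5)

    @pytest.mark.parametrize(
        "group,expected",
        [("control", 1666.0), ("low_current", 1666.0), ("mid_current", 1674.0),
         ("high_current", 1659.0), ("extreme", 1674.0)],
    )
    def test_amide_presets(self, group, expected):
        d2 = processed_group(group, seed=11)
        assert abs(amide_peak_position(d2) - expected) <= 2.0

    def test_low_current_exclusive_bands(self):
        """Strained carbonyls and the thiol band appear only in the
        low-current preset."""
        windows = {b.name: b for b in load_band_definitions()}
        d2_low = processed_group("low_current", seed=3)
        d2_ctrl = processed_group("control", seed=3)
        for name in ("carbonyl_1821", "carbonyl_1929", "thiol"):
            assert integrate_band(d2_low, windows[name]) > 0
            assert integrate_band(d2_ctrl, windows[name]) == pytest.approx(0.0, abs=1e-6)


class TestAssignments:
    @pytest.mark.parametrize(
        "pos,label",
        [(1666.0, "beta-turn"), (1674.0, "beta-turn"), (1659.0, "alpha-helix"),
         (1650.0, "alpha-helix"), (1649.0, "beta-sheet/random-coil"),
         (1660.0, "beta-turn")],
    )
    def test_structure_map(self, pos, label):
        assert assign_secondary_structure(pos) == label

    def test_out_of_region_rejected(self):
        with pytest.raises(ValueError):
            assign_secondary_structure(1500.0)

    def test_flat_region_has_no_peak(self):
        d2 = spectrum_from(np.zeros(GRID.size), stage="second_derivative")
        with pytest.raises(ValueError, match="degenerate"):
            amide_peak_position(d2)

    def test_water_combination_sum(self):
        """The combination position is the plain sum of the fundamentals;
        1640 + 3400 = 5040 cm⁻¹ (which notably differs from the observed
        2129 cm⁻¹ association band — the formula is applied as stated)."""
        assert water_combination_check(1640.0, 3400.0) == 5040.0
        assert water_combination_check(0.0, 777.0) == 777.0
        assert water_combination_check(1.0, 2.0) == water_combination_check(2.0, 1.0)


class TestPipelineOrder:
    def test_out_of_order_calls_fail(self):
        raw = gen_ftir_spectrum("control", seed=0)
        with pytest.raises(PipelineOrderError):
            savgol_smooth(raw)                      # smooth before baseline
        with pytest.raises(PipelineOrderError):
            second_derivative(baseline_correct(raw))  # derivative before smooth
        with pytest.raises(PipelineOrderError):
            baseline_correct(baseline_correct(raw))   # baseline twice
        with pytest.raises(PipelineOrderError):
            average_group([raw])                      # average raw spectra
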