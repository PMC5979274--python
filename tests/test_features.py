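import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftirpheno.features import (baseline_value, compute_ratios, corrected_area,
                                corrected_height, extract_features, extract_row,
                                locate_peak, split_area)
from ftirpheno.preprocess import PreprocessConfig, second_derivative
from ftirpheno.scheme import (APEX, SECOND_DERIVATIVE, PeakDef, RegionDef, SplitDef,
                              default_alfalfa_scheme)
from ftirpheno.spectra import Spectrum, SpectrumSet

from .conftest import gaussian_spectrum

TC = RegionDef("TC", 1178.0, 941.0)
AMIDE = RegionDef("amide", 1710.0, 1484.0, area_name="AA")


def _random_spectrum(seed, lo=700.0, hi=4000.0, spacing=2.0):
    rng = np.random.default_rng(seed)
    w = np.arange(lo, hi + spacing / 2, spacing)
    centers = rng.uniform(950, 3000, size=6)
    amps = rng.uniform(0.05, 0.6, size=6)
    sig = rng.uniform(8, 40, size=6)
    a = np.zeros_like(w)
    for c, A, s in zip(centers, amps, sig):
        a += A * np.exp(-((w - c) ** 2) / (2 * s ** 2))
    return Spectrum(w, a + 0.01)


class TestBaseline:
    def test_flat_endpoints_flat_baseline(self):
        w = np.arange(941.0, 1179.0, 2.0)
        s = Spectrum(w, np.full_like(w, 0.2))
        for at in (941.0, 1026.0, 1104.0, 1178.0):
            assert baseline_value(s, TC, at) == pytest.approx(0.2)

    def test_linear_interpolation_at_midpoint(self):
        region = RegionDef("CHO", 1484.0, 941.0)
        w = np.arange(941.0, 1485.0, 1.0)
        a = 0.543 * (1484.0 - w) / (1484.0 - 941.0)
        s = Spectrum(w, a)
        assert baseline_value(s, region, (941.0 + 1484.0) / 2) == pytest.approx(0.2715)

    def test_baseline_meets_spectrum_at_endpoints(self):
        s = _random_spectrum(3)
        w = s.wavenumbers
        i_lo = np.argmin(np.abs(w - TC.low))
        i_hi = np.argmin(np.abs(w - TC.high))
        assert baseline_value(s, TC, w[i_lo]) == pytest.approx(s.absorbance[i_lo])
        assert baseline_value(s, TC, w[i_hi]) == pytest.approx(s.absorbance[i_hi])

    def test_outside_region_rejected(self):
        s = _random_spectrum(4)
        with pytest.raises(ValueError, match="outside region"):
            baseline_value(s, TC, 1500.0)


class TestCorrectedHeight:
    def test_spectrum_equal_to_baseline_gives_zero(self):
        w = np.arange(941.0, 1179.0, 2.0)
        s = Spectrum(w, 0.1 + 1e-4 * w)
        assert corrected_height(s, TC, 1074.0) == pytest.approx(0.0, abs=1e-12)

    def test_recovers_band_amplitude(self):
        s = gaussian_spectrum(1074, 0.3, 12)
        assert corrected_height(s, TC, 1074.0) == pytest.approx(0.3, abs=1e-6)

    def test_invariant_to_added_line(self):
        s = gaussian_spectrum(1074, 0.3, 12)
        tilted = s.with_values(s.absorbance + 0.001 * s.wavenumbers + 0.05)
        assert corrected_height(tilted, TC, 1074.0) == pytest.approx(
            corrected_height(s, TC, 1074.0), abs=1e-9)

    def test_negative_height_warned_not_clipped(self):
        s = gaussian_spectrum(1074, -0.0, 12)
        dip = s.with_values(s.absorbance - 0.05 * np.exp(
            -((s.wavenumbers - 1074.0) ** 2) / (2 * 144.0)))
        with pytest.warns(UserWarning, match="negative corrected height"):
            h = corrected_height(dip, TC, 1074.0)
        assert h == pytest.approx(-0.05, abs=1e-6)


class TestCorrectedArea:
    def test_triangle_area(self):
        w = np.arange(940.0, 1180.0, 10.0)
        a = np.zeros_like(w)
        a[w == 1010.0] = 1.0
        region = RegionDef("t", 1170.0, 940.0)
        assert corrected_area(Spectrum(w, a), region) == pytest.approx(10.0)

    def test_gaussian_closed_form(self):
        A, sigma = 0.5, 10.0
        s = gaussian_spectrum(1060, A, sigma, spacing=2.0)
        area = corrected_area(s, TC)
        assert area == pytest.approx(A * sigma * np.sqrt(2 * np.pi), rel=1e-3)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**16), slope=st.floats(-2e-3, 2e-3),
           intercept=st.floats(-0.2, 0.2))
    def test_invariant_to_added_line(self, seed, slope, intercept):
        s = _random_spectrum(seed)
        tilted = s.with_values(s.absorbance + slope * s.wavenumbers + intercept)
        assert corrected_area(tilted, TC) == pytest.approx(corrected_area(s, TC),
                                                           abs=1e-9)

    def test_matches_fine_grid_riemann_sum(self):
        s = gaussian_spectrum(1100, 0.4, 15, spacing=2.0)
        w = s.wavenumbers
        lo = w[np.argmin(np.abs(w - TC.low))]
        hi = w[np.argmin(np.abs(w - TC.high))]
        fine = np.arange(lo, hi + 0.01, 0.2)  # 10x finer
        vals = np.interp(fine, w, s.absorbance)
        base = np.interp([lo, hi], w, s.absorbance)
        line = base[0] + (base[1] - base[0]) * (fine - lo) / (hi - lo)
        riemann = np.sum((vals - line)[:-1] + (vals - line)[1:]) / 2 * 0.2
        assert corrected_area(s, TC) == pytest.approx(riemann, rel=5e-3)

    def test_scaling_amplitudes_scales_features_exactly(self):
        s = gaussian_spectrum([1026, 1104], [0.3, 0.2], [10, 12])
        k = 3.7
        scaled = s.with_values(k * s.absorbance)
        assert corrected_area(scaled, TC) == pytest.approx(k * corrected_area(s, TC),
                                                           rel=1e-12)
        assert corrected_height(scaled, TC, 1026.0) == pytest.approx(
            k * corrected_height(s, TC, 1026.0), rel=1e-12)


class TestSplitArea:
    SPLIT = SplitDef("amide_split", "amide", 1575.0, ("AIA", "AIIA"))

    def test_symmetric_band_splits_evenly(self):
        w = np.arange(1484.0, 1711.0, 2.0)  # 1575 falls between nodes 1574/1576
        split = SplitDef("s", "amide", 1574.0, ("hi", "lo"))
        a = 0.4 * np.exp(-((w - 1574.0) ** 2) / (2 * 15 ** 2))
        hi, lo = split_area(Spectrum(w, a), split, AMIDE)
        # asymmetry only from the far tails touching the baseline endpoints
        assert hi == pytest.approx(lo, abs=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**16))
    def test_parts_sum_to_whole(self, seed):
        s = _random_spectrum(seed)
        hi, lo = split_area(s, self.SPLIT, AMIDE)
        assert hi + lo == pytest.approx(corrected_area(s, AMIDE), abs=1e-12)

    def test_band_entirely_on_high_side(self):
        s = gaussian_spectrum(1660, 0.5, 7)
        hi, lo = split_area(s, self.SPLIT, AMIDE)
        assert hi == pytest.approx(0.5 * 7 * np.sqrt(2 * np.pi), rel=1e-2)
        assert abs(lo) < 1e-6  # only the band's far tail leaks below the cut


class TestLocatePeak:
    def test_apex_of_isolated_band(self):
        s = gaussian_spectrum(1026, 0.5, 10)
        p = PeakDef("TC1", 1026.0, "TC", mode=APEX)
        assert locate_peak(s, None, p) == pytest.approx(1026.0, abs=2.0)

    def test_second_derivative_resolves_merged_bands(self):
        # visually merged pair: one envelope, two derivative minima
        s = gaussian_spectrum([1074, 1104], [0.5, 0.45], [15, 15])
        d2 = second_derivative(s)
        for nominal in (1074.0, 1104.0):
            p = PeakDef("x", nominal, "TC", mode=SECOND_DERIVATIVE)
            assert abs(locate_peak(s, d2, p) - nominal) <= 4.0

    def test_flat_spectrum_falls_back_to_nominal(self):
        w = np.arange(941.0, 1179.0, 2.0)
        s = Spectrum(w, np.full_like(w, 0.3))
        p = PeakDef("TC1", 1026.0, "TC", mode=APEX)
        assert locate_peak(s, None, p) == 1026.0

    def test_window_outside_grid_rejected(self):
        s = gaussian_spectrum(1026, 0.5, 10, lo=1020, hi=1200)
        with pytest.raises(ValueError, match="outside grid"):
            locate_peak(s, None, PeakDef("TC1", 1026.0, "TC", mode=APEX))


class TestRatios:
    def test_half_area_ratio(self, scheme):
        row = {"AIA": 5.0, "AA": 10.0, "AIIA": 5.0, "AmideI": 1.0, "AmideII": 1.0,
               "AlphaHelix": 1.0, "BetaSheet": 1.0}
        out = compute_ratios(row, scheme)
        assert out["AIA/AA"] == pytest.approx(0.5)

    def test_zero_denominator_becomes_nan(self, scheme):
        row = {"AIA": 5.0, "AA": 0.0, "AIIA": 5.0, "AmideI": 1.0, "AmideII": 1.0,
               "AlphaHelix": 1.0, "BetaSheet": 1.0}
        with pytest.warns(UserWarning, match="denominator"):
            out = compute_ratios(row, scheme)
        assert np.isnan(out["AIA/AA"])


class TestExtractFeatures:
    def test_feature_count_per_row(self, feature_table, scheme):
        assert list(feature_table.columns[3:]) == scheme.feature_names()
        assert feature_table.shape[1] == 3 + 30
        assert feature_table.iloc[:, 3:].notna().all().all()

    def test_duplicate_spectra_give_identical_rows(self, scheme):
        s1 = gaussian_spectrum([1026, 1540, 1649, 2850], [0.5, 0.2, 0.3, 0.1],
                               [10, 12, 12, 10], genotype="WT", sample_id="W1",
                               subsample_id="1")
        s2 = Spectrum(s1.wavenumbers, s1.absorbance, "WT", "W1", "2")
        ft = extract_features(SpectrumSet([s1, s2]), scheme)
        np.testing.assert_array_equal(ft.iloc[0, 3:].to_numpy(dtype=float),
                                      ft.iloc[1, 3:].to_numpy(dtype=float))

    def test_zero_noise_heights_recover_amplitudes(self, scheme):
        # isolated bands, no normalization: corrected height ~ amplitude
        amps = {"CEC": 0.08, "CCO": 0.15, "AsCH3": 0.12}
        s = gaussian_spectrum([1237, 1733, 2955], [0.08, 0.15, 0.12], [10, 8, 10],
                              genotype="WT", sample_id="W1", subsample_id="1")
        row = extract_row(s, scheme, PreprocessConfig(normalize="none"))
        for name in ("CEC", "CCO", "AsCH3"):
            assert row[name] == pytest.approx(amps[name], rel=0.02)

    def test_bad_spectrum_skipped_with_identity(self, scheme):
        good = gaussian_spectrum([1026, 1649], [0.5, 0.3], [10, 12],
                                 genotype="WT", sample_id="W1", subsample_id="1")
        flat = Spectrum(good.wavenumbers, np.full_like(good.wavenumbers, 0.2),
                        "WT", "W1", "2")
        with pytest.warns(UserWarning, match="W1"):
            ft = extract_features(SpectrumSet([good, flat]), scheme)
        assert len(ft) == 1

    def test_planted_stc3_fold_change_recovered(self, feature_table):
        g = feature_table.groupby("genotype")["STC3"].mean()
        assert 1.3 < g["HB12i"] / g["WT"] < 1.5
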