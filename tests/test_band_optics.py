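import numpy as np
import pytest

from snowbloom.band_optics import (
    BandDefinition,
    CONTINUUM_FACTOR,
    SENTINEL2A_BANDS,
    band_depth_ib4,
    band_equivalent_reflectance,
    band_reflectances,
    continuum_reflectance_b4,
    ib4_from_spectrum,
    mean_reflectance,
    percent_reduction,
)
from snowbloom.spectra_io import Spectrum, SpectrumRangeError


def test_continuum_factor_value():
    assert CONTINUUM_FACTOR == pytest.approx(104.0 / 144.0)


def test_mean_reflectance_of_constant(flat_spectrum):
    s = flat_spectrum(0.37)
    assert mean_reflectance(s, 400.0, 700.0) == pytest.approx(0.37)


def test_mean_reflectance_of_linear_ramp_is_midpoint(grid):
    s = Spectrum(grid, grid / 1000.0)
    assert mean_reflectance(s, 550.0, 650.0) == pytest.approx(0.600, abs=1e-12)
    assert mean_reflectance(s, 700.0, 1300.0) == pytest.approx(1.000, abs=1e-12)


def test_mean_reflectance_handles_non_grid_endpoints(grid):
    s = Spectrum(grid, grid / 1000.0)
    assert mean_reflectance(s, 550.5, 650.5) == pytest.approx(0.6005, abs=1e-12)


def test_mean_reflectance_outside_support_raises(grid):
    s = Spectrum(grid, np.full(grid.size, 0.2))
    with pytest.raises(SpectrumRangeError):
        mean_reflectance(s, 350.0, 500.0)


def test_continuum_hand_value():
    # rcont = rb3 + 104/144 * (rb5 - rb3)
    rcont = continuum_reflectance_b4(0.30, 0.20)
    assert rcont == pytest.approx(0.30 + (104.0 / 144.0) * (0.20 - 0.30))
    assert rcont == pytest.approx(0.2277778, abs=1e-6)


def test_band_depth_hand_value():
    rcont = 0.30 + (104.0 / 144.0) * (0.20 - 0.30)
    expected = (rcont - 0.1873) / rcont
    assert band_depth_ib4(0.30, 0.1873, 0.20) == pytest.approx(expected)


def test_band_depth_zero_for_flat_spectrum(flat_spectrum):
    assert ib4_from_spectrum(flat_spectrum(0.25)) == pytest.approx(0.0, abs=1e-12)


def test_band_depth_bounded_above_by_one():
    assert band_depth_ib4(0.3, 0.0, 0.2) == pytest.approx(1.0)
    assert band_depth_ib4(0.3, 0.05, 0.2) < 1.0


def test_band_depth_requires_positive_continuum():
    with pytest.raises(ValueError):
        band_depth_ib4(0.0, 0.1, 0.0)


def test_boxcar_band_equals_window_mean(grid):
    rng = np.random.default_rng(2)
    s = Spectrum(grid, rng.uniform(0.05, 0.4, grid.size))
    b4 = SENTINEL2A_BANDS[1]
    lo, hi = b4.support
    assert band_equivalent_reflectance(s, b4) == pytest.approx(
        mean_reflectance(s, lo, hi), rel=1e-12
    )


def test_gaussian_band_on_linear_spectrum_hits_center(grid):
    s = Spectrum(grid, grid / 1000.0)
    band = BandDefinition("G", 665.0, 20.0, srf_shape="gaussian")
    # symmetric SRF on a linear spectrum averages to the center value
    assert band_equivalent_reflectance(s, band) == pytest.approx(0.665, abs=1e-6)


def test_tabulated_band_matches_boxcar_table(grid):
    rng = np.random.default_rng(3)
    s = Spectrum(grid, rng.uniform(0.05, 0.4, grid.size))
    table = tuple((float(w), 1.0) for w in np.arange(649.5, 680.6, 0.5))
    band = BandDefinition("T", 665.0, 31.0, srf_shape="tabulated", srf_table=table)
    boxcar = band_equivalent_reflectance(s, SENTINEL2A_BANDS[1])
    assert band_equivalent_reflectance(s, band) == pytest.approx(boxcar, rel=1e-3)


def test_band_reflectances_keys(grid):
    s = Spectrum(grid, np.full(grid.size, 0.2))
    rb = band_reflectances(s)
    assert set(rb) == {"B3", "B4", "B5"}


def test_ib4_positive_for_chlorophyll_dip(grid):
    dip = 0.25 * (1.0 - 0.3 * np.exp(-0.5 * ((grid - 678.0) / 14.0) ** 2))
    assert ib4_from_spectrum(Spectrum(grid, dip)) > 0.0


def test_ib4_needs_three_bands(flat_spectrum):
    with pytest.raises(ValueError):
        ib4_from_spectrum(flat_spectrum(0.2), bands=SENTINEL2A_BANDS[:2])


def test_percent_reduction_printed_examples():
    assert percent_reduction(0.25, 0.11) == pytest.approx(56.0)
    assert percent_reduction(0.25, 0.15) == pytest.approx(40.0)
    assert percent_reduction(0.25, 0.19) == pytest.approx(24.0)
    with pytest.raises(ValueError):
        percent_reduction(0.0, 0.1)


def test_band_definition_validation():
    with pytest.raises(ValueError):
        BandDefinition("X", 500.0, -1.0)
    with pytest.raises(ValueError):
        BandDefinition("X", 500.0, 10.0, srf_shape="triangle")
    with pytest.raises(ValueError):
        BandDefinition("X", 500.0, 10.0, srf_shape="tabulated")
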