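import numpy as np
import pandas as pd
import pytest

from snowbloom.spectra_io import (
    Spectrum,
    SpectrumParseError,
    SpectrumRangeError,
    analysis_grid,
    read_biology_table,
    read_irradiance,
    read_manifest,
    read_spectrum,
    resample_to_grid,
    write_irradiance,
    write_spectrum,
)
from snowbloom.synthetic_data import synthetic_solar_irradiance


def test_analysis_grid_is_1nm_400_to_1300():
    g = analysis_grid()
    assert g.size == 901
    assert g[0] == 400.0 and g[-1] == 1300.0
    assert np.all(np.diff(g) == 1.0)


def test_spectrum_validation_rejects_bad_inputs():
    with pytest.raises(SpectrumParseError):
        Spectrum(np.array([500.0, 400.0]), np.array([0.1, 0.2]))  # decreasing
    with pytest.raises(SpectrumParseError):
        Spectrum(np.array([400.0, 500.0]), np.array([0.1, -0.2]))  # negative
    with pytest.raises(SpectrumParseError):
        Spectrum(np.array([400.0, 500.0]), np.array([0.1, np.nan]))  # non-finite
    with pytest.raises(ValueError):
        Spectrum(np.array([400.0, 500.0]), np.array([0.1, 0.2]), color_group="blue")


def test_write_read_round_trip(tmp_path, grid):
    rng = np.random.default_rng(0)
    s = Spectrum(grid, rng.uniform(0.05, 0.4, grid.size), sample_id="a")
    path = tmp_path / "s.csv"
    write_spectrum(s, path)
    back = read_spectrum(path, sample_id="a")
    np.testing.assert_array_equal(back.wavelengths_nm, s.wavelengths_nm)
    np.testing.assert_allclose(back.hdrf, s.hdrf, rtol=0, atol=1e-12)


def test_read_spectrum_collapses_duplicate_wavelengths_by_mean(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("wavelength_nm,value\n500,0.2\n500,0.4\n600,0.3\n")
    s = read_spectrum(path)
    np.testing.assert_array_equal(s.wavelengths_nm, [500.0, 600.0])
    assert s.hdrf[0] == pytest.approx(0.30)


def test_read_spectrum_reports_row_of_bad_value(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("wavelength_nm,value\n500,0.2\n501,oops\n")
    with pytest.raises(SpectrumParseError, match="row 2"):
        read_spectrum(path)


def test_read_spectrum_negative_handling(tmp_path, caplog):
    path = tmp_path / "neg.csv"
    path.write_text("500,0.2\n501,-0.01\n")
    with caplog.at_level("WARNING", logger="snowbloom"):
        s = read_spectrum(path)
    assert s.hdrf.min() == 0.0
    assert any("clipped" in r.message for r in caplog.records)
    with pytest.raises(SpectrumParseError):
        read_spectrum(path, negative="error")


def test_read_spectrum_drops_out_of_instrument_range_rows(tmp_path):
    path = tmp_path / "range.csv"
    path.write_text("100,0.9\n500,0.2\n600,0.3\n3000,0.9\n")
    s = read_spectrum(path)
    np.testing.assert_array_equal(s.wavelengths_nm, [500.0, 600.0])


def test_resample_linear_ramp_is_exact():
    w = np.array([350.0, 800.0, 1400.0])
    s = Spectrum(w, w / 1000.0)
    r = resample_to_grid(s)
    np.testing.assert_allclose(r.hdrf, r.wavelengths_nm / 1000.0, atol=1e-12)


def test_resample_is_idempotent(grid):
    rng = np.random.default_rng(1)
    s = Spectrum(grid, rng.uniform(0.05, 0.4, grid.size))
    once = resample_to_grid(s)
    twice = resample_to_grid(once)
    np.testing.assert_array_equal(once.hdrf, twice.hdrf)


def test_resample_refuses_extrapolation():
    s = Spectrum(np.array([450.0, 1300.0]), np.array([0.2, 0.1]))
    with pytest.raises(SpectrumRangeError):
        resample_to_grid(s)  # default grid starts at 400 < 450


def test_irradiance_round_trip(tmp_path):
    ed = synthetic_solar_irradiance()
    path = tmp_path / "ed.csv"
    write_irradiance(ed, path)
    back = read_irradiance(path)
    np.testing.assert_allclose(back.ed, ed.ed, rtol=1e-12)


def test_biology_table_grouping_and_missing_pigments(tmp_path):
    path = tmp_path / "bio.csv"
    pd.DataFrame([
        {"sample_id": "g1", "color_group": "green", "cell_shape": "prolate_spheroid",
         "dim_major_um": 21.1, "dim_minor_um": 14.7, "density_cells_ml": 97815,
         "astax_ug_ml": 0.92, "chla_ug_ml": 0.59, "chlb_ug_ml": 0.81,
         "bcar_ug_ml": 0.05},
        {"sample_id": "g1", "color_group": "green", "cell_shape": "sphere",
         "dim_major_um": 8.3, "dim_minor_um": None, "density_cells_ml": 2185,
         "astax_ug_ml": None, "chla_ug_ml": None, "chlb_ug_ml": None,
         "bcar_ug_ml": None},
        {"sample_id": "r1", "color_group": "red", "cell_shape": "sphere",
         "dim_major_um": 35.96, "dim_minor_um": None, "density_cells_ml": 3175,
         "astax_ug_ml": None, "chla_ug_ml": None, "chlb_ug_ml": None,
         "bcar_ug_ml": None},
    ]).to_csv(path, index=False)
    records = {b.sample_id: b for b in read_biology_table(path)}
    g1 = records["g1"]
    assert len(g1.cell_populations) == 2
    assert g1.pigments.astax == pytest.approx(0.92)
    assert not g1.pigments.missing
    assert records["r1"].pigments.missing


def test_biology_table_rejects_negative_density(tmp_path):
    path = tmp_path / "bio.csv"
    pd.DataFrame([{"sample_id": "r1", "color_group": "red", "cell_shape": "sphere",
                   "dim_major_um": 30.0, "density_cells_ml": -5}]).to_csv(
        path, index=False)
    with pytest.raises(ValueError, match="negative cell density"):
        read_biology_table(path)


def test_manifest_validation(tmp_path):
    path = tmp_path / "mf.csv"
    pd.DataFrame([{"file": "a.csv", "sample_id": "a", "color_group": "purple",
                   "replicate": 1}]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="color_group"):
        read_manifest(path)
    pd.DataFrame([{"file": "a.csv", "sample_id": "a"}]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing manifest columns"):
        read_manifest(path)
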