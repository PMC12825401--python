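import filecmp

import numpy as np
import pytest

from snowbloom.band_optics import ib4_from_spectrum, mean_reflectance
from snowbloom.spectra_io import NIR_WINDOW, PAR_WINDOW, PigmentProfile
from snowbloom.synthetic_data import (
    BloomArchetype,
    CLEAN_ARCHETYPE,
    DEFAULT_ARCHETYPES,
    GREEN_ARCHETYPE,
    ORANGE_ARCHETYPE,
    RED_ARCHETYPE,
    calibrate_archetype_optics,
    clean_baseline,
    draw_sample_biology,
    generate_dataset,
    synth_bloom_spectrum,
    synth_clean_spectrum,
    synth_sample_set,
    synthetic_solar_irradiance,
)

PRINTED_MEANS = {  # color: (PAR mean, NIR mean)
    "red": (0.11, 0.12),
    "orange": (0.15, 0.19),
    "green": (0.19, 0.16),
}


def noise_free_clean():
    return synth_clean_spectrum(0, amplitude_cv=0.0, noise_sd=0.0, shape_sd=0.0)


def test_clean_baseline_hits_window_targets():
    clean = noise_free_clean()
    assert mean_reflectance(clean, *PAR_WINDOW) == pytest.approx(0.25, abs=1e-6)
    assert mean_reflectance(clean, *NIR_WINDOW) == pytest.approx(0.16, abs=1e-6)


def test_clean_baseline_smooth_and_positive(grid):
    _, base = clean_baseline(grid)
    assert np.all(base > 0)
    assert np.max(np.abs(np.diff(base))) < 0.005  # no jumps at 1-nm resolution


def test_archetype_mean_spectra_land_on_calibration_targets():
    clean = noise_free_clean()
    for arch in DEFAULT_ARCHETYPES:
        bloom = synth_bloom_spectrum(clean, arch.pigment_means, arch, 0,
                                     noise_sd=0.0)
        par, nir = PRINTED_MEANS[arch.name]
        assert mean_reflectance(bloom, *PAR_WINDOW) == pytest.approx(par, abs=1e-3)
        assert mean_reflectance(bloom, *NIR_WINDOW) == pytest.approx(nir, abs=1e-3)


def test_archetype_band_depth_ordering_orange_green_red():
    clean = noise_free_clean()
    ib4 = {
        a.name: ib4_from_spectrum(
            synth_bloom_spectrum(clean, a.pigment_means, a, 0, noise_sd=0.0))
        for a in DEFAULT_ARCHETYPES
    }
    assert ib4["orange"] > ib4["green"] > ib4["red"] > 0


def test_zero_pigments_is_identity():
    arch = BloomArchetype(name="green", pigment_means=PigmentProfile(),
                          population_specs=RED_ARCHETYPE.population_specs)
    clean = noise_free_clean()
    bloom = synth_bloom_spectrum(clean, PigmentProfile(), arch, 0, noise_sd=0.0)
    np.testing.assert_allclose(bloom.hdrf, clean.hdrf, rtol=0, atol=1e-15)


def test_doubling_chla_deepens_band_depth():
    clean = noise_free_clean()
    arch = GREEN_ARCHETYPE
    lo = synth_bloom_spectrum(clean, PigmentProfile(chla=0.5), arch, 0, noise_sd=0.0)
    hi = synth_bloom_spectrum(clean, PigmentProfile(chla=1.0), arch, 0, noise_sd=0.0)
    assert ib4_from_spectrum(hi) > ib4_from_spectrum(lo)


def test_astaxanthin_lowers_par_more_than_nir():
    clean = noise_free_clean()
    arch = BloomArchetype(name="red", pigment_means=PigmentProfile(astax=1.0),
                          population_specs=RED_ARCHETYPE.population_specs,
                          packaging_scale=2.0)
    bloom = synth_bloom_spectrum(clean, PigmentProfile(astax=1.0), arch, 0,
                                 noise_sd=0.0)
    par_drop = 1.0 - (mean_reflectance(bloom, *PAR_WINDOW)
                      / mean_reflectance(clean, *PAR_WINDOW))
    nir_drop = 1.0 - (mean_reflectance(bloom, *NIR_WINDOW)
                      / mean_reflectance(clean, *NIR_WINDOW))
    assert par_drop > nir_drop >= 0.0


def test_bloom_reflectance_bounded_by_clean():
    clean = noise_free_clean()
    par = clean.wavelengths_nm <= 700.0
    for arch in DEFAULT_ARCHETYPES:
        bloom = synth_bloom_spectrum(clean, arch.pigment_means, arch, 0,
                                     noise_sd=0.0)
        # pigment + gray absorption only darkens in the visible; the NIR
        # snow-physics offset may brighten (orange NIR exceeds clean snow)
        assert np.all(bloom.hdrf[par] <= clean.hdrf[par] + 1e-12)
        assert np.all(bloom.hdrf > 0)


def test_archetype_validation():
    with pytest.raises(ValueError):
        BloomArchetype(name="violet", pigment_means=PigmentProfile())
    with pytest.raises(ValueError):
        BloomArchetype(name="clean", pigment_means=PigmentProfile(astax=1.0))
    with pytest.raises(ValueError):
        BloomArchetype(name="red", pigment_means=PigmentProfile(),
                       chl_masking=1.5)


def test_sample_biology_draws_center_on_archetype_means():
    rng = np.random.default_rng(7)
    n = 400
    chla = [draw_sample_biology(RED_ARCHETYPE, rng, f"r{i}").pigments.chla
            for i in range(n)]
    se = RED_ARCHETYPE.pigment_means.chla * 0.17 / np.sqrt(n)  # combined cv
    assert np.mean(chla) == pytest.approx(RED_ARCHETYPE.pigment_means.chla,
                                          abs=4 * se)


def test_generated_pigment_group_means_within_3_se_over_50_seeds():
    per_seed = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        vals = [draw_sample_biology(GREEN_ARCHETYPE, rng, f"g{i}").pigments.astax
                for i in range(7)]
        per_seed.append(np.mean(vals))
    per_seed = np.asarray(per_seed)
    se = per_seed.std(ddof=1) / np.sqrt(per_seed.size)
    assert abs(per_seed.mean() - GREEN_ARCHETYPE.pigment_means.astax) < 3 * se


def test_generate_dataset_counts_and_determinism():
    spectra, biology, taxa = generate_dataset(n_per_group=7, n_clean=6, seed=11)
    assert len(spectra) == 27
    assert len(biology) == 21
    assert set(taxa.sample_id.str[:3].unique()) <= {"red", "ora", "gre"}
    again, bio2, taxa2 = generate_dataset(n_per_group=7, n_clean=6, seed=11)
    for a, b in zip(spectra, again):
        np.testing.assert_array_equal(a.hdrf, b.hdrf)
    assert taxa.equals(taxa2)


def test_generate_dataset_seed_changes_output():
    s1, _, _ = generate_dataset(n_per_group=1, n_clean=1, seed=0)
    s2, _, _ = generate_dataset(n_per_group=1, n_clean=1, seed=1)
    assert not np.array_equal(s1[0].hdrf, s2[0].hdrf)


def test_synth_sample_set_writes_byte_identical_fixture_sets(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    synth_sample_set(a, DEFAULT_ARCHETYPES, n_per_group=2, n_clean=2, seed=3)
    synth_sample_set(b, DEFAULT_ARCHETYPES, n_per_group=2, n_clean=2, seed=3)
    spectra = sorted(p.name for p in (a / "spectra").glob("*.csv"))
    assert len(spectra) == 8  # 3 colors x 2 + 2 clean
    for name in ["manifest.csv", "biology.csv", "taxa.csv", "irradiance.csv"]:
        assert filecmp.cmp(a / name, b / name, shallow=False)
    for name in spectra:
        assert filecmp.cmp(a / "spectra" / name, b / "spectra" / name,
                           shallow=False)


def test_solar_irradiance_magnitude_and_shape(grid):
    ed = synthetic_solar_irradiance()
    assert ed.value_at(500.0) == pytest.approx(1.35)
    assert np.all(ed.ed > 0)
    assert ed.value_at(1300.0) < ed.value_at(500.0)


def test_calibration_reproduces_frozen_green_constants():
    scale, masking, tau, gray = calibrate_archetype_optics(
        GREEN_ARCHETYPE.pigment_means,
        par_ratio=0.19 / 0.25,
        nir_ratio=0.16 / 0.16,
        ib4_target=0.1926,
    )
    assert scale == pytest.approx(GREEN_ARCHETYPE.packaging_scale, abs=1e-3)
    assert masking == pytest.approx(GREEN_ARCHETYPE.chl_masking, abs=1e-3)
    assert tau == pytest.approx(GREEN_ARCHETYPE.nir_tau, abs=1e-3)
    assert gray == 0.0


def test_clean_archetype_has_no_biology():
    assert CLEAN_ARCHETYPE.pigment_means.total == 0.0
    assert CLEAN_ARCHETYPE.population_specs == ()
    assert ORANGE_ARCHETYPE.taxon_profile[0][1] == pytest.approx(0.47)
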