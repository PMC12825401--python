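"""Synthetic snow-algae spectra, communities and pigment tables.

The generator is the package's forward model: clean-snow HDRF is a smooth
baseline with a visible plateau (~0.25 mean over 400-700 nm) and a declining
near-infrared tail (~0.16 mean over 700-1300 nm); a bloom spectrum is the
clean baseline attenuated multiplicatively, Beer-Lambert style,

    R_algae(l) = R_clean(l) * exp(-OD_pig(l) - OD_gray - tau * ramp_NIR(l))

where OD_pig is a sum of Gaussian pigment absorption kernels scaled by the
sample's pigment concentrations, OD_gray is a spectrally flat "package
effect" term for astaxanthin-laden cysts (dense intracellular pigment
flattens in-situ absorption toward gray), and the smooth NIR ramp captures
color-specific snow-physics effects that pigments alone cannot produce.

Each color archetype (red / orange / green) is parameterized from published
group means: pigment pools, cell geometry and densities.  The optical
constants per archetype — a packaging scale on the Gaussian kernels, a
chlorophyll-masking factor, the NIR optical-depth offset, and for red the
flat cyst gray depth — are calibrated once (scripts/calibrate_archetypes.py)
so the archetype mean spectrum lands on the published group-mean PAR/NIR
reflectances and band-depth index; the constants are frozen here.  Because
the flat gray term cancels exactly in the continuum-removed band-depth
ratio, red snow keeps a small band depth (and a weak band-depth-to-Chl-a
coupling) despite strong visible darkening, while the unmasked chlorophyll
of orange/green blooms drives a strong band-depth-to-Chl-a coupling.

All randomness flows from one integer seed through numpy SeedSequence
spawning; regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_io import (
    CellPopulation,
    IrradianceTable,
    NIR_WINDOW,
    PAR_WINDOW,
    PigmentProfile,
    SampleBiology,
    Spectrum,
    analysis_grid,
    write_irradiance,
    write_spectrum,
)

# ---------------------------------------------------------------------------
# pigment absorption kernels: Gaussian optical-depth shapes per ug ml^-1.
# Centers/widths are in-vivo conventions: Chl-a red peak ~680 nm, Chl-b
# ~650 nm, astaxanthin a broad carotenoid band through the green (its long
# tail past 560 nm is what depresses the Band-3 continuum shoulder in red
# snow), beta-carotene ~454 nm.
PIGMENT_KERNELS: dict[str, tuple[float, float, float]] = {
    # name: (center_nm, sigma_nm, strength per ug ml^-1)
    "astax": (480.0, 35.0, 0.45),
    "bcar": (454.0, 28.0, 0.40),
    "chla": (678.0, 14.0, 0.80),
    "chlb": (650.0, 12.0, 0.50),
}

#: Per-wavelength additive measurement noise SD on generated spectra.
SPECTRAL_NOISE_SD = 0.002
#: Relative amplitude variability of clean-snow samples across sites.
CLEAN_AMPLITUDE_CV = 0.08
#: Relative amplitude variability of the snow base under bloom samples
#: (replicates within one bloom patch share snow conditions more closely).
BLOOM_AMPLITUDE_CV = 0.03
#: Relative SD of the smooth per-sample baseline shape perturbation (snow
#: grain size, stratification and inorganic-particle effects vary the
#: spectral shape site to site, not just its amplitude).
SHAPE_NOISE_SD = 0.015
#: Knots of the smooth shape perturbation across the analysis window (nm).
_SHAPE_KNOTS = np.array([400.0, 580.0, 760.0, 940.0, 1120.0, 1300.0])

_PAR_TARGET = 0.25   # published clean-snow visible mean HDRF
_NIR_TARGET = 0.16   # published clean-snow near-infrared mean HDRF


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _raw_baseline(grid: np.ndarray) -> np.ndarray:
    """Smooth monotone-declining snow reflectance shape (unnormalized)."""
    from scipy.interpolate import PchipInterpolator

    knots = np.array([
        (350.0, 0.26), (550.0, 0.26), (650.0, 0.245), (700.0, 0.23),
        (800.0, 0.195), (950.0, 0.155), (1100.0, 0.125), (1350.0, 0.095),
    ])
    return PchipInterpolator(knots[:, 0], knots[:, 1])(grid)


def clean_baseline(grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """The analytic clean-snow baseline, scaled to the target window means.

    Returns (grid, baseline).  Two smooth multiplicative corrections blend
    across 650-750 nm so the PAR and NIR means each land on target.
    """
    if grid is None:
        grid = analysis_grid()
    base = _raw_baseline(grid)

    def window_mean(vals: np.ndarray, lo: float, hi: float) -> float:
        sel = (grid >= lo) & (grid <= hi)
        return float(np.trapezoid(vals[sel], grid[sel]) / (hi - lo))

    blend = _smoothstep((grid - 650.0) / 100.0)
    for _ in range(4):  # alternate corrections converge quickly
        f_par = _PAR_TARGET / window_mean(base, *PAR_WINDOW)
        base = base * ((1.0 - blend) * f_par + blend)
        f_nir = _NIR_TARGET / window_mean(base, *NIR_WINDOW)
        base = base * ((1.0 - blend) + blend * f_nir)
    return grid, base


def nir_ramp(grid: np.ndarray) -> np.ndarray:
    """Smooth 0-to-1 ramp across 700-1000 nm for NIR optical-depth offsets."""
    return _smoothstep((grid - 700.0) / 300.0)


def pigment_optical_depth(
    pigments: PigmentProfile,
    grid: np.ndarray,
    packaging_scale: float = 1.0,
    chl_masking: float = 1.0,
) -> np.ndarray:
    """Summed Gaussian pigment optical depth on the grid.

    ``packaging_scale`` multiplies all kernels (bulk concentration to in-situ
    optical effect); ``chl_masking`` in (0, 1] additionally down-weights the
    chlorophyll kernels, emulating pigment packaging inside carotenoid-rich
    cysts.
    """
    if pigments.missing:
        raise ValueError("cannot build optical depth from a missing pigment profile")
    od = np.zeros_like(grid, dtype=float)
    for name, (center, sigma, strength) in PIGMENT_KERNELS.items():
        conc = getattr(pigments, name)
        if conc < 0:
            raise ValueError("negative pigment concentration")
        weight = strength * conc * packaging_scale
        if name in ("chla", "chlb"):
            weight *= chl_masking
        od += weight * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return od


# ---------------------------------------------------------------------------
# archetypes

@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distribution for one cell population within an archetype."""

    shape: str
    dim_major_um: float
    dim_major_cv: float
    density_cells_ml: float
    density_cv: float
    dim_minor_um: float | None = None
    dim_minor_cv: float = 0.0


@dataclass(frozen=True)
class BloomArchetype:
    """Parameter bundle for one bloom color: pigments, cells, optics, taxa."""

    name: str
    pigment_means: PigmentProfile
    pigment_cv: float = 0.15
    population_specs: tuple[PopulationSpec, ...] = ()
    packaging_scale: float = 1.0
    chl_masking: float = 1.0
    nir_tau: float = 0.0
    cyst_gray_od: float = 0.0
    amplitude_cv: float = BLOOM_AMPLITUDE_CV
    taxon_profile: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.name not in ("red", "orange", "green", "clean"):
            raise ValueError(f"unknown archetype name {self.name!r}")
        if self.name == "clean" and (
            self.pigment_means.total > 0 or self.population_specs
        ):
            raise ValueError("clean archetype must have zero pigments and populations")
        if self.packaging_scale < 0 or not 0 < self.chl_masking <= 1:
            raise ValueError("packaging_scale >= 0 and 0 < chl_masking <= 1 required")
        if self.cyst_gray_od < 0:
            raise ValueError("cyst_gray_od must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


# Optical constants calibrated once against published group-mean reflectances
# (PAR/NIR HDRF: red 0.11/0.12, orange 0.15/0.19, green 0.19/0.16 against
# clean 0.25/0.16) and the published group-mean band-depth indices; frozen
# from scripts/calibrate_archetypes.py.  Orange and green have no gray cyst
# term; red's packaging scale is fixed to the orange/green mean (the Gaussian
# kernel scale is treated as a shared cell-optics property) and its remaining
# PAR darkening is carried by the flat cyst package term.
_CALIBRATED = {
    #        packaging  chl_masking  nir_tau   cyst_gray_od
    "red":    (2.4087,   0.1418,     -0.0616,   0.3287),
    "orange": (2.7042,   0.5698,     -0.2523,   0.0),
    "green":  (2.1133,   0.2455,     -0.0018,   0.0),
}

# Pigment pools (ug ml^-1 melted snow) and cell populations parameterized
# from published group means; Chl-a split from total Chl via the published
# per-cell Chl-a contents times group cell densities.
RED_ARCHETYPE = BloomArchetype(
    name="red",
    pigment_means=PigmentProfile(astax=2.39, chla=0.434, chlb=0.186, bcar=0.13),
    population_specs=(
        PopulationSpec("sphere", 35.96, 0.030, 3175.0, 0.15),
    ),
    packaging_scale=_CALIBRATED["red"][0],
    chl_masking=_CALIBRATED["red"][1],
    nir_tau=_CALIBRATED["red"][2],
    cyst_gray_od=_CALIBRATED["red"][3],
    taxon_profile=(
        ("Sanguina nivaloides", 0.60), ("Chloromonas alpina", 0.20),
        ("Chloromonas sp.", 0.17), ("other Chlorophyta", 0.03),
    ),
)

ORANGE_ARCHETYPE = BloomArchetype(
    name="orange",
    pigment_means=PigmentProfile(astax=1.85, chla=0.310, chlb=0.290, bcar=0.03),
    population_specs=(
        PopulationSpec("prolate_spheroid", 25.9, 0.070, 19154.0, 0.15,
                       dim_minor_um=14.6, dim_minor_cv=0.040),
    ),
    packaging_scale=_CALIBRATED["orange"][0],
    chl_masking=_CALIBRATED["orange"][1],
    nir_tau=_CALIBRATED["orange"][2],
    taxon_profile=(
        ("Chloromonas sp.", 0.47), ("Chloromonas alpina", 0.46),
        ("Sanguina nivaloides", 0.04), ("other Chlorophyta", 0.03),
    ),
)

GREEN_ARCHETYPE = BloomArchetype(
    name="green",
    pigment_means=PigmentProfile(astax=0.92, chla=0.587, chlb=0.813, bcar=0.05),
    population_specs=(
        PopulationSpec("prolate_spheroid", 21.1, 0.055, 97815.0, 0.15,
                       dim_minor_um=14.7, dim_minor_cv=0.070),
        PopulationSpec("sphere", 8.3, 0.035, 2185.0, 0.25),
    ),
    packaging_scale=_CALIBRATED["green"][0],
    chl_masking=_CALIBRATED["green"][1],
    nir_tau=_CALIBRATED["green"][2],
    taxon_profile=(
        ("Chloromonas alpina", 0.86), ("Chloromonas sp.", 0.06),
        ("Sanguina nivaloides", 0.05), ("other Chlorophyta", 0.03),
    ),
)

CLEAN_ARCHETYPE = BloomArchetype(
    name="clean",
    pigment_means=PigmentProfile(missing=False),
    population_specs=(),
    amplitude_cv=CLEAN_AMPLITUDE_CV,
)

DEFAULT_ARCHETYPES = (RED_ARCHETYPE, ORANGE_ARCHETYPE, GREEN_ARCHETYPE)


# ---------------------------------------------------------------------------
# spectrum synthesis

def _shape_perturbation(rng: np.random.Generator, grid: np.ndarray,
                        shape_sd: float) -> np.ndarray:
    """Smooth unit-mean multiplicative shape wiggle (cubic through 6 knots)."""
    if shape_sd <= 0:
        return np.ones_like(grid)
    from scipy.interpolate import CubicSpline

    knots = 1.0 + rng.normal(0.0, shape_sd, size=_SHAPE_KNOTS.size)
    return CubicSpline(_SHAPE_KNOTS, knots, bc_type="natural")(grid)


def synth_clean_spectrum(
    seed: int | np.random.Generator,
    sample_id: str = "clean",
    replicate: int = 1,
    amplitude_cv: float = CLEAN_AMPLITUDE_CV,
    noise_sd: float = SPECTRAL_NOISE_SD,
    shape_sd: float = SHAPE_NOISE_SD,
) -> Spectrum:
    """One clean-snow spectrum: scaled, shape-perturbed baseline plus noise."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    grid, base = clean_baseline()
    hdrf = base * _lognormal_factor(rng, amplitude_cv)
    hdrf = hdrf * _shape_perturbation(rng, grid, shape_sd)
    if noise_sd > 0:
        hdrf = hdrf + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(hdrf, 0.0, None), sample_id=sample_id,
                    color_group="clean", replicate=replicate)


def synth_bloom_spectrum(
    clean: Spectrum,
    pigments: PigmentProfile,
    archetype: BloomArchetype,
    seed: int | np.random.Generator,
    noise_sd: float = SPECTRAL_NOISE_SD,
) -> Spectrum:
    """Attenuate a clean spectrum by the archetype's pigment + NIR optics.

    Three optical-depth terms: the Gaussian pigment kernels (chlorophylls
    down-weighted by the masking factor), a spectrally flat "gray" package
    term for astaxanthin-laden cysts that scales with the sample's
    astaxanthin pool, and the smooth NIR ramp.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    grid = clean.wavelengths_nm
    od = pigment_optical_depth(pigments, grid, archetype.packaging_scale,
                               archetype.chl_masking)
    if archetype.cyst_gray_od > 0:
        mean_astax = archetype.pigment_means.astax
        rel = pigments.astax / mean_astax if mean_astax > 0 else 1.0
        od = od + archetype.cyst_gray_od * rel
    od = od + archetype.nir_tau * nir_ramp(grid)
    hdrf = clean.hdrf * np.exp(-od)
    if noise_sd > 0:
        hdrf = hdrf + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(hdrf, 0.0, None), sample_id=clean.sample_id,
                    color_group=archetype.name, replicate=clean.replicate)


def draw_sample_biology(
    archetype: BloomArchetype,
    rng: np.random.Generator,
    sample_id: str,
) -> SampleBiology:
    """Draw one sample's populations and pigments around the archetype means.

    A shared lognormal biomass factor scales densities and all pigments
    together (blooms with more cells carry more pigment), with smaller
    independent per-pigment and per-population jitters on top.
    """
    biomass = _lognormal_factor(rng, archetype.pigment_cv)
    pig_vals = {}
    for name in ("astax", "chla", "chlb", "bcar"):
        jitter = _lognormal_factor(rng, archetype.pigment_cv / 2.0)
        pig_vals[name] = getattr(archetype.pigment_means, name) * biomass * jitter
    pops = []
    for spec in archetype.population_specs:
        dens = spec.density_cells_ml * biomass * _lognormal_factor(
            rng, spec.density_cv / 2.0
        )
        minor = None
        if spec.dim_minor_um is not None:
            minor = spec.dim_minor_um * _lognormal_factor(rng, spec.dim_minor_cv)
        pops.append(CellPopulation(
            shape=spec.shape,
            dim_major_um=spec.dim_major_um * _lognormal_factor(rng, spec.dim_major_cv),
            dim_minor_um=minor,
            density_cells_ml=dens,
        ))
    return SampleBiology(
        sample_id=sample_id,
        color_group=archetype.name,
        cell_populations=tuple(pops),
        pigments=PigmentProfile(**pig_vals),
    )


def draw_taxon_abundances(
    archetype: BloomArchetype, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Relative taxon abundances: archetype profile with logit-normal jitter."""
    if not archetype.taxon_profile:
        return []
    names = [t for t, _ in archetype.taxon_profile]
    props = np.array([p for _, p in archetype.taxon_profile], dtype=float)
    jittered = props * np.exp(rng.normal(0.0, 0.10, size=props.size))
    jittered = jittered / jittered.sum()
    return list(zip(names, jittered.tolist()))


def synthetic_solar_irradiance(grid: np.ndarray | None = None) -> IrradianceTable:
    """SYNTHETIC clear-sky downwelling irradiance (W m^-2 nm^-1).

    A smooth blackbody-shaped (5800 K) analytic approximation scaled to
    ~1.35 W m^-2 nm^-1 at 500 nm, giving realistic clear-sky magnitudes over
    400-1300 nm.  This table is a stand-in for site-specific modeled
    irradiance and is NOT authoritative; any user-supplied CSV can replace it.
    """
    if grid is None:
        grid = analysis_grid()
    h, c, kb, temp = 6.626e-34, 2.998e8, 1.381e-23, 5800.0
    lam = grid * 1e-9
    planck = (1.0 / lam ** 5) / np.expm1(h * c / (lam * kb * temp))
    lam0 = 500e-9
    planck0 = (1.0 / lam0 ** 5) / np.expm1(h * c / (lam0 * kb * temp))
    return IrradianceTable(grid, 1.35 * planck / planck0)


# ---------------------------------------------------------------------------
# full study-design sample sets

def generate_dataset(
    archetypes: Sequence[BloomArchetype] = DEFAULT_ARCHETYPES,
    n_per_group: int = 7,
    n_clean: int = 6,
    seed: int = 0,
) -> tuple[list[Spectrum], list[SampleBiology], pd.DataFrame]:
    """In-memory synthetic study: spectra, biology and taxon tables.

    Emulates the field design: ``n_per_group`` bloom sites per color plus
    ``n_clean`` clean-snow reference sites, one spectrum per site, joinable by
    sample_id.  Deterministic per seed via SeedSequence spawning.
    """
    if n_per_group < 1 or n_clean < 1:
        raise ValueError("n_per_group and n_clean must be >= 1")
    ss = np.random.SeedSequence(seed)
    spectra: list[Spectrum] = []
    biology: list[SampleBiology] = []
    taxa_rows: list[dict] = []

    clean_children = ss.spawn(n_clean)
    for i, child in enumerate(clean_children):
        rng = np.random.default_rng(child)
        sid = f"clean_{i + 1:02d}"
        spectra.append(synth_clean_spectrum(rng, sample_id=sid, replicate=1))

    for archetype in archetypes:
        children = ss.spawn(n_per_group)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            sid = f"{archetype.name}_{i + 1:02d}"
            bio = draw_sample_biology(archetype, rng, sid)
            base = synth_clean_spectrum(
                rng, sample_id=sid, replicate=1,
                amplitude_cv=archetype.amplitude_cv, noise_sd=0.0,
            )
            spectra.append(synth_bloom_spectrum(base, bio.pigments, archetype, rng))
            biology.append(bio)
            for taxon, ab in draw_taxon_abundances(archetype, rng):
                taxa_rows.append(
                    {"sample_id": sid, "taxon": taxon, "relative_abundance": ab}
                )
    taxa = pd.DataFrame(taxa_rows, columns=["sample_id", "taxon",
                                            "relative_abundance"])
    return spectra, biology, taxa


def biology_to_frame(biology: Sequence[SampleBiology]) -> pd.DataFrame:
    """Flatten SampleBiology records to the documented biology CSV schema."""
    rows = []
    for bio in biology:
        for j, pop in enumerate(bio.cell_populations):
            rows.append({
                "sample_id": bio.sample_id,
                "color_group": bio.color_group,
                "cell_shape": pop.shape,
                "dim_major_um": pop.dim_major_um,
                "dim_minor_um": pop.dim_minor_um,
                "density_cells_ml": pop.density_cells_ml,
                # per-sample columns only on the first population row
                "astax_ug_ml": bio.pigments.astax if j == 0 else np.nan,
                "chla_ug_ml": bio.pigments.chla if j == 0 else np.nan,
                "chlb_ug_ml": bio.pigments.chlb if j == 0 else np.nan,
                "bcar_ug_ml": bio.pigments.bcar if j == 0 else np.nan,
                "laip_mg_m2": bio.laip_mg_m2 if j == 0 else np.nan,
            })
    return pd.DataFrame(rows)


def synth_sample_set(
    outdir: str | Path,
    archetypes: Sequence[BloomArchetype] = DEFAULT_ARCHETYPES,
    n_per_group: int = 7,
    n_clean: int = 6,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete on-disk fixture set in the documented CSV formats.

    Produces spectra/*.csv, manifest.csv, biology.csv, taxa.csv and a bundled
    synthetic irradiance.csv, all joinable by sample_id; byte-identical when
    regenerated with the same seed.
    """
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    spectra, biology, taxa = generate_dataset(archetypes, n_per_group, n_clean, seed)

    manifest_rows = []
    for s in spectra:
        fname = f"spectra/{s.sample_id}.csv"
        write_spectrum(s, outdir / fname)
        manifest_rows.append({
            "file": fname, "sample_id": s.sample_id,
            "color_group": s.color_group, "replicate": s.replicate,
        })
    paths = {
        "manifest": outdir / "manifest.csv",
        "biology": outdir / "biology.csv",
        "taxa": outdir / "taxa.csv",
        "irradiance": outdir / "irradiance.csv",
    }
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    biology_to_frame(biology).to_csv(paths["biology"], index=False)
    taxa.to_csv(paths["taxa"], index=False)
    write_irradiance(synthetic_solar_irradiance(), paths["irradiance"])
    return paths


# ---------------------------------------------------------------------------
# one-off optical calibration (used by scripts/calibrate_archetypes.py)

def _window_ratio(base: np.ndarray, atten: np.ndarray, grid: np.ndarray,
                  lo: float, hi: float) -> float:
    sel = (grid >= lo) & (grid <= hi)
    return float(
        np.trapezoid((base * atten)[sel], grid[sel])
        / np.trapezoid(base[sel], grid[sel])
    )


def calibrate_archetype_optics(
    pigment_means: PigmentProfile,
    par_ratio: float,
    nir_ratio: float,
    ib4_target: float | None = None,
    fixed_packaging_scale: float | None = None,
) -> tuple[float, float, float, float]:
    """Solve the optical constants (scale, masking, nir_tau, gray) for one
    archetype so its mean spectrum lands on published group means.

    The free constant that matches the PAR reflectance ratio is the packaging
    scale by default; when ``fixed_packaging_scale`` is given (red cysts,
    whose Gaussian kernel scale is pinned to the shared cell-optics value),
    the spectrally flat cyst gray optical depth takes over that role.  The
    flat term cancels exactly in the continuum-removed band-depth ratio, so
    the band-depth target is carried entirely by the masked chlorophyll
    kernels.  nir_tau matches the NIR ratio; when ``ib4_target`` is given,
    chl_masking is solved so the band-depth index lands on the published
    value.  The one-dimensional solves iterate to joint convergence.
    """
    from scipy.optimize import brentq

    from .band_optics import ib4_from_spectrum

    grid, base = clean_baseline()
    ramp = nir_ramp(grid)

    def total_od(scale, masking, tau, gray):
        od = pigment_optical_depth(pigment_means, grid, scale, masking)
        return od + gray + tau * ramp

    def ratio_of(window, scale, masking, tau, gray):
        return _window_ratio(base, np.exp(-total_od(scale, masking, tau, gray)),
                             grid, *window)

    def ib4_of(scale, masking, tau, gray):
        s = Spectrum(grid, base * np.exp(-total_od(scale, masking, tau, gray)))
        return ib4_from_spectrum(s)

    scale = fixed_packaging_scale if fixed_packaging_scale is not None else 1.0
    masking, tau, gray = 1.0, 0.0, 0.0
    for _ in range(80):
        prev = (scale, masking, tau, gray)
        if fixed_packaging_scale is None:
            scale = brentq(
                lambda s: ratio_of(PAR_WINDOW, s, masking, tau, gray) - par_ratio,
                0.0, 200.0, xtol=1e-12)
        else:
            gray = brentq(
                lambda g: ratio_of(PAR_WINDOW, scale, masking, tau, g) - par_ratio,
                0.0, 20.0, xtol=1e-12)
        if ib4_target is not None:
            masking = brentq(
                lambda m: ib4_of(scale, m, tau, gray) - ib4_target,
                1e-6, 1.0, xtol=1e-12)
        tau = brentq(
            lambda t: ratio_of(NIR_WINDOW, scale, masking, t, gray) - nir_ratio,
            -10.0, 10.0, xtol=1e-12)
        if max(abs(a - b) for a, b in zip((scale, masking, tau, gray), prev)) < 1e-9:
            break
    return float(scale), float(masking), float(tau), float(gray)
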