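# Methods

This document defines the quantities computed by `snowbloom`, the forward
model behind the synthetic-data generator, how the generator was calibrated,
and the numerical choices and known limitations.

## Data model

- **Spectrum** — hemispherical-directional reflectance factor (HDRF) samples
  on a wavelength grid in nm. The analysis grid is 400–1300 nm at 1-nm
  spacing (901 points). Input files may cover the full instrument range
  (350–2500 nm); readers keep only in-range rows, average duplicate
  wavelengths, and either clip small negative values to zero with a warning
  or, in strict mode, reject them.
- **Windows** — PAR is 400–700 nm, NIR is 700–1300 nm. Window means are
  trapezoid-rule averages, `∫R dλ / (hi − lo)`, with the window endpoints
  inserted into the grid so sub-grid windows are handled exactly.
- **IrradianceTable** — downwelling spectral irradiance Ed(λ) in W m⁻² nm⁻¹.
- **SampleBiology** — per-sample cell populations (shape and dimensions in
  µm, density in cells ml⁻¹ of melted snow) and a pigment profile
  (astaxanthin, Chl-a, Chl-b, β-carotene in µg ml⁻¹ of melted snow).

## Band depth (IB4)

Band-equivalent reflectances use Sentinel-2A boxcar bands:

| band | center (nm) | width (nm) | support (nm) |
|------|-------------|------------|---------------|
| B3   | 560         | 36         | 542–578       |
| B4   | 665         | 31         | 649.5–680.5   |
| B5   | 705         | 15         | 697.5–712.5   |

For a boxcar response the band value is the window mean over the support;
Gaussian or tabulated responses are integrated on a 0.1-nm fine grid. The
continuum under B4 is the linear interpolation between the B3 and B5 centers
evaluated at 665 nm:

```
R_cont = R_B3 + (104/144) · (R_B5 − R_B3)
IB4    = (R_cont − R_B4) / R_cont
```

`snowbloom` reports IB4 as a fraction (0.19 = 19%); published tables that
use a ×100 scaling are directly comparable after multiplying by 100. A key
property used throughout: any spectrally flat multiplicative factor on the
spectrum cancels in the ratio, so IB4 isolates the shape of the chlorophyll
absorption near 680 nm from overall brightness.

## Instantaneous radiative forcing (IRF)

```
IRF(lo, hi) = ∫_lo^hi Ed(λ) · (R_clean(λ) − R_algae(λ)) dλ      [W m⁻²]
```

where R_clean is the mean of the clean-snow reference spectra. Integration
is trapezoidal with window endpoints inserted, which makes the PAR + NIR
partition of the full-window IRF exact to floating point. Normalizations
divide by cell density in units of 10³ cells ml⁻¹ or by biovolume in
10⁶ µm³ ml⁻¹. IRF can be negative in a window where the bloom is brighter
than clean snow.

## Biomass and pigments

Cell volumes are a sphere `π/6·d³` or a prolate spheroid `π/6·a·b²`
(major axis a, minor axis b). Total biovolume sums `density × volume` over
populations. Per-cell and per-biovolume pigment normalizations divide the
pool concentrations by total density and total biovolume respectively.
`pigment_signature` expresses each pigment as a percentage of the summed
pool. Note that per-cell quantities computed from group-mean dimensions
differ from means of per-cell quantities (Jensen's inequality); `snowbloom`
always computes per sample first.

## Group statistics

Kruskal–Wallis uses the tie-corrected H statistic with a chi-square
reference distribution (via scipy). Dunn's post-hoc z for groups i, j uses
mean mid-ranks and the tie-corrected variance

```
z_ij = (R̄_i − R̄_j) / sqrt( [N(N+1)/12 − T/(12(N−1))] · (1/n_i + 1/n_j) )
T    = Σ_ties (t³ − t)
```

with two-sided normal p-values and Bonferroni or Holm adjustment. Pearson
correlations and log₁₀-abundance regressions wrap scipy. A two-way ANOVA
entry point exists only as a documented stub (`NotImplementedError`):
the sampling designs targeted here are unbalanced and non-normal, so the
rank-based path is the supported one.

## Synthetic-data generator

The generator exists to exercise the pipeline and to run parameter-recovery
experiments; its defaults are the study conditions and are not tuned per
run.

### Clean snow

An analytic smooth monotone-declining baseline (PCHIP through fixed knots)
is rescaled by two smooth multiplicative corrections blending across
650–750 nm so that the noise-free baseline has PAR mean 0.25 and NIR mean
0.16 exactly. Per sample, the baseline is multiplied by a lognormal
amplitude factor (CV 0.08 for clean sites, 0.03 for the snow under bloom
replicates) and by a smooth shape perturbation — a natural cubic spline
through unit-mean Gaussian knots at 400/580/760/940/1120/1300 nm with SD
0.015 — then white measurement noise with SD 0.002 is added.

### Bloom forward model

```
R_algae(λ) = R_clean(λ) · exp( −OD_pig(λ) − OD_gray − τ · ramp_NIR(λ) )
```

- **OD_pig** — a sum of Gaussian absorption kernels per pigment, scaled by
  concentration, a per-archetype `packaging_scale`, and (for the two
  chlorophylls) a `chl_masking` factor in (0, 1] that emulates packaging of
  chlorophyll inside carotenoid-rich cells. Kernels (center, σ, strength
  per µg ml⁻¹): astaxanthin (480, 35, 0.45), β-carotene (454, 28, 0.40),
  Chl-a (678, 14, 0.80), Chl-b (650, 12, 0.50).
- **OD_gray** — a spectrally flat optical depth for astaxanthin-laden cysts
  (red archetype only), scaled by the sample's astaxanthin pool relative to
  the archetype mean. Because it is flat it darkens both windows but cancels
  exactly in the IB4 ratio: red samples can be strongly darkened yet show
  almost no band depth, and their IB4 carries little biomass information.
- **τ · ramp_NIR** — a smoothstep ramp from 700 to 1000 nm with archetype
  coefficient τ, capturing NIR brightening/darkening by the bloom's effect
  on snow physics (τ < 0 brightens; orange snow has a higher NIR mean than
  clean snow, so bloom reflectance may legitimately exceed clean in the
  NIR).

### Biology draws

Each sample draws a shared unit-mean lognormal biomass factor (CV 0.15)
that multiplies all pigment pools and cell densities together, with smaller
independent unit-mean lognormal jitters on top (CV 0.075 per pigment,
half the nominal density CV per population, plus dimension jitters). The
shared factor encodes that denser blooms carry more pigment of every kind;
it sets a correlation floor of roughly 0.8 between log pigment pools, so
only a band metric that is insensitive to biomass (red IB4, via the flat
gray term) decorrelates from Chl-a.

### Calibration (one-time, frozen)

For each archetype, `scripts/calibrate_archetypes.py` solves (by bracketed
root-finding on the noise-free mean spectrum, iterated to 1e-9 joint
convergence) for the optical constants that put the archetype-mean spectrum
on its calibration targets: PAR mean, NIR mean, and IB4. Orange and green
are solved first with `packaging_scale` free; red's `packaging_scale` is
fixed a priori to the orange/green average (cell optics, not redness,
should set it) and the flat gray term absorbs red's remaining PAR
darkening. The frozen result:

| archetype | packaging_scale | chl_masking | nir_tau  | cyst_gray_od |
|-----------|-----------------|-------------|----------|--------------|
| red       | 2.4087          | 0.1418      | −0.0616  | 0.3287       |
| orange    | 2.7042          | 0.5698      | −0.2523  | 0.0          |
| green     | 2.1133          | 0.2455      | −0.0018  | 0.0          |

These constants are data in `snowbloom/synthetic_data.py`; the script exists
so the derivation is reproducible, not to be re-run per analysis.

### Determinism

All randomness flows from a single integer seed through numpy
`SeedSequence` spawning: per-sample child sequences are created in a fixed
order, so generated datasets are byte-identical across runs and platforms
for a given seed, and independent across seeds.

## Numerical choices

- Trapezoid integration everywhere, with exact endpoint insertion for
  sub-grid windows; this makes window additivity exact rather than
  approximate.
- Non-boxcar band responses are evaluated on a 0.1-nm fine grid by linear
  interpolation; for the piecewise-linear spectra used here the fine-grid
  midpoint rule is exact up to floating point.
- Resampling to the analysis grid is linear interpolation and refuses to
  extrapolate beyond the data's wavelength range.
- Root-finding in calibration uses Brent's method with wide fixed brackets
  and 1e-12 tolerance.

## Limitations

- The synthetic solar irradiance is a smooth analytic curve of plausible
  magnitude, suitable for testing and relative comparisons; it is not an
  atmospheric radiative-transfer product and absolute IRF values from it
  should not be quoted as field results.
- The generator models between-sample dispersion within one snowfield
  campaign; it does not model between-site, between-season, or topographic
  variability, nor mixed-color patches.
- Bloom optics are a three-term scalar model (pigment kernels, flat cyst
  term, NIR ramp); it reproduces window means and band depths but is not a
  radiative-transfer model of snow and should not be inverted for physical
  grain or impurity properties.
- Two-way ANOVA is deliberately unimplemented (see above).
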