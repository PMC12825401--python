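"""Band-range means, Sentinel-2A band-equivalent reflectance, and IB4.

The chlorophyll band-depth index IB4 quantifies the 665-nm chlorophyll-a
absorption feature against a linear continuum spanned between Sentinel-2A
Band 3 (560 nm) and Band 5 (705 nm):

    Rcont_B4 = R_B3 + (664 - 560) / (704 - 560) * (R_B5 - R_B3)
    IB4      = (Rcont_B4 - R_B4) / Rcont_B4

IB4 is positive when Band 4 sits below the continuum (chlorophyll absorption)
and suppressed when carotenoid absorption depresses the Band-3 shoulder — the
masking effect that makes red, astaxanthin-rich blooms hard to detect even
when their per-cell chlorophyll is high.

The continuum interpolation factor is 104/144 exactly as published (the
constants 664/704 differ by 1 nm from the nominal band centers 665/705; we
keep the published arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra_io import Spectrum, SpectrumRangeError

#: Continuum interpolation factor from the published band-depth formula.
CONTINUUM_FACTOR = (664.0 - 560.0) / (704.0 - 560.0)


@dataclass(frozen=True)
class BandDefinition:
    """A satellite band's spectral response function (SRF).

    ``boxcar`` weights [center - fwhm/2, center + fwhm/2] uniformly;
    ``gaussian`` uses a Gaussian with the given FWHM; ``tabulated`` uses an
    explicit (nm, weight) table.
    """

    name: str
    center_nm: float
    fwhm_nm: float
    srf_shape: str = "boxcar"
    srf_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.srf_shape not in ("boxcar", "gaussian", "tabulated"):
            raise ValueError(f"unknown srf_shape {self.srf_shape!r}")
        if self.srf_shape == "tabulated":
            if not self.srf_table:
                raise ValueError("tabulated SRF requires srf_table")
            w = np.array([p[1] for p in self.srf_table], dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("tabulated SRF weights must be >= 0 with positive sum")

    @property
    def support(self) -> tuple[float, float]:
        if self.srf_shape == "boxcar":
            h = self.fwhm_nm / 2.0
            return self.center_nm - h, self.center_nm + h
        if self.srf_shape == "gaussian":
            sigma = self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.center_nm - 4.0 * sigma, self.center_nm + 4.0 * sigma
        wl = [p[0] for p in self.srf_table]  # type: ignore[union-attr]
        return min(wl), max(wl)


#: Nominal Sentinel-2A visible/red-edge bands used for the chlorophyll index
#: (centers 560/665/705 nm, bandwidths 36/31/15 nm, boxcar by default).
SENTINEL2A_B3 = BandDefinition("B3", 560.0, 36.0)
SENTINEL2A_B4 = BandDefinition("B4", 665.0, 31.0)
SENTINEL2A_B5 = BandDefinition("B5", 705.0, 15.0)
SENTINEL2A_BANDS = (SENTINEL2A_B3, SENTINEL2A_B4, SENTINEL2A_B5)


def _refined_nodes(s: Spectrum, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Spectrum nodes restricted to [lo, hi] with the endpoints inserted."""
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if not s.covers(lo, hi):
        raise SpectrumRangeError(
            f"window [{lo}, {hi}] outside spectrum support {s.support}"
        )
    w = s.wavelengths_nm
    inner = w[(w > lo) & (w < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    return grid, s.value_at(grid)


def mean_reflectance(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoid-integral mean of HDRF over [lo, hi] nm.

    Exact for the piecewise-linear interpolant of the sampled spectrum.
    """
    grid, vals = _refined_nodes(s, lo, hi)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def band_equivalent_reflectance(s: Spectrum, band: BandDefinition) -> float:
    """SRF-weighted band reflectance: int R*S dl / int S dl over the band support."""
    lo, hi = band.support
    if band.srf_shape == "boxcar":
        return mean_reflectance(s, lo, hi)
    if not s.covers(lo, hi):
        raise SpectrumRangeError(
            f"band {band.name} support [{lo:.1f}, {hi:.1f}] outside spectrum "
            f"support {s.support}"
        )
    # fine common grid keeps the convolution accurate for any smooth SRF
    grid = np.linspace(lo, hi, int(np.ceil((hi - lo) / 0.1)) + 1)
    r = s.value_at(grid)
    if band.srf_shape == "gaussian":
        sigma = band.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        srf = np.exp(-0.5 * ((grid - band.center_nm) / sigma) ** 2)
    else:
        table = np.asarray(band.srf_table, dtype=float)
        order = np.argsort(table[:, 0])
        srf = np.interp(grid, table[order, 0], table[order, 1])
    denom = np.trapezoid(srf, grid)
    return float(np.trapezoid(r * srf, grid) / denom)


def continuum_reflectance_b4(rb3: float, rb5: float) -> float:
    """Linear continuum between Bands 3 and 5 evaluated at Band 4."""
    if not (np.isfinite(rb3) and np.isfinite(rb5)):
        raise ValueError("band reflectances must be finite")
    return rb3 + CONTINUUM_FACTOR * (rb5 - rb3)


def band_depth_ib4(rb3: float, rb4: float, rb5: float) -> float:
    """Scaled continuum-removed band depth at Band 4: (Rcont - RB4) / Rcont."""
    rcont = continuum_reflectance_b4(rb3, rb5)
    if rcont <= 0:
        raise ValueError("continuum reflectance <= 0: band depth undefined")
    return (rcont - rb4) / rcont


def ib4_from_spectrum(
    s: Spectrum, bands: Sequence[BandDefinition] = SENTINEL2A_BANDS
) -> float:
    """IB4 from a full spectrum via band-equivalent reflectances."""
    if len(bands) != 3:
        raise ValueError("need exactly three band definitions (B3, B4, B5)")
    rb3, rb4, rb5 = (band_equivalent_reflectance(s, b) for b in bands)
    return band_depth_ib4(rb3, rb4, rb5)


def band_reflectances(
    s: Spectrum, bands: Sequence[BandDefinition] = SENTINEL2A_BANDS
) -> dict[str, float]:
    """Band-equivalent reflectances keyed by band name."""
    return {b.name: band_equivalent_reflectance(s, b) for b in bands}


def percent_reduction(r_clean: float, r_algae: float) -> float:
    """Reflectance reduction of algal snow relative to clean snow, in percent."""
    if r_clean <= 0:
        raise ValueError("clean-snow reflectance must be > 0")
    return 100.0 * (r_clean - r_algae) / r_clean
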