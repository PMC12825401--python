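"""Reflectance and irradiance spectra: data model, readers, writers, resampling.

Field spectra are hemispherical-directional reflectance factors (HDRF) measured
with a contact-probe spectroradiometer and exported as two-column
wavelength/value tables.  All downstream optics assume a common 1-nm analysis
grid spanning 400-1300 nm: the visible/PAR window (400-700 nm) plus the
near-infrared window (700-1300 nm), where algal pigment signals live.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("snowbloom")

#: Common analysis grid: 1-nm steps, 400-1300 nm inclusive.
GRID_START_NM = 400.0
GRID_STOP_NM = 1300.0
GRID_STEP_NM = 1.0
PAR_WINDOW = (400.0, 700.0)
NIR_WINDOW = (700.0, 1300.0)

#: Wavelengths outside the instrument's physical range are rejected on read.
INSTRUMENT_RANGE_NM = (350.0, 2500.0)

COLOR_GROUPS = ("red", "orange", "green", "clean")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed into a valid Spectrum."""


class SpectrumRangeError(ValueError):
    """Raised when an operation requests wavelengths outside a spectrum's support."""


def analysis_grid() -> np.ndarray:
    """The default 1-nm analysis grid, 400-1300 nm inclusive (901 points)."""
    n = int(round((GRID_STOP_NM - GRID_START_NM) / GRID_STEP_NM)) + 1
    return GRID_START_NM + GRID_STEP_NM * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance measurement on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    hdrf
        Dimensionless reflectance factor per wavelength; finite and >= 0.
    sample_id
        Identifier joining the spectrum to its biology record.
    color_group
        One of ``red``, ``orange``, ``green``, ``clean``.
    replicate
        Replicate index within the sample's site.
    """

    wavelengths_nm: np.ndarray
    hdrf: np.ndarray
    sample_id: str = ""
    color_group: str = "clean"
    replicate: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        r = np.asarray(self.hdrf, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "hdrf", r)
        if w.ndim != 1 or r.shape != w.shape or w.size == 0:
            raise SpectrumParseError("wavelengths and hdrf must be matching 1-D arrays")
        if not np.all(np.diff(w) > 0):
            raise SpectrumParseError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise SpectrumParseError("hdrf values must be finite")
        if np.any(r < 0):
            raise SpectrumParseError("hdrf values must be >= 0 (clip on read or fix input)")
        if self.color_group not in COLOR_GROUPS:
            raise ValueError(f"unknown color_group {self.color_group!r}")

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def covers(self, lo: float, hi: float) -> bool:
        a, b = self.support
        return a <= lo and hi <= b

    def value_at(self, wavelength_nm: float | np.ndarray) -> np.ndarray:
        """Linear interpolation within support; no extrapolation."""
        w = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        a, b = self.support
        if np.any(w < a) or np.any(w > b):
            raise SpectrumRangeError(
                f"requested wavelength outside support [{a}, {b}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.hdrf)


@dataclass(frozen=True)
class IrradianceTable:
    """Downwelling spectral irradiance Ed(lambda) in W m^-2 nm^-1."""

    wavelengths_nm: np.ndarray
    ed: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        e = np.asarray(self.ed, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "ed", e)
        if w.ndim != 1 or e.shape != w.shape or w.size < 2:
            raise ValueError("irradiance table needs matching 1-D arrays, >= 2 rows")
        if not np.all(np.diff(w) > 0):
            raise ValueError("irradiance wavelengths must be strictly increasing")
        if not np.all(np.isfinite(e)) or np.any(e < 0):
            raise ValueError("irradiance must be finite and >= 0")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def value_at(self, wavelength_nm: float | np.ndarray) -> np.ndarray:
        w = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        a, b = self.support
        if np.any(w < a) or np.any(w > b):
            raise SpectrumRangeError(
                f"requested wavelength outside irradiance support [{a}, {b}] nm"
            )
        return np.interp(w, self.wavelengths_nm, self.ed)


# --- biology-side records (types owned here, math lives in biomass_pigments) ---

@dataclass(frozen=True)
class CellPopulation:
    """One morphological cell population within a sample.

    ``sphere`` uses dim_major_um as the diameter; ``prolate_spheroid`` uses
    dim_major_um / dim_minor_um as the major / minor axes.
    """

    shape: str
    dim_major_um: float
    density_cells_ml: float
    dim_minor_um: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "prolate_spheroid"):
            raise ValueError(f"unknown cell shape {self.shape!r}")
        if self.density_cells_ml < 0:
            raise ValueError("cell density must be >= 0")
        if self.dim_major_um < 0:
            raise ValueError("cell dimensions must be >= 0")
        if self.dim_minor_um is not None and self.dim_minor_um < 0:
            raise ValueError("cell dimensions must be >= 0")
        if self.shape == "prolate_spheroid" and self.density_cells_ml > 0:
            if self.dim_minor_um is None:
                raise ValueError("prolate spheroid requires a minor axis")
        if self.density_cells_ml > 0 and self.dim_major_um <= 0:
            raise ValueError("populated sample needs positive dimensions")


@dataclass(frozen=True)
class PigmentProfile:
    """Pigment concentrations in micrograms per millilitre of melted snow.

    The four pigments quantified in snow-algae blooms: the photoprotective
    ketocarotenoid astaxanthin, chlorophylls a and b, and beta-carotene.
    ``missing`` marks samples whose pigment columns were empty; pigment
    operations refuse such profiles.
    """

    astax: float = 0.0
    chla: float = 0.0
    chlb: float = 0.0
    bcar: float = 0.0
    missing: bool = False

    def __post_init__(self) -> None:
        for name in ("astax", "chla", "chlb", "bcar"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"pigment {name} must be finite and >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "astax": self.astax,
            "chla": self.chla,
            "chlb": self.chlb,
            "bcar": self.bcar,
        }

    @property
    def total(self) -> float:
        return self.astax + self.chla + self.chlb + self.bcar


@dataclass(frozen=True)
class SampleBiology:
    """Per-sample biology: cell populations, pigments and snow covariates."""

    sample_id: str
    color_group: str
    cell_populations: tuple[CellPopulation, ...] = ()
    pigments: PigmentProfile = field(default_factory=lambda: PigmentProfile(missing=True))
    laip_mg_m2: float | None = None
    snow_depth_cm: float | None = None
    surface_temp_c: float | None = None
    water_content_pct: float | None = None

    def __post_init__(self) -> None:
        if self.color_group not in COLOR_GROUPS:
            raise ValueError(f"unknown color_group {self.color_group!r}")
        if self.color_group != "clean" and not self.cell_populations:
            raise ValueError(
                f"sample {self.sample_id}: non-clean sample needs >= 1 cell population"
            )
        if self.laip_mg_m2 is not None and self.laip_mg_m2 < 0:
            raise ValueError("LAIP load must be >= 0")


# ----------------------------- readers / writers -----------------------------

def _read_two_column(path: Path) -> pd.DataFrame:
    """Read a two-column numeric table, tolerating one optional header line."""
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumParseError(f"{path}: expected two columns, got {df.shape[1]}")
    df = df.iloc[:, :2]
    # optional single header line: first row not parseable as numbers
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.empty:
        raise SpectrumParseError(f"{path}: no data rows")
    for col in (0, 1):
        coerced = pd.to_numeric(df.iloc[:, col], errors="coerce")
        bad = coerced.isna() & df.iloc[:, col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectrumParseError(
                f"{path}: non-numeric value {df.iloc[row, col]!r} in column "
                f"{col + 1}, data row {row + 1}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SpectrumParseError(f"{path}: missing value in data row {row + 1}")
        df.isetitem(col, coerced)
    return df.astype(float)


def read_spectrum(
    path: str | Path,
    sample_id: str = "",
    color_group: str = "clean",
    replicate: int = 1,
    negative: str = "clip",
) -> Spectrum:
    """Read a two-column wavelength/HDRF CSV into a validated Spectrum.

    Rows outside the instrument range (350-2500 nm) are dropped; duplicate
    wavelengths collapse by mean.  Negative reflectances are instrument noise
    and are clipped to zero with a warning (``negative="error"`` for strict
    mode).
    """
    path = Path(path)
    df = _read_two_column(path)
    df.columns = ["wavelength_nm", "value"]
    lo, hi = INSTRUMENT_RANGE_NM
    df = df[(df.wavelength_nm >= lo) & (df.wavelength_nm <= hi)]
    if df.empty:
        raise SpectrumParseError(f"{path}: no rows within {lo}-{hi} nm")
    collapsed = df.groupby("wavelength_nm", sort=True)["value"].mean()
    w = collapsed.index.to_numpy(dtype=float)
    r = collapsed.to_numpy(dtype=float)
    if np.any(r < 0):
        if negative == "error":
            raise SpectrumParseError(f"{path}: negative reflectance values present")
        n_neg = int(np.sum(r < 0))
        logger.warning("%s: clipped %d negative reflectance value(s) to 0", path, n_neg)
        r = np.clip(r, 0.0, None)
    return Spectrum(w, r, sample_id=sample_id, color_group=color_group,
                    replicate=replicate)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a Spectrum as the documented CSV dialect (wavelength_nm, value)."""
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, "value": s.hdrf}).to_csv(
        path, index=False
    )


def read_irradiance(path: str | Path) -> IrradianceTable:
    """Read a two-column wavelength / Ed (W m^-2 nm^-1) CSV."""
    df = _read_two_column(Path(path))
    df.columns = ["wavelength_nm", "ed"]
    df = df.sort_values("wavelength_nm")
    return IrradianceTable(df.wavelength_nm.to_numpy(), df.ed.to_numpy())


def write_irradiance(table: IrradianceTable, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": table.wavelengths_nm, "ed_w_m2_nm": table.ed}
    ).to_csv(path, index=False)


def resample_to_grid(
    s: Spectrum,
    grid_start: float = GRID_START_NM,
    grid_stop: float = GRID_STOP_NM,
    step: float = GRID_STEP_NM,
) -> Spectrum:
    """Linearly interpolate a spectrum onto a regular grid; never extrapolate."""
    if grid_stop <= grid_start or step <= 0:
        raise ValueError("grid_stop must exceed grid_start and step must be > 0")
    a, b = s.support
    if grid_start < a or grid_stop > b:
        raise SpectrumRangeError(
            f"requested grid [{grid_start}, {grid_stop}] outside spectrum "
            f"support [{a}, {b}]"
        )
    n = int(np.floor((grid_stop - grid_start) / step + 1e-9)) + 1
    grid = grid_start + step * np.arange(n)
    return replace(s, wavelengths_nm=grid, hdrf=np.interp(grid, s.wavelengths_nm, s.hdrf))


BIOLOGY_COLUMNS = [
    "sample_id", "color_group", "cell_shape", "dim_major_um", "dim_minor_um",
    "density_cells_ml", "astax_ug_ml", "chla_ug_ml", "chlb_ug_ml",
    "bcar_ug_ml", "laip_mg_m2",
]
_OPTIONAL_COVARIATES = ["snow_depth_cm", "surface_temp_c", "water_content_pct"]


def read_biology_table(path: str | Path) -> list[SampleBiology]:
    """Read the per-sample biology CSV; one SampleBiology per sample_id group.

    Each row describes one cell population; pigment and covariate columns are
    per-sample and are taken from the first non-missing row of the group.
    Empty pigment columns yield a profile flagged missing, which downstream
    pigment operations refuse.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "color_group", "cell_shape", "dim_major_um",
                "density_cells_ml"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing biology columns {sorted(missing_cols)}")
    out: list[SampleBiology] = []
    for sample_id, rows in df.groupby("sample_id", sort=False):
        color = str(rows.color_group.iloc[0])
        pops = []
        for _, row in rows.iterrows():
            dens = float(row.density_cells_ml)
            if dens < 0:
                raise ValueError(f"sample {sample_id}: negative cell density")
            if dens == 0 and pd.isna(row.cell_shape):
                continue
            minor = row.get("dim_minor_um")
            minor = None if pd.isna(minor) else float(minor)
            pops.append(CellPopulation(
                shape=str(row.cell_shape),
                dim_major_um=float(row.dim_major_um),
                dim_minor_um=minor,
                density_cells_ml=dens,
            ))

        def _first(col: str) -> float | None:
            if col not in rows.columns:
                return None
            vals = rows[col].dropna()
            return float(vals.iloc[0]) if len(vals) else None

        pig_vals = {k: _first(f"{k}_ug_ml") for k in ("astax", "chla", "chlb", "bcar")}
        if all(v is None for v in pig_vals.values()):
            pigments = PigmentProfile(missing=True)
        else:
            pigments = PigmentProfile(**{k: (v or 0.0) for k, v in pig_vals.items()})
        out.append(SampleBiology(
            sample_id=str(sample_id),
            color_group=color,
            cell_populations=tuple(pops),
            pigments=pigments,
            laip_mg_m2=_first("laip_mg_m2"),
            snow_depth_cm=_first("snow_depth_cm"),
            surface_temp_c=_first("surface_temp_c"),
            water_content_pct=_first("water_content_pct"),
        ))
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the manifest CSV mapping spectrum files to sample metadata."""
    df = pd.read_csv(path)
    required = {"file", "sample_id", "color_group", "replicate"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing_cols)}")
    bad = ~df.color_group.isin(COLOR_GROUPS)
    if bad.any():
        raise ValueError(f"{path}: unknown color_group values "
                         f"{sorted(df.color_group[bad].unique())}")
    return df


def load_spectra(manifest: pd.DataFrame, base_dir: str | Path,
                 resample: bool = True) -> list[Spectrum]:
    """Load every spectrum listed in a manifest, optionally onto the 1-nm grid."""
    base = Path(base_dir)
    out = []
    for _, row in manifest.iterrows():
        s = read_spectrum(base / row.file, sample_id=str(row.sample_id),
                          color_group=str(row.color_group),
                          replicate=int(row.replicate))
        if resample:
            s = resample_to_grid(s)
        out.append(s)
    return out
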