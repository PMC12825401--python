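"""Cell-geometry biovolume and pigment metrics.

Cell volumes follow standard phytoplankton geometric assumptions: spheres
(pi/6 * d^3) for the large red cysts and prolate spheroids (pi/6 * a * b^2)
for the oval orange cells; green communities mix both shapes.  Total
biovolume is the density-weighted sum of population volumes (um^3 per ml of
melted snow).

Pigment metrics: the signature (each pigment's percentage of the summed
pigment pool), the astaxanthin:Chl-a ratio (photoprotection vs photosynthetic
capacity), and per-cell / per-biovolume normalizations used to compare
chlorophyll packaging across bloom colors.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .spectra_io import CellPopulation, PigmentProfile

_PIGMENTS = ("astax", "chla", "chlb", "bcar")


def cell_volume(pop: CellPopulation) -> float:
    """Geometric cell volume in um^3 from the population's mean dimensions."""
    if pop.shape == "sphere":
        return float(np.pi / 6.0 * pop.dim_major_um ** 3)
    if pop.dim_minor_um is None:
        raise ValueError("prolate spheroid requires a minor axis")
    return float(np.pi / 6.0 * pop.dim_major_um * pop.dim_minor_um ** 2)


def mean_cell_volume(
    majors_um: Sequence[float],
    minors_um: Sequence[float] | None,
    shape: str,
) -> float:
    """Mean of per-cell volumes from individual cell measurements.

    Alternative averaging convention to :func:`cell_volume` (which uses the
    volume of the mean-dimension cell); per-cell averaging weights large cells
    more and is the convention some field datasets use.
    """
    majors = np.asarray(majors_um, dtype=float)
    if np.any(majors <= 0):
        raise ValueError("cell dimensions must be > 0")
    if shape == "sphere":
        return float(np.mean(np.pi / 6.0 * majors ** 3))
    if shape != "prolate_spheroid":
        raise ValueError(f"unknown cell shape {shape!r}")
    if minors_um is None:
        raise ValueError("prolate spheroid requires minor axes")
    minors = np.asarray(minors_um, dtype=float)
    if minors.shape != majors.shape or np.any(minors <= 0):
        raise ValueError("minor axes must match majors and be > 0")
    return float(np.mean(np.pi / 6.0 * majors * minors ** 2))


def total_biovolume(pops: Iterable[CellPopulation]) -> float:
    """Total biovolume (um^3 ml^-1): sum over populations of volume * density."""
    pops = list(pops)
    if not pops:
        raise ValueError("need at least one cell population")
    return float(sum(cell_volume(p) * p.density_cells_ml for p in pops))


def total_density(pops: Iterable[CellPopulation]) -> float:
    """Total cell density (cells ml^-1) over all populations."""
    pops = list(pops)
    if not pops:
        raise ValueError("need at least one cell population")
    return float(sum(p.density_cells_ml for p in pops))


def population_fractions(pops: Sequence[CellPopulation]) -> list[float]:
    """Each population's share of total cell density, in percent."""
    dens = np.array([p.density_cells_ml for p in pops], dtype=float)
    total = dens.sum()
    if total <= 0:
        raise ValueError("total cell density must be > 0")
    return list(100.0 * dens / total)


def _require_measured(p: PigmentProfile) -> None:
    if p.missing:
        raise ValueError("pigment profile is flagged missing; cannot compute")


def pigment_signature(p: PigmentProfile) -> dict[str, float]:
    """Each pigment's percentage of the total pigment pool; sums to 100."""
    _require_measured(p)
    total = p.total
    if total <= 0:
        raise ValueError("total pigment concentration must be > 0")
    return {k: 100.0 * getattr(p, k) / total for k in _PIGMENTS}


def astax_chla_ratio(p: PigmentProfile) -> float:
    """Astaxanthin : chlorophyll-a mass ratio."""
    _require_measured(p)
    if p.chla <= 0:
        raise ValueError("chlorophyll-a must be > 0 for the astaxanthin ratio")
    return p.astax / p.chla


def pigment_per_cell(p: PigmentProfile, density_cells_ml: float) -> dict[str, float]:
    """Pigment content per cell (ug per cell) from bulk melted-snow concentration."""
    _require_measured(p)
    if density_cells_ml <= 0:
        raise ValueError("cell density must be > 0")
    return {k: getattr(p, k) / density_cells_ml for k in _PIGMENTS}


def pigment_per_biovolume(p: PigmentProfile, biovolume_um3_ml: float) -> dict[str, float]:
    """Pigment content per unit biovolume (ug per um^3)."""
    _require_measured(p)
    if biovolume_um3_ml <= 0:
        raise ValueError("biovolume must be > 0")
    return {k: getattr(p, k) / biovolume_um3_ml for k in _PIGMENTS}


def total_chlorophyll(p: PigmentProfile) -> float:
    """Chl-a + Chl-b (the paper-style aggregated chlorophyll pool)."""
    _require_measured(p)
    return p.chla + p.chlb
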