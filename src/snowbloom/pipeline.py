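"""End-to-end orchestration: spectra + biology -> band metrics, forcing, stats.

`run_pipeline` composes the whole analysis chain deterministically: it loads
the manifest, spectra, irradiance and biology tables, computes per-sample
window means, Sentinel-2A band reflectances, the chlorophyll band-depth
index, radiative forcing (full/PAR/NIR, raw and biomass-normalized),
biovolume and pigment metrics, then per-color-group summaries, percent
reductions against the clean reference, and rank-based group comparisons.
Outputs mirror the supplementary-table layout of field studies: a per-sample
table, a group summary, and a statistics table with significance stars.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .band_optics import (
    SENTINEL2A_BANDS,
    band_depth_ib4,
    band_reflectances,
    mean_reflectance,
    percent_reduction,
)
from .biomass_pigments import (
    astax_chla_ratio,
    pigment_per_biovolume,
    pigment_per_cell,
    pigment_signature,
    total_biovolume,
    total_density,
)
from .group_stats import compare_groups, significance_stars
from .radiative_forcing import irf_for_sample, mean_clean_spectrum
from .spectra_io import (
    NIR_WINDOW,
    PAR_WINDOW,
    SampleBiology,
    Spectrum,
    load_spectra,
    read_biology_table,
    read_irradiance,
    read_manifest,
)

logger = logging.getLogger("snowbloom")

#: Variables compared across color groups in the stats table.
STATS_VARIABLES = ("par_mean", "nir_mean", "ib4", "irf_full_w_m2")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (paths, windows, options)."""

    manifest: str
    irradiance: str
    biology: str
    outdir: str
    taxa: str | None = None
    base_dir: str = "."
    par_window: tuple[float, float] = PAR_WINDOW
    nir_window: tuple[float, float] = NIR_WINDOW
    normalization_mode: str = "cell_density"
    dunn_adjust: str = "bonferroni"
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.par_window, self.nir_window):
            if not (400.0 <= lo < hi <= 1300.0):
                raise ValueError("analysis windows must lie within 400-1300 nm")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("par_window", "nir_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def sample_metrics(
    spectrum: Spectrum,
    clean_ref: Spectrum,
    ed,
    biology: SampleBiology | None,
    par_window=PAR_WINDOW,
    nir_window=NIR_WINDOW,
) -> dict:
    """All per-sample quantities for one bloom (or clean) spectrum."""
    row: dict = {
        "sample_id": spectrum.sample_id,
        "color_group": spectrum.color_group,
        "replicate": spectrum.replicate,
        "par_mean": mean_reflectance(spectrum, *par_window),
        "nir_mean": mean_reflectance(spectrum, *nir_window),
        "full_mean": mean_reflectance(spectrum, par_window[0], nir_window[1]),
    }
    rb = band_reflectances(spectrum, SENTINEL2A_BANDS)
    row.update({"rb3": rb["B3"], "rb4": rb["B4"], "rb5": rb["B5"]})
    row["ib4"] = band_depth_ib4(rb["B3"], rb["B4"], rb["B5"])

    if spectrum.color_group != "clean":
        density = biovolume = None
        if biology is not None and biology.cell_populations:
            density = total_density(biology.cell_populations)
            biovolume = total_biovolume(biology.cell_populations)
            row["density_cells_ml"] = density
            row["biovolume_um3_ml"] = biovolume
        irf = irf_for_sample(clean_ref, spectrum, ed,
                             cell_density=density, biovolume=biovolume)
        row.update({
            "irf_full_w_m2": irf.irf_full_w_m2,
            "irf_par_w_m2": irf.irf_par_w_m2,
            "irf_nir_w_m2": irf.irf_nir_w_m2,
            "irf_per_kilocell": irf.irf_per_kilocell,
            "irf_per_biovolume": irf.irf_per_biovolume,
        })
        if biology is not None and not biology.pigments.missing:
            pig = biology.pigments
            sig = pigment_signature(pig)
            row.update({f"pct_{k}": v for k, v in sig.items()})
            if pig.chla > 0:
                row["astax_chla_ratio"] = astax_chla_ratio(pig)
            if density:
                row["chla_per_cell_ug"] = pigment_per_cell(pig, density)["chla"]
            if biovolume:
                row["chla_per_biovolume_ug_um3"] = (
                    pigment_per_biovolume(pig, biovolume)["chla"]
                )
    return row


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns and writes the result tables.

    Outputs (also written as CSV under ``config.outdir``):

    - ``per_sample``: one row per bloom/clean spectrum with all metrics
    - ``group_summary``: mean/SD per color group, plus percent reflectance
      reduction of each bloom color relative to the clean reference
    - ``stats``: Kruskal-Wallis + Dunn comparisons across bloom colors
    - ``dominant_taxa`` (when a taxon table is configured)
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(Path(config.base_dir) / config.manifest)
    spectra = load_spectra(manifest, config.base_dir)
    logger.info("loaded %d spectra from manifest", len(spectra))
    ed = read_irradiance(Path(config.base_dir) / config.irradiance)
    biology = {b.sample_id: b
               for b in read_biology_table(Path(config.base_dir) / config.biology)}

    bloom_ids = {s.sample_id for s in spectra if s.color_group != "clean"}
    orphans = sorted(bloom_ids - set(biology))
    if orphans:
        raise ValueError(f"bloom spectra without biology rows: {orphans}")

    cleans = [s for s in spectra if s.color_group == "clean"]
    if not cleans:
        raise ValueError("no clean-snow spectra in manifest: cannot build reference")
    clean_ref = mean_clean_spectrum(cleans)
    logger.info("clean reference from %d spectra", len(cleans))

    rows = [
        sample_metrics(s, clean_ref, ed, biology.get(s.sample_id),
                       config.par_window, config.nir_window)
        for s in spectra
    ]
    per_sample = pd.DataFrame(rows)

    numeric = per_sample.select_dtypes("number").columns.drop("replicate")
    grouped = per_sample.groupby("color_group")[list(numeric)]
    group_summary = grouped.agg(["mean", "std"])
    group_summary.columns = [f"{a}_{b}" for a, b in group_summary.columns]
    group_summary = group_summary.reset_index()

    clean_row = group_summary.set_index("color_group")
    for window in ("par_mean", "nir_mean", "full_mean"):
        r_clean = float(clean_row.loc["clean", f"{window}_mean"])
        group_summary[f"{window}_reduction_pct"] = [
            percent_reduction(r_clean, float(clean_row.loc[g, f"{window}_mean"]))
            if g != "clean" else 0.0
            for g in group_summary.color_group
        ]

    blooms = per_sample[per_sample.color_group != "clean"]
    stats_rows = []
    for var in STATS_VARIABLES:
        if var not in blooms.columns:
            continue
        groups = {g: sub[var].dropna().to_numpy()
                  for g, sub in blooms.groupby("color_group")}
        groups = {g: v for g, v in groups.items() if v.size > 0}
        if len(groups) < 2:
            continue
        comp = compare_groups(groups, adjust=config.dunn_adjust)
        for _, pair in comp.pairwise.iterrows():
            stats_rows.append({
                "variable": var,
                "h_statistic": comp.h_statistic,
                "kw_p": comp.p_value,
                "group_a": pair.group_a,
                "group_b": pair.group_b,
                "z": pair.z,
                "p_adjusted": pair.p_adjusted,
                "stars": significance_stars(pair.p_adjusted),
            })
    stats = pd.DataFrame(stats_rows)

    results = {"per_sample": per_sample, "group_summary": group_summary,
               "stats": stats}

    if config.taxa:
        taxa = pd.read_csv(Path(config.base_dir) / config.taxa)
        results["dominant_taxa"] = summarize_dominant_taxon(taxa)

    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    run_manifest = {
        "config_hash": config.config_hash(),
        "snowbloom_version": _version(),
        "n_spectra": len(spectra),
        "n_clean": len(cleans),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return results


def _version() -> str:
    from . import __version__
    return __version__


NEAR_TIE_DELTA = 0.05


def summarize_dominant_taxon(taxa: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dominant taxon by relative abundance, flagging near-ties.

    A runner-up within ``NEAR_TIE_DELTA`` of the leader is reported alongside
    it (communities where two taxa share dominance, as in orange blooms).
    """
    required = {"sample_id", "taxon", "relative_abundance"}
    if taxa.empty or not required <= set(taxa.columns):
        raise ValueError(f"taxon table needs columns {sorted(required)}")
    rows = []
    for sid, sub in taxa.groupby("sample_id"):
        sub = sub.sort_values("relative_abundance", ascending=False)
        top = sub.iloc[0]
        near_tie = (
            len(sub) > 1
            and top.relative_abundance - sub.iloc[1].relative_abundance
            < NEAR_TIE_DELTA
        )
        rows.append({
            "sample_id": sid,
            "dominant_taxon": top.taxon,
            "abundance": float(top.relative_abundance),
            "near_tie": bool(near_tie),
            "runner_up": sub.iloc[1].taxon if near_tie else None,
            "runner_up_abundance": (
                float(sub.iloc[1].relative_abundance) if near_tie else None
            ),
        })
    return pd.DataFrame(rows)
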