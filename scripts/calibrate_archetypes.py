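#!/usr/bin/env python
"""One-off calibration of archetype optical constants.

Solves, per bloom archetype, the packaging scale (and for red the chlorophyll
masking factor) and NIR optical-depth offset so that the archetype's mean
spectrum reproduces the published field group means:

    PAR/NIR HDRF  — red 0.11/0.12, orange 0.15/0.19, green 0.19/0.16,
                    against clean snow 0.25/0.16
    band-depth index (fractional) — red 0.0242, orange 0.2264, green 0.1926

Run from the repository root; paste the printed constants into the
_CALIBRATED table in src/snowbloom/synthetic_data.py.  This is deterministic
(no randomness) and only needs re-running if the pigment kernels or the
clean baseline change.
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from snowbloom.synthetic_data import (  # noqa: E402
    GREEN_ARCHETYPE,
    ORANGE_ARCHETYPE,
    RED_ARCHETYPE,
    calibrate_archetype_optics,
)

CLEAN_PAR, CLEAN_NIR = 0.25, 0.16
TARGETS = {
    # name: (par_mean, nir_mean, ib4_target)
    "red": (0.11, 0.12, 0.0242),
    "orange": (0.15, 0.19, 0.2264),
    "green": (0.19, 0.16, 0.1926),
}
ARCHETYPES = {a.name: a for a in (RED_ARCHETYPE, ORANGE_ARCHETYPE, GREEN_ARCHETYPE)}


def main() -> None:
    # Orange and green first: their packaging scales are free and define the
    # shared cell-optics value.  Red's Gaussian kernel scale is fixed to the
    # orange/green mean; its extra visible darkening is carried by the flat
    # cyst gray term instead (which cancels in the band-depth ratio).
    results = {}
    for name in ("orange", "green"):
        par, nir, ib4 = TARGETS[name]
        results[name] = calibrate_archetype_optics(
            ARCHETYPES[name].pigment_means,
            par_ratio=par / CLEAN_PAR,
            nir_ratio=nir / CLEAN_NIR,
            ib4_target=ib4,
        )
    shared_scale = (results["orange"][0] + results["green"][0]) / 2.0
    par, nir, ib4 = TARGETS["red"]
    results["red"] = calibrate_archetype_optics(
        ARCHETYPES["red"].pigment_means,
        par_ratio=par / CLEAN_PAR,
        nir_ratio=nir / CLEAN_NIR,
        ib4_target=ib4,
        fixed_packaging_scale=shared_scale,
    )
    print("_CALIBRATED = {")
    print("    #        packaging  chl_masking  nir_tau   cyst_gray_od")
    for name in ("red", "orange", "green"):
        scale, masking, tau, gray = results[name]
        print(f'    "{name}": ({scale:.4f}, {masking:.4f}, {tau:.4f}, {gray:.4f}),')
    print("}")


if __name__ == "__main__":
    main()
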