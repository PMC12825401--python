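"""Shared fixtures: a small deterministic synthetic study on disk."""

from __future__ import annotations

import numpy as np
import pytest

from snowbloom.spectra_io import Spectrum, analysis_grid
from snowbloom.synthetic_data import DEFAULT_ARCHETYPES, synth_sample_set


@pytest.fixture(scope="session")
def grid():
    return analysis_grid()


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A complete on-disk synthetic study: 3 colors x 3 samples + 3 clean."""
    outdir = tmp_path_factory.mktemp("study")
    synth_sample_set(outdir, DEFAULT_ARCHETYPES, n_per_group=3, n_clean=3, seed=42)
    return outdir


@pytest.fixture()
def flat_spectrum(grid):
    def make(level: float = 0.5, **kwargs) -> Spectrum:
        return Spectrum(grid, np.full(grid.size, level), **kwargs)

    return make
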