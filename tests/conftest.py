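"""Shared fixtures: small genomes, planted loci, simulated track pairs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from termscan import CoverageTrack
from termscan import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def compact_layout():
    """Scaled study layout: 20 non-pA + 5 mRNA loci on 5 x 60 kb."""
    loci, chrom_lengths = sd.compact_loci()
    return loci, chrom_lengths


@pytest.fixture(scope="session")
def nrd1_model():
    return sd.OccupancyModel.for_factor("Nrd1")


@pytest.fixture(scope="session")
def nrd1_tracks(compact_layout, nrd1_model):
    """One control/depleted track pair under Nrd1-like depletion."""
    loci, chrom_lengths = compact_layout
    control = sd.simulate_occupancy(loci, nrd1_model, "control", "Nrd1", chrom_lengths, seed=101)
    treated = sd.simulate_occupancy(loci, nrd1_model, "depleted", "Nrd1", chrom_lengths, seed=202)
    return control, treated


@pytest.fixture()
def toy_track():
    """Factory for small single-chromosome tracks with given values."""

    def make(plus=None, minus=None, length=None, chrom="chrT"):
        arrays = {}
        if plus is not None:
            arrays["+"] = np.asarray(plus, dtype=float)
        if minus is not None:
            arrays["-"] = np.asarray(minus, dtype=float)
        if length is None:
            length = max(len(a) for a in arrays.values())
        track = CoverageTrack({chrom: length})
        for strand, values in arrays.items():
            full = np.zeros(length)
            full[: len(values)] = values
            track.set_values(chrom, strand, full)
        return track

    return make
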