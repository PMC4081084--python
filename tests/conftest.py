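"""Shared fixtures: small synthetic bundles generated at test time."""

from __future__ import annotations

import pytest

from peakscape import SimConfig, simulate, write_simulation


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulation exercising every artifact (400 peaks, 80 genes)."""
    cfg = SimConfig(seed=11, n_peaks=400, n_genes=80, n_chrom=2,
                    chrom_length=800_000)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_sim_paths(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return write_simulation(small_sim, outdir)
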