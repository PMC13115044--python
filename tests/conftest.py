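"""Shared fixtures: one small noiseless synthetic screen reused across
modules, plus a handful of cheap helpers."""

from __future__ import annotations

import pytest

from coldscreen.simulate import SimConfig, SimOutput, simulate_screen


def small_config(**overrides) -> SimConfig:
    """A small but complete screen: 2 chromosomes, 20 genes, 120 mutants."""
    kwargs = dict(
        seed=7,
        n_chrom=2,
        chrom_len=60_000,
        n_genes=20,
        n_mutants=120,
        depth_per_sample=30_000,
        subst_error_rate=0.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory) -> SimOutput:
    """Full noiseless synthetic screen written to disk once per session."""
    outdir = tmp_path_factory.mktemp("noiseless_sim")
    return simulate_screen(small_config(), outdir)


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory) -> SimOutput:
    """Same screen with substitution sequencing noise."""
    outdir = tmp_path_factory.mktemp("noisy_sim")
    return simulate_screen(small_config(seed=8, subst_error_rate=0.002), outdir)
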