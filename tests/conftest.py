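"""Shared fixtures: programmatic haplotype matrices and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepdriver.popio import HaplotypeMatrix


def make_matrix(
    entries,
    positions=None,
    population: str = "popA",
    chrom: str = "1",
    polarized: bool = True,
) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from a 0/1 array and optional positions."""
    entries = np.asarray(entries, dtype=np.uint8)
    n_hap, n_sites = entries.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    positions = np.asarray(positions, dtype=np.int64)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "ancestral": "A",
            "derived": "C",
        }
    )
    return HaplotypeMatrix(
        entries=entries,
        sites=sites,
        sample_ids=[f"s{i}" for i in range(n_hap // 2)],
        population=population,
        polarized=polarized,
    )


def random_matrix(
    rng: np.random.Generator,
    n_hap: int = 30,
    n_sites: int = 50,
    span: int = 100_000,
    population: str = "popA",
) -> HaplotypeMatrix:
    entries = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    positions = np.sort(rng.choice(np.arange(1, span), n_sites, replace=False))
    return make_matrix(entries, positions, population=population)


@pytest.fixture(scope="session")
def small_sim():
    """A cheap neutral two-deme simulation shared across tests."""
    from sweepdriver import synthpop

    cfg = synthpop.SimConfig(
        n_demes=2,
        deme_size=100,
        split_generations=(80,),
        migration_rate=1e-3,
        seq_length=50_000,
        mu=5e-7,
        rec_rate=2e-6,
        sample_sizes=40,
        seed=11,
    )
    return synthpop.simulate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
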