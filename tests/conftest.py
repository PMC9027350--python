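"""Shared fixtures: random datasets and a small discovery/cohort bundle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from leopanel import simulate as sim
from leopanel.datamodel import NUCLEOTIDES, SiteRecord, VariantDataset


def random_dataset(
    rng: np.random.Generator,
    n_sites: int = 50,
    n_samples: int = 10,
    missing_rate: float = 0.1,
    max_depth: int = 12,
) -> VariantDataset:
    """A random but valid VariantDataset for oracle-style tests."""
    sites = []
    for i in range(n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SiteRecord(f"sc{i // 5}", 100 + (i % 5) * 200, NUCLEOTIDES[ref], NUCLEOTIDES[alt])
        )
    genotypes = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    missing = rng.random((n_sites, n_samples)) < missing_rate
    genotypes[missing] = -1
    depths = rng.integers(0, max_depth + 1, size=(n_sites, n_samples)).astype(np.int32)
    samples = [f"s{j}" for j in range(n_samples)]
    return VariantDataset(sites=sites, samples=samples, genotypes=genotypes, depths=depths)


@pytest.fixture(scope="session")
def discovery_bundle(tmp_path_factory):
    """A small on-disk discovery bundle (seed 11, 1500 sites)."""
    out = tmp_path_factory.mktemp("discovery")
    config = sim.discovery_config(seed=11, n_sites=1500)
    paths = sim.generate_dataset(config, sim.MtDNAModel(), out, force=True)
    return {"config": config, "paths": paths}


@pytest.fixture(scope="session")
def discovery_pieces():
    """In-memory discovery simulation products (seed 11, 1500 sites)."""
    config = sim.discovery_config(seed=11, n_sites=1500)
    freqs = sim.simulate_allele_frequencies(config)
    truth = sim.simulate_genotypes(freqs, config)
    observed = sim.simulate_coverage_and_calls(truth, config)
    flanks = sim.simulate_flanks(observed, config)
    return {
        "config": config,
        "freqs": freqs,
        "truth": truth,
        "observed": observed,
        "flanks": flanks,
    }
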