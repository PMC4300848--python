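"""Shared fixtures: hand-built datasets and a session-scoped simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from divkit.data_model import GenotypeDataset
from divkit.synthetic_data import SimConfig, simulate_dataset


def make_dataset(calls, regions, zones, populations=None, varieties=None,
                 statuses=None, loci=None, ids=None) -> GenotypeDataset:
    """Convenience factory for small hand-built genotype datasets."""
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[0], calls.shape[1]
    ids = ids or [f"I{i + 1:02d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "region": regions,
            "zone": zones,
            "population": populations or [f"P{i + 1:02d}" for i in range(n)],
            "variety": varieties or ["v1"] * n,
            "status": statuses or ["traditional"] * n,
        },
        index=pd.Index(ids, name="id"),
    )
    return GenotypeDataset(meta, loci or [f"L{j + 1}" for j in range(L)], calls)


def random_dataset(rng: np.random.Generator, n: int, n_loci: int,
                   n_groups: int = 2, n_alleles: int = 4,
                   missing_rate: float = 0.0, level: str = "zone") -> GenotypeDataset:
    """Random diploid dataset with individuals spread over groups."""
    calls = rng.integers(1, n_alleles + 1, size=(n, n_loci, 2)).astype(np.int32)
    if missing_rate > 0:
        miss = rng.random((n, n_loci)) < missing_rate
        calls[miss] = 0
    groups = [f"G{k + 1}" for k in rng.integers(0, n_groups, size=n)]
    if level == "zone":
        regions = ["R1"] * n
        zones = groups
    else:
        regions = groups
        zones = [f"{g}Z" for g in groups]
    return make_dataset(calls, regions, zones)


@pytest.fixture(scope="session")
def sim_default():
    """One study-scale simulated dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim_config():
    """A fast, small generator configuration for structural tests."""
    return SimConfig(
        seed=11,
        zones_per_region=(2, 2),
        populations_per_zone=((8, 8), (8, 8)),
        n_loci=8,
        allele_count_range=(5, 12),
        progenies_per_population=10,
        n_bw_populations=0,
        n_bw_excluded=0,
        check_rows=(12, 8),
    )
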