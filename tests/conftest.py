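import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from urbancfd import SimConfig, simulate

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from urbancfd.containers import CommunityMatrix, TraitTable
from urbancfd.traits import prepare_traits


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_species=40, n_nonnative=4, n_fuas=6, cells_per_fua=10, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def prepared_small(small_study):
    table, report = prepare_traits(small_study.traits)
    return table


def random_communities(
    species: list[str],
    n_comm: int,
    rng: np.random.Generator,
    k_min: int = 5,
    k_max: int = 20,
) -> CommunityMatrix:
    """Communities drawn uniformly from the pool (no structure)."""
    pres = np.zeros((n_comm, len(species)), dtype=np.int8)
    for i in range(n_comm):
        k = int(rng.integers(k_min, min(k_max, len(species)) + 1))
        pres[i, rng.choice(len(species), size=k, replace=False)] = 1
    presence = pd.DataFrame(pres, index=[f"c{i:04d}" for i in range(n_comm)], columns=species)
    meta = pd.DataFrame(
        {"fua": ["f0"] * n_comm, "country": ["XX"] * n_comm}, index=presence.index
    )
    return CommunityMatrix(
        presence=presence,
        cell_meta=meta,
        nonnative=pd.Series(False, index=species),
    )


def toy_trait_table(values: pd.DataFrame, meta: pd.DataFrame) -> TraitTable:
    return TraitTable(
        values=values, meta=meta, nonnative=pd.Series(False, index=values.index)
    )
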