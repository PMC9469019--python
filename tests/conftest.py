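import numpy as np
import pytest

import kinflow as kf
from kinflow.data import Individual, PopulationSample, TemporalDataset


def make_population(code, genotypes_per_ind, loci, time_code=1, lat=20.0, lon=110.0):
    """Population from a list of per-individual genotype dicts."""
    inds = [
        Individual(f"{code}_{i:03d}", {l: g.get(l) for l in loci for g in [gts]})
        for i, gts in enumerate(genotypes_per_ind)
    ]
    return PopulationSample(code, code, lat, lon, time_code, "2016-05-01", inds)


@pytest.fixture
def two_pop_dataset():
    """Two populations, two loci, with one missing genotype."""
    loci = ["L1", "L2"]
    pop_a = make_population(
        "AA1",
        [{"L1": (150, 150), "L2": (200, 202)},
         {"L1": (150, 152), "L2": (200, 200)},
         {"L1": (150, 152), "L2": None}],
        loci, time_code=1, lat=25.0, lon=119.0)
    pop_b = make_population(
        "BB1",
        [{"L1": (152, 152), "L2": (202, 202)},
         {"L1": (150, 152), "L2": (200, 202)}],
        loci, time_code=1, lat=22.0, lon=114.0)
    return TemporalDataset(loci, [pop_a, pop_b])


@pytest.fixture(scope="session")
def sim_two_deme():
    """2-deme, fully parent-sampled simulation with 30% migrant parents."""
    cfg = kf.SimConfig(
        n_demes=2, deme_size=100, sample_per_deme=50, n_time_slices=1,
        parent_sampling_fraction=1.0, n_generations=1, seed=42,
        migration_matrix=kf.uniform_migration(2, 0.3))
    dataset, truth = kf.simulate_metapopulation(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def sim_multi_slice():
    """6-deme, 4-slice simulation used by pipeline-level tests."""
    cfg = kf.SimConfig(
        n_demes=6, deme_size=40, sample_per_deme=14, n_time_slices=4,
        parent_sampling_fraction=0.5, seed=11, error_rate=0.001,
        missing_rate=0.01, migration_matrix=kf.uniform_migration(6, 0.3))
    dataset, truth = kf.simulate_metapopulation(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160512)
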