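import numpy as np
import pandas as pd
import pytest

from haplomerge import simcore
from haplomerge.types import CohortDataset, PopulationModel


@pytest.fixture(scope="session")
def small_panel():
    """A 400-site, 1200-haplotype panel with two populations and LD."""
    model = PopulationModel(n_pops=2, fst=[0.0, 0.1], pop_weights=[0.85, 0.15])
    return simcore.simulate_panel(model, n_sites=400, n_haplotypes=1200,
                                  map_length_cm=60.0, mutation_rate=3e-4,
                                  n_generations=10, seed=7, n_founders=48)


@pytest.fixture(scope="session")
def small_designs(small_panel):
    return simcore.make_array_designs(small_panel, 160, 280, 80, seed=3)


@pytest.fixture()
def small_cohort(small_panel, small_designs):
    design_a, _ = small_designs
    return simcore.genotype_cohort(small_panel, design_a, n_samples=80,
                                   pop_mix={"pop0": 1.0}, n_waves=2,
                                   per_wave_missing_rate=0.02, error_rate=0.0,
                                   seed=11, name="cohA")


def make_cohort(genotypes, site_indices=None, waves=None, cases=None, pops=None):
    """Hand-build a CohortDataset around a genotype matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, s = genotypes.shape
    samples = pd.DataFrame({
        "id": [f"s{i:03d}" for i in range(n)],
        "wave": waves if waves is not None else np.zeros(n, dtype=int),
        "case": cases if cases is not None else np.zeros(n, dtype=bool),
        "pop_label": pops if pops is not None else ["pop0"] * n,
        "age": 30,
        "sex": 0,
    })
    sites = np.arange(s) if site_indices is None else np.asarray(site_indices)
    return CohortDataset(genotypes=genotypes, site_indices=sites, samples=samples)
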