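import numpy as np
import pytest

from eigenblup import popsim
from eigenblup.grm import GenotypeMatrix, GRMBundle, build_grm


def tiny_scenario(**overrides) -> popsim.SimScenario:
    """A fast micro-scenario (~0.3 s) with the full two-phase structure."""
    params = dict(
        n_hist_generations=30,
        hist_size_start=80,
        hist_size_bottleneck=30,
        hist_size_end=160,
        n_recent_generations=10,
        n_dams_per_gen=40,
        n_sires_per_gen=5,
        n_genotyped=240,
        n_chromosomes=5,
        chrom_length_cM=100.0,
        n_snp=400,
        n_qtl=100,
        heritability=0.5,
        seed=1234,
    )
    params.update(overrides)
    return popsim.SimScenario(**params)


@pytest.fixture(scope="session")
def tiny_sim() -> popsim.SimOutput:
    return popsim.simulate(tiny_scenario())


@pytest.fixture(scope="session")
def tiny_genome():
    sc = tiny_scenario()
    rng = np.random.default_rng(7)
    return popsim.build_genome(sc, rng)


@pytest.fixture()
def toy_genotypes() -> GenotypeMatrix:
    """4 animals x 3 polymorphic markers, hand-enterable."""
    values = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [1, 2, 1],
        ]
    )
    return GenotypeMatrix(
        values=values,
        animal_ids=np.array(["a", "b", "c", "d"]),
        marker_ids=np.array(["m1", "m2", "m3"]),
    )


def random_grm(n: int, m: int, seed: int) -> GRMBundle:
    """A small dense GRM from random genotypes (all polymorphic)."""
    rng = np.random.default_rng(seed)
    while True:
        values = rng.integers(0, 3, size=(n, m))
        p = values.mean(axis=0) / 2.0
        if np.all((p > 0) & (p < 1)):
            break
    geno = GenotypeMatrix(values, np.arange(n), np.arange(m))
    return build_grm(geno)


@pytest.fixture()
def grm5() -> GRMBundle:
    return random_grm(5, 20, seed=42)
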