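"""Shared fixtures: small demographies, maps, and simulated datasets."""

import numpy as np
import pytest

from argdemog.coalsim import drop_mutations, simulate_arg
from argdemog.scenarios import (Demography, Population, SizeSegment,
                                build_demography, make_uniform_map)

MU = 4.6e-9


def constant_demography(n: float = 10_000.0) -> Demography:
    """Single population of constant diploid size (split pushed far back)."""
    return Demography(
        populations=(Population("pop1", (SizeSegment(0.0, 1e9, n, n),)),),
        split_time=1e9,
        ancestral_size=n,
        mutation_rate=MU,
    )


@pytest.fixture(scope="session")
def const_demog():
    return constant_demography()


@pytest.fixture(scope="session")
def model3():
    return build_demography(3)


@pytest.fixture(scope="session")
def small_map():
    return make_uniform_map(MU, 0.1, chrom_length=1e6)


@pytest.fixture(scope="session")
def small_sim(const_demog, small_map):
    """One 1 Mb chromosome, 4 haplotypes, constant N=10,000."""
    ts = simulate_arg(const_demog, small_map, {"pop1": 4}, seed=1234)
    vt = drop_mutations(ts, MU, seed=4321)
    return ts, vt


@pytest.fixture(scope="session")
def model3_sim(model3, small_map):
    """1 Mb chromosome under demography model 3, 4 diploids in pop1+pop2."""
    ts = simulate_arg(model3, small_map, {"pop1": 8, "pop2": 8}, seed=99)
    vt = drop_mutations(ts, MU, seed=98)
    return ts, vt
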