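import datetime as dt

import numpy as np
import pytest

from kinbond.core_io import Individual, PedigreeTable
from kinbond.synthdata import SimConfig, simulate_group


def ind(id, mother=None, father=None, year=2000, sex="female"):
    """Shorthand Individual builder for pedigree fixtures."""
    return Individual(
        id, mother_id=mother, father_id=father,
        birth_date=dt.date(year, 6, 15), sex=sex,
    )


def pedigree(*individuals):
    return PedigreeTable(individuals)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study group, shared across tests."""
    return simulate_group(SimConfig(seed=11))


def random_pedigree(rng, n_founder_f=3, n_founder_m=3, n_offspring=8):
    """Random non-inbred pedigree (resampled until no parents are related).

    Offspring pick a random earlier female as mother and a random earlier
    (or fresh founder) male as father; used to cross-check path counting
    against the tabular additive-relationship recursion.
    """
    from kinbond.pedigree import is_inbred

    for _ in range(50):
        individuals = []
        females, males = [], []
        for i in range(n_founder_f):
            individuals.append(ind(f"f{i}", year=1990))
            females.append(f"f{i}")
        for i in range(n_founder_m):
            individuals.append(ind(f"m{i}", year=1990, sex="male"))
            males.append(f"m{i}")
        for k in range(n_offspring):
            mother = females[rng.integers(len(females))]
            if rng.random() < 0.4:
                father = f"m_extra{k}"
                individuals.append(ind(father, year=1990, sex="male"))
            else:
                father = males[rng.integers(len(males))]
            sex = "female" if rng.random() < 0.7 else "male"
            child = f"c{k}"
            individuals.append(ind(child, mother=mother, father=father,
                                   year=1995 + k, sex=sex))
            (females if sex == "female" else males).append(child)
        ped = PedigreeTable(individuals)
        if not is_inbred(ped):
            return ped
    raise RuntimeError("could not generate a non-inbred pedigree")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
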