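import numpy as np
import pytest

from pedrecon.genome import default_genome, uniform_genome
from pedrecon.pedigree import FEMALE, MALE, Individual, Pedigree


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Four 100-Mbp chromosomes; fast drops, same 1 cM/Mbp map."""
    return uniform_genome(4, 100.0)


def make_pedigree(rows):
    """rows: (id, sex, generation, father, mother); extant iff generation 0."""
    P = Pedigree()
    for iid, sex, gen, fa, mo in rows:
        P.add(Individual(iid, sex=sex, generation=gen, father_id=fa,
                         mother_id=mo, extant=(gen == 0)))
    return P


@pytest.fixture
def cousin_pedigree():
    """Three generations: two couples of full-sib parents -> first cousins.

    g2: grandparent couple (GF, GM) plus unrelated spouses; g1: sibs A, B
    married to S1, S2; g0: cousins c1, c2 plus sib pair c1, c1b.
    """
    return make_pedigree([
        ("GF", MALE, 2, None, None),
        ("GM", FEMALE, 2, None, None),
        ("A", MALE, 1, "GF", "GM"),
        ("B", FEMALE, 1, "GF", "GM"),
        ("S1", FEMALE, 1, None, None),
        ("S2", MALE, 1, None, None),
        ("c1", MALE, 0, "A", "S1"),
        ("c1b", FEMALE, 0, "A", "S1"),
        ("c2", MALE, 0, "S2", "B"),
        ("U", MALE, 0, None, None),
    ])


@pytest.fixture
def halfsib_pedigree():
    """One father F with two mates -> extant half sibs h1, h2; plus full sibs."""
    return make_pedigree([
        ("F", MALE, 1, None, None),
        ("M1", FEMALE, 1, None, None),
        ("M2", FEMALE, 1, None, None),
        ("h1", MALE, 0, "F", "M1"),
        ("h1b", FEMALE, 0, "F", "M1"),
        ("h2", MALE, 0, "F", "M2"),
    ])
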