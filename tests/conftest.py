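"""Shared fixtures: ideal peptides and the synthetic motif stand-ins."""

import numpy as np
import pytest

from ramastrain import build_peptide
from ramastrain.standins import g52a_standin, parent_standin
from ramastrain.synthetic import GeometryTable


def make_helix(n=15, seq=None):
    """Ideal α-helix at (−57, −47)."""
    seq = seq or "A" * n
    plan = [(None, -47.0)] + [(-57.0, -47.0)] * (n - 2) + [(-57.0, None)]
    return build_peptide(seq, plan)


@pytest.fixture(scope="session")
def geometry():
    return GeometryTable.default()


@pytest.fixture(scope="session")
def helix15():
    return make_helix(15)


@pytest.fixture(scope="session")
def eps_tripeptide():
    """Ala tripeptide with the middle residue at the ε conformation
    (117.3, −170.9) reported for the mutant's position 52."""
    return build_peptide("AAA", [(None, -47.0), (117.3, -170.9), (-57.0, None)])


@pytest.fixture(scope="session")
def mutant_standin():
    return g52a_standin()


@pytest.fixture(scope="session")
def parent_standin_model():
    return parent_standin()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
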