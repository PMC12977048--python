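import warnings

import pytest

from rxnforge import FixtureSpec, generate_dataset, parse_reaction_smiles

SN2 = "[CH3:1][Br:2].[OH-:3]>>[CH3:1][OH:3].[Br-:2]"
IDENTITY = "[CH4:1]>>[CH4:1]"


@pytest.fixture
def sn2():
    return parse_reaction_smiles(SN2)


@pytest.fixture
def identity_rxn():
    return parse_reaction_smiles(IDENTITY)


@pytest.fixture(scope="session")
def small_table():
    """40 synthetic reactions with noise and rings (session-wide, seeded)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _ = generate_dataset(FixtureSpec(n=40, seed=11))
    return table


@pytest.fixture(scope="session")
def geom_table():
    """30 synthetic reactions with toy geometries."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, geoms = generate_dataset(FixtureSpec(n=30, seed=5, geometry=True))
    return table, geoms
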