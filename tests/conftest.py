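import numpy as np
import pytest

from macroring import (
    choose_break_plan,
    generate_conformer,
    merge_nonpolar_hydrogens,
    open_rings,
    perceive_rings,
    read_molecule,
)


def prepared(smiles: str, seed: int = 1, name: str = "") -> "Molecule":
    """SMILES -> merged, embedded molecule (shared test helper)."""
    mol = merge_nonpolar_hydrogens(read_molecule(smiles, name=name))
    return generate_conformer(mol, seed=seed)


def opened(smiles: str, seed: int = 1, name: str = ""):
    """SMILES -> (reference molecule, opened molecule with glue pairs)."""
    mol = prepared(smiles, seed=seed, name=name)
    rings = perceive_rings(mol)
    plan = choose_break_plan(mol, rings)
    return mol, open_rings(mol, plan)


# function-scoped: several tests mutate coordinates in place
@pytest.fixture()
def cyclononane():
    return prepared("C1CCCCCCCC1", name="cyclononane")


@pytest.fixture()
def opened_cyclononane():
    return opened("C1CCCCCCCC1", name="cyclononane")
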