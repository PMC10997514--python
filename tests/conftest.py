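"""Shared fixtures: small deterministic models and reflection sets."""

import numpy as np
import pandas as pd
import pytest

from flashmap.core import AtomicModel, ReflectionSet, UnitCell


@pytest.fixture
def cubic_cell():
    return UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)


@pytest.fixture
def triclinic_cell():
    return UnitCell(10.0, 12.0, 14.0, 80.0, 95.0, 100.0)


def build_model(cell, atoms):
    """atoms: list of (element, name, resname, resnum, chain, x, y, z, occ, b)."""
    cols = ["element", "name", "resname", "resnum", "chain", "x", "y", "z", "occ", "b"]
    return AtomicModel(cell=cell, atoms=pd.DataFrame(atoms, columns=cols))


@pytest.fixture
def two_atom_model(cubic_cell):
    return build_model(
        cubic_cell,
        [
            ("C", "C1", "GLY", 1, "A", 0.0, 0.0, 0.0, 1.0, 15.0),
            ("O", "O1", "GLY", 2, "A", 3.0, 4.0, 0.0, 1.0, 20.0),
        ],
    )


@pytest.fixture
def random_model(cubic_cell):
    rng = np.random.default_rng(11)
    rows = []
    elements = ["C", "N", "O", "S", "C", "C", "N", "O", "C", "P"]
    for i, el in enumerate(elements):
        x, y, z = rng.uniform(0, 10, 3)
        rows.append((el, f"{el}{i}", "RES", i // 2 + 1, "A", x, y, z, 1.0, rng.uniform(5, 30)))
    return build_model(cubic_cell, rows)


@pytest.fixture
def random_reflections(cubic_cell):
    rng = np.random.default_rng(5)
    hkl = []
    for h in range(0, 4):
        for k in range(-3, 4):
            for l in range(-3, 4):
                if (h, k, l) != (0, 0, 0) and (h > 0 or (h == 0 and (k > 0 or (k == 0 and l > 0)))):
                    hkl.append((h, k, l))
    hkl = np.array(hkl[:50])
    return ReflectionSet(
        cell=cubic_cell,
        hkl=hkl,
        amplitude=rng.uniform(1, 20, len(hkl)),
        sigma=rng.uniform(0.1, 1.0, len(hkl)),
        phase=rng.uniform(-180, 180, len(hkl)),
    )
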