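import numpy as np
import pytest

from mbasm import make_fixture
from mbasm.surface import featurize_surface, map_surface, select_representative_points


@pytest.fixture
def glycine():
    return make_fixture("glycine_like")


@pytest.fixture
def methacrylic():
    return make_fixture("methacrylic_like")


@pytest.fixture
def species_order(glycine, methacrylic):
    return tuple(sorted(set(glycine.symbols) | set(methacrylic.symbols)))


def surface_reps(mol, species, k=4, seed=0, points_per_atom=64):
    """Map, featurize and cluster one molecule's surface (small budget)."""
    pts = map_surface(mol, points_per_atom)
    featurize_surface(pts, mol, species)
    return select_representative_points(pts, min(k, len(pts)), seed)


@pytest.fixture
def rep_pair(glycine, methacrylic, species_order):
    return (
        surface_reps(glycine, species_order, k=3, seed=1),
        surface_reps(methacrylic, species_order, k=3, seed=2),
    )


def random_molecule(rng, n=6, element="C", box=8.0):
    from mbasm.molecule import Molecule, VdwRadiusTable

    table = VdwRadiusTable.default()
    coords = (rng.random((n, 3)) - 0.5) * box
    return Molecule.from_symbols_coords([element] * n, coords, name="rand", radius_table=table)
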