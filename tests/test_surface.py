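"""Surface sampling, chemical-environment featurization and medoid selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist, pdist

from mbasm import make_fixture
from mbasm.molecule import Molecule
from mbasm.surface import (
    ENV_DECAY_DENOMINATOR,
    OCCLUSION_TOL,
    SurfacePoint,
    deserno_sphere_points,
    featurize_point,
    featurize_surface,
    map_surface,
    select_representative_points,
)


def brute_force_keep(points, parent, molecule, scale=1.0):
    """Independent occlusion rule: keep p iff min_j (|p - c_j| - r_j) >= -tol."""
    keep = []
    for p in points:
        ok = True
        for j in range(molecule.n_atoms):
            if j == parent:
                continue
            if np.linalg.norm(p - molecule.coords[j]) < scale * molecule.radii[j] - OCCLUSION_TOL:
                ok = False
                break
        keep.append(ok)
    return np.array(keep)


class TestDesernoPoints:
    def test_all_points_on_sphere(self):
        pts = deserno_sphere_points(200, 1.0, (0, 0, 0))
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_deterministic(self):
        a = deserno_sphere_points(333, 2.0, (1, 2, 3))
        b = deserno_sphere_points(333, 2.0, (1, 2, 3))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("n_target", [50, 200, 500, 1000])
    def test_count_within_15_percent(self, n_target):
        pts = deserno_sphere_points(n_target, 1.0)
        assert abs(len(pts) - n_target) <= 0.15 * n_target

    def test_uniformity_nearest_neighbor_spacing(self):
        # Equal-area lattice: NN spacings stay within [0.5, 2]x the ideal cell size.
        pts = deserno_sphere_points(500, 1.0)
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        ideal = np.sqrt(4 * np.pi / 500)
        assert nn.min() >= 0.5 * ideal
        assert nn.max() <= 2.0 * ideal

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            deserno_sphere_points(0, 1.0)
        with pytest.raises(ValueError):
            deserno_sphere_points(10, -1.0)

    @settings(max_examples=25, derandomize=True)
    @given(radius=st.floats(0.3, 5.0), n=st.integers(10, 400))
    def test_sphere_membership_property(self, radius, n):
        center = np.array([0.5, -1.0, 2.0])
        pts = deserno_sphere_points(n, radius, center)
        assert np.allclose(np.linalg.norm(pts - center, axis=1), radius, atol=1e-10)


class TestMapSurface:
    def test_isolated_atom_keeps_all_points(self):
        mol = make_fixture("single_atom", {"element": "C"})
        pts = map_surface(mol, 100)
        assert abs(len(pts) - 100) <= 15
        assert all(p.parent_atom == 0 for p in pts)

    def test_distant_atoms_no_occlusion(self):
        mol = Molecule.from_symbols_coords(["C", "C"], [[0, 0, 0], [10, 0, 0]])
        per_atom = len(deserno_sphere_points(100, mol.radii[0]))
        pts = map_surface(mol, 100)
        assert len(pts) == 2 * per_atom

    def test_close_atoms_match_brute_force_oracle(self):
        mol = Molecule.from_symbols_coords(["C", "C"], [[0, 0, 0], [1.0, 0, 0]])
        pts = map_surface(mol, 200)
        for i in range(2):
            raw = deserno_sphere_points(200, mol.radii[i], mol.coords[i])
            keep = brute_force_keep(raw, i, mol)
            kept = np.array([p.position for p in pts if p.parent_atom == i])
            assert len(kept) == keep.sum()
            assert np.allclose(kept, raw[keep])

    def test_surface_point_invariants_on_fixture(self):
        mol = make_fixture("glycine_like")
        for p in map_surface(mol, 64):
            r = np.linalg.norm(p.position - mol.coords[p.parent_atom])
            assert abs(r - mol.radii[p.parent_atom]) <= 1e-6
            others = [j for j in range(mol.n_atoms) if j != p.parent_atom]
            d = np.linalg.norm(p.position - mol.coords[others], axis=1)
            assert np.all(d >= mol.radii[others] - 1e-6)

    def test_shrinking_radius_scale_never_decreases_retained_fraction(self):
        mol = Molecule.from_symbols_coords(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        fractions = []
        for scale in (1.0, 0.8, 0.6, 0.4):
            pts = map_surface(mol, 128, radius_scale=scale)
            per_atom = len(deserno_sphere_points(128, 1.0))
            fractions.append(len(pts) / (2 * per_atom))
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))

    def test_bad_budget_rejected(self):
        mol = make_fixture("single_atom")
        with pytest.raises(ValueError):
            map_surface(mol, 0)


class TestFeaturization:
    def test_degenerate_point_on_lone_atom(self):
        mol = make_fixture("single_atom", {"element": "C"})
        p = SurfacePoint(position=[0, 0, 0], parent_atom=0, molecule_id=mol.id)
        vec = featurize_point(p, mol, ("C",))
        assert vec.values[0] == pytest.approx(1.0, abs=1e-15)

    def test_single_term_sums_match_formula(self):
        mol = Molecule.from_symbols_coords(["C", "O"], [[0, 0, 0], [0, 0, 3.0]])
        p = SurfacePoint(position=[0, 0, 1.7], parent_atom=0, molecule_id=mol.id)
        vec = featurize_point(p, mol, ("C", "O"))
        assert vec.values[0] == pytest.approx(np.exp(-1.7**2 / 3), rel=1e-12)
        assert vec.values[1] == pytest.approx(np.exp(-1.3**2 / 3), rel=1e-12)

    def test_matches_double_loop_brute_force_on_glycine(self):
        mol = make_fixture("glycine_like")
        species = mol.species
        pts = map_surface(mol, 16)[:50]
        for p in pts:
            vec = featurize_point(p, mol, species)
            for k, s in enumerate(species):
                expected = 0.0
                for i in range(mol.n_atoms):
                    if mol.symbols[i] == s:
                        d = np.linalg.norm(p.position - mol.coords[i])
                        expected += np.exp(-d * d / ENV_DECAY_DENOMINATOR)
                assert abs(vec.values[k] - expected) <= 1e-12

    def test_missing_species_is_an_error(self):
        mol = make_fixture("glycine_like")
        p = SurfacePoint(position=[5, 5, 5], parent_atom=0, molecule_id=mol.id)
        with pytest.raises(ValueError, match="species"):
            featurize_point(p, mol, ("C", "H"))

    def test_permutation_invariant_within_species(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]])
        a = Molecule.from_symbols_coords(["C", "C", "O"], coords)
        b = Molecule.from_symbols_coords(["C", "C", "O"], coords[[1, 0, 2]])
        p = SurfacePoint(position=[0.3, 0.4, 2.0], parent_atom=0, molecule_id=a.id)
        va = featurize_point(p, a, ("C", "O"))
        p.molecule_id = b.id
        vb = featurize_point(p, b, ("C", "O"))
        assert np.allclose(va.values, vb.values, atol=1e-15)


class TestRepresentativeSelection:
    def _featurized_points(self, seed=0, n=40):
        mol = make_fixture("glycine_like")
        pts = map_surface(mol, 8)[:n]
        featurize_surface(pts, mol, mol.species)
        return pts

    def test_k_equals_n_identity(self):
        pts = self._featurized_points(n=12)
        reps = select_representative_points(pts, len(pts), seed=0)
        assert [r.point for r in reps] == pts
        assert all(r.cluster_size == 1 for r in reps)

    def test_k_equals_one_matches_exhaustive_medoid(self):
        pts = self._featurized_points()
        X = np.vstack([p.feature.values for p in pts])
        mean = X.mean(axis=0)
        expected = int(np.argmin(np.linalg.norm(X - mean, axis=1)))
        reps = select_representative_points(pts, 1, seed=3)
        assert reps[0].point is pts[expected]
        assert reps[0].cluster_size == len(pts)

    def test_two_blobs_give_one_representative_each(self):
        # One C-rich and one O-rich region in feature space.
        pts = []
        for i in range(10):
            p = SurfacePoint(position=np.zeros(3), parent_atom=0, molecule_id="m")
            from mbasm.surface import ChemEnvVector

            p.feature = ChemEnvVector(("C", "O"), [1.0 + 0.01 * i, 0.0])
            pts.append(p)
        for i in range(10):
            p = SurfacePoint(position=np.zeros(3), parent_atom=0, molecule_id="m")
            from mbasm.surface import ChemEnvVector

            p.feature = ChemEnvVector(("C", "O"), [0.0, 1.0 + 0.01 * i])
            pts.append(p)
        reps = select_representative_points(pts, 2, seed=0)
        blobs = {("C" if r.point.feature.values[0] > r.point.feature.values[1] else "O") for r in reps}
        assert blobs == {"C", "O"}

    def test_deterministic_under_seed_and_members_of_input(self):
        pts = self._featurized_points()
        a = select_representative_points(pts, 4, seed=11)
        b = select_representative_points(pts, 4, seed=11)
        assert [id(r.point) for r in a] == [id(r.point) for r in b]
        assert all(r.point in pts for r in a)

    def test_k_too_large_and_unfeaturized_errors(self):
        pts = self._featurized_points(n=5)
        with pytest.raises(ValueError):
            select_representative_points(pts, 6)
        pts[2].feature = None
        with pytest.raises(RuntimeError):
            select_representative_points(pts, 2)
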