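import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intarch.structures import (
    Assembly,
    AssemblyComponent,
    Atom,
    Residue,
    RigidTransform,
    Structure,
    StructureError,
    ca_distance,
    radius_of_gyration,
    read_structure,
    superpose,
    write_structure,
)

from .conftest import ca_structure, random_transform, single_component_assembly

SINGLE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00 10.00           C\n"
    "END\n"
)


class TestReadWrite:
    def test_single_atom_record(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(SINGLE_ATOM_PDB)
        s = read_structure(p)
        assert list(s.chains) == ["A"]
        assert s.n_residues == 1
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.ca_coord("A", 1), [1.0, 2.0, 3.0])

    def test_round_trip_coordinates(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(SINGLE_ATOM_PDB)
        s = read_structure(p)
        out = tmp_path / "out.pdb"
        write_structure(s, out)
        s2 = read_structure(out)
        np.testing.assert_allclose(s2.ca_coord("A", 1), s.ca_coord("A", 1), atol=1e-3)

    def test_ca_distance_on_fixture(self, line_structure, tmp_path):
        out = tmp_path / "line.pdb"
        write_structure(line_structure, out)
        s = read_structure(out)
        assert ca_distance(s, ("A", 1), ("A", 3)) == pytest.approx(7.6, abs=1e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError, match="not found"):
            read_structure(tmp_path / "nope.pdb")

    def test_unknown_format(self, tmp_path):
        p = tmp_path / "x.cif"
        p.write_text("data_x\n")
        with pytest.raises(StructureError, match="format"):
            read_structure(p, format="cif")

    def test_zero_atoms(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_write_empty_structure_errors(self):
        with pytest.raises(StructureError, match="empty"):
            write_structure(Structure("x", {}), "/tmp/should_not_exist.pdb")

    def test_toy_round_trip(self, toy_complex, tmp_path):
        receptor, _, _ = toy_complex
        out = tmp_path / "rec.pdb"
        write_structure(receptor, out)
        again = read_structure(out)
        assert list(again.chains) == list(receptor.chains)
        np.testing.assert_allclose(
            again.ca_coords(), receptor.ca_coords(), atol=1.5e-3
        )

    def test_insertion_codes_and_gaps_roundtrip(self, tmp_path):
        residues = [
            Residue(1, "", "ALA", [Atom("CA", "C", [0.0, 0, 0])]),
            Residue(2, "A", "GLY", [Atom("CA", "C", [3.8, 0, 0])]),
            Residue(2, "B", "GLY", [Atom("CA", "C", [7.6, 0, 0])]),
            Residue(10, "", "SER", [Atom("CA", "C", [11.4, 0, 0])]),
        ]
        s = Structure("ins", {"A": residues})
        out = tmp_path / "ins.pdb"
        write_structure(s, out)
        s2 = read_structure(out)
        assert [(r.number, r.icode) for r in s2.chains["A"]] == [
            (1, ""), (2, "A"), (2, "B"), (10, ""),
        ]

    def test_flatten_remaps_colliding_chains(self, tmp_path):
        a = ca_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], id="a", chain="A")
        b = ca_structure([[20, 0, 0], [23.8, 0, 0], [27.6, 0, 0]], id="b", chain="A")
        asm = Assembly(
            [
                AssemblyComponent("rec", a, RigidTransform.identity(), "receptor"),
                AssemblyComponent("mob", b, RigidTransform.identity(), "mobile"),
            ]
        )
        flat = asm.flatten()
        out = tmp_path / "flat.pdb"
        write_structure(flat, out)
        again = read_structure(out)
        assert sorted(again.chains) == ["A", "B"]  # receptor keeps A, mobile remapped
        np.testing.assert_allclose(again.ca_coord("A", 1), [0, 0, 0], atol=1e-3)
        np.testing.assert_allclose(again.ca_coord("B", 1), [20, 0, 0], atol=1e-3)


class TestCaDistance:
    def test_identity_site(self, line_structure):
        assert ca_distance(line_structure, ("A", 1), ("A", 1)) == 0.0

    def test_3_4_5_triangle(self):
        s = ca_structure([[0, 0, 0], [3, 4, 0]])
        assert ca_distance(s, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_symmetric(self, line_structure):
        assert ca_distance(line_structure, ("A", 1), ("A", 3)) == ca_distance(
            line_structure, ("A", 3), ("A", 1)
        )

    def test_missing_residue_names_site(self, line_structure):
        with pytest.raises(StructureError, match="A:99"):
            ca_distance(line_structure, ("A", 1), ("A", 99))

    def test_invariant_under_rigid_transform(self, toy_complex):
        receptor, mobile, assembly = toy_complex
        rng = np.random.default_rng(5)
        d0 = ca_distance(assembly, ("A", 3), ("B", 7))
        for _ in range(5):
            g = random_transform(rng)
            moved = Assembly(
                [
                    AssemblyComponent(c.label, c.structure, g.compose(c.transform), c.role)
                    for c in assembly.components
                ]
            )
            assert ca_distance(moved, ("A", 3), ("B", 7)) == pytest.approx(d0, abs=1e-6)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(0)
        g = random_transform(rng)
        ident = g.compose(g.inverse())
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-9)

    def test_preserves_pairwise_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 10, (30, 3))
        g = random_transform(rng)
        moved = g.apply(pts)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(moved), pdist(pts), atol=1e-6)

    def test_rejects_improper_rotation(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(StructureError):
            RigidTransform(R, np.zeros(3))

    def test_round_trip_dict(self):
        g = random_transform(np.random.default_rng(2))
        g2 = RigidTransform.from_dict(g.to_dict())
        np.testing.assert_allclose(g2.rotation, g.rotation)
        np.testing.assert_allclose(g2.translation, g.translation)


class TestSuperpose:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(0, 5, (10, 3))
        g, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(g.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_90deg_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 5, (20, 3))
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
        g, rmsd = superpose(pts, pts @ Rz.T)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(g.rotation, Rz, atol=1e-6)

    def test_too_few_points(self):
        with pytest.raises(StructureError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(StructureError, match="collinear"):
            superpose(line, line)

    def test_noise_rmsd_monte_carlo(self):
        # both sets perturbed by isotropic noise of total per-point variance σ²;
        # Kabsch removes 6 of 3n degrees of freedom
        rng = np.random.default_rng(7)
        n, sigma = 100, 0.8
        expected = sigma * np.sqrt(2.0) * np.sqrt(1.0 - 3.0 / n)
        rmsds = []
        base = rng.normal(0, 10, (n, 3))
        for _ in range(100):
            a = base + rng.normal(0, sigma / np.sqrt(3), (n, 3))
            b = base + rng.normal(0, sigma / np.sqrt(3), (n, 3))
            rmsds.append(superpose(a, b)[1])
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.04)

    def test_involution_restores_coordinates(self, toy_complex):
        receptor, _, _ = toy_complex
        pts = receptor.ca_coords()
        rng = np.random.default_rng(9)
        g = random_transform(rng)
        moved = g.apply(pts)
        recovered, rmsd = superpose(moved, pts)
        assert rmsd < 1e-6
        np.testing.assert_allclose(recovered.apply(moved), pts, atol=1e-6)


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_2A_apart(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)

    def test_solid_sphere_closed_form(self):
        rng = np.random.default_rng(42)
        r = 30.0 * rng.random(100_000) ** (1.0 / 3.0)
        direction = rng.normal(size=(100_000, 3))
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        pts = r[:, None] * direction
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.005)

    def test_empty_errors(self):
        with pytest.raises(StructureError):
            radius_of_gyration(np.zeros((0, 3)))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 7, (25, 3))
        g = random_transform(rng)
        assert radius_of_gyration(g.apply(pts)) == pytest.approx(
            radius_of_gyration(pts), abs=1e-6
        )


class TestAssembly:
    def test_duplicate_labels_rejected(self, line_structure):
        with pytest.raises(StructureError):
            Assembly(
                [
                    AssemblyComponent("x", line_structure, RigidTransform.identity()),
                    AssemblyComponent("x", line_structure, RigidTransform.identity()),
                ]
            )

    def test_two_mobiles_rejected(self, line_structure):
        b = ca_structure([[0, 0, 0]], chain="B")
        with pytest.raises(StructureError):
            Assembly(
                [
                    AssemblyComponent("a", line_structure, RigidTransform.identity(), "mobile"),
                    AssemblyComponent("b", b, RigidTransform.identity(), "mobile"),
                ]
            )

    def test_missing_ca_is_hard_error(self):
        res = Residue(1, "", "UNK", [Atom("CB", "C", [0.0, 0, 0])])
        s = Structure("noca", {"A": [res]})
        asm = single_component_assembly(s)
        with pytest.raises(StructureError):
            asm.ca_coord("A", 1)
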