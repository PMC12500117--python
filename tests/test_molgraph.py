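"""Geometry primitives, internal-coordinate extraction, and file I/O."""

import math

import numpy as np
import pytest

from molscale.molgraph import (GeometryReference, MolecularGraph, bond_angle,
                               dihedral, extract_geometry_reference,
                               pairwise_distances, read_structures,
                               write_structures)
from molscale.synthetic import SyntheticSpec, make_synthetic

from conftest import random_rigid_motion


def rotation_about(axis, theta):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = pairwise_distances(np.array([[0.0, 0, 0], [3.0, 4, 0]]))
        np.testing.assert_allclose(d, [[0, 5], [5, 0]])

    def test_single_point(self):
        assert pairwise_distances(np.zeros((1, 3))).shape == (1, 1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        d = pairwise_distances(pts)
        brute = np.array([[np.linalg.norm(a - b) for b in pts] for a in pts])
        np.testing.assert_allclose(d, brute, atol=1e-12)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        d = pairwise_distances(rng.normal(size=(8, 3)))
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestBondAngle:
    def test_orthogonal(self):
        assert bond_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(math.pi / 2)

    def test_collinear(self):
        a = bond_angle([1, 0, 0], [0, 0, 0], [-1, 0, 0])
        assert a == pytest.approx(math.pi, abs=1e-4)

    def test_tetrahedral(self):
        # two arms of an ideal tetrahedron subtend arccos(-1/3)
        arms = np.array([[1, 1, 1], [1, -1, -1]], float)
        got = bond_angle(arms[0], [0, 0, 0], arms[1])
        assert got == pytest.approx(math.acos(-1 / 3), abs=1e-12)
        assert got == pytest.approx(1.910633, abs=1e-6)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            bond_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestDihedral:
    A, B, C = np.array([1.0, 1, 0]), np.array([1.0, 0, 0]), np.array([0.0, 0, 0])

    def test_cis_is_zero(self):
        assert dihedral(self.A, self.B, self.C, [0, 1, 0]) == pytest.approx(0.0)

    def test_trans_is_pi(self):
        assert dihedral(self.A, self.B, self.C, [0, -1, 0]) == pytest.approx(math.pi)

    def test_rotation_oracle(self):
        # rotating the cis position about the central-bond axis u = r_j - r_k
        # by an angle must reproduce that dihedral, sign included
        u = self.B - self.C
        for theta in np.linspace(-2.8, 2.8, 29):
            R = rotation_about(u, theta)
            d_pos = self.C + R @ (np.array([0.0, 1, 0]) - self.C)
            got = dihedral(self.A, self.B, self.C, d_pos)
            assert got == pytest.approx(theta, abs=1e-9)

    def test_sixty_degrees(self):
        u = self.B - self.C
        d_pos = self.C + rotation_about(u, math.pi / 3) @ np.array([0.0, 1, 0])
        assert dihedral(self.A, self.B, self.C, d_pos) == pytest.approx(math.pi / 3)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            dihedral([2, 0, 0], [1, 0, 0], [0, 0, 0], [0, 1, 0])


class TestRigidMotionInvariance:
    def test_angle_and_dihedral_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2.0
            try:
                a0 = bond_angle(*pts[:3])
                t0 = dihedral(*pts)
            except ValueError:
                continue
            Q, t = random_rigid_motion(rng)
            moved = pts @ Q.T + t
            assert bond_angle(*moved[:3]) == pytest.approx(a0, abs=1e-6)
            assert dihedral(*moved) == pytest.approx(t0, abs=1e-6)

    def test_reflection_flips_dihedral_not_angle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(4, 3))
        a0, t0 = bond_angle(*pts[:3]), dihedral(*pts)
        mirrored = -pts
        assert bond_angle(*mirrored[:3]) == pytest.approx(a0, abs=1e-12)
        assert dihedral(*mirrored) == pytest.approx(-t0, abs=1e-9)


class TestExtractGeometryReference:
    def test_two_atom_counts(self):
        g = make_synthetic(SyntheticSpec("alkane_chain", 2))
        ref = extract_geometry_reference(g)
        assert (len(ref.distances), len(ref.angles), len(ref.torsions)) == (1, 0, 0)

    def test_linear_chain_counts(self):
        g = make_synthetic(SyntheticSpec("alkane_chain", 4))
        ref = extract_geometry_reference(g)
        assert (len(ref.distances), len(ref.angles), len(ref.torsions)) == (3, 2, 1)

    def test_cyclohexane_ring_angles(self):
        g = make_synthetic(SyntheticSpec("cycloalkane", 6))
        ref = extract_geometry_reference(g)
        for v in ref.angles.values():
            assert v == pytest.approx(g.meta["ring_angle"], abs=1e-9)

    def test_values_recompute_from_coords(self):
        g = make_synthetic(SyntheticSpec("decorated_scaffold", 8, seed=3))
        ref = extract_geometry_reference(g)
        R = g.coords
        for (i, j), v in ref.distances.items():
            assert v == pytest.approx(np.linalg.norm(R[i] - R[j]))
        for (i, j, k), v in ref.angles.items():
            assert v == pytest.approx(bond_angle(R[i], R[j], R[k]))
        for (i, j, k, l), v in ref.torsions.items():
            assert v == pytest.approx(dihedral(R[i], R[j], R[k], R[l]))

    def test_tsv_roundtrip(self, tmp_path):
        g = make_synthetic(SyntheticSpec("alkane_chain", 6, seed=1))
        ref = extract_geometry_reference(g)
        p = tmp_path / "ref.tsv"
        ref.to_tsv(p)
        back = GeometryReference.from_tsv(p)
        assert back.distances == pytest.approx(ref.distances)
        assert back.angles == pytest.approx(ref.angles)
        assert back.torsions == pytest.approx(ref.torsions)


class TestGraphInvariants:
    def test_bond_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="references atom"):
            MolecularGraph(np.zeros((2, 4)), np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]],
                           [(0, 5, 1)], ["C", "C"])

    def test_self_bond_rejected(self):
        with pytest.raises(ValueError, match="self-bond"):
            MolecularGraph(np.zeros((2, 4)), [[0, 0, 0], [1, 0, 0]],
                           [(1, 1, 1)], ["C", "C"])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MolecularGraph(np.zeros((1, 4)), [[np.nan, 0, 0]], [], ["C"])


class TestXYZ:
    def test_two_carbon_inferred_bond(self, tmp_path):
        p = tmp_path / "c2.xyz"
        p.write_text("2\nethane backbone\nC 0 0 0\nC 1.54 0 0\n")
        graphs = read_structures(p)
        assert len(graphs) == 1
        g = graphs[0]
        assert g.atom_count == 2
        assert g.bonds == [(0, 1, 1)]

    def test_empty_file_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_structures(p) == []
        assert "no records" in caplog.text

    def test_malformed_atom_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nx\nC 0 0\n")
        with pytest.raises(ValueError, match="record 1"):
            read_structures(p)

    def test_roundtrip_precision(self, tmp_path):
        g = make_synthetic(SyntheticSpec("alkane_chain", 7, seed=2))
        p = tmp_path / "out.xyz"
        write_structures(g, p)
        back = read_structures(p)[0]
        np.testing.assert_allclose(back.coords, g.coords, atol=1e-6)
        assert back.bonds == g.bonds


class TestSDF:
    def test_roundtrip_precision(self, tmp_path):
        g = make_synthetic(SyntheticSpec("decorated_scaffold", 9, seed=4))
        p = tmp_path / "out.sdf"
        write_structures(g, p)
        back = read_structures(p)[0]
        np.testing.assert_allclose(back.coords, g.coords, atol=1e-4)
        assert {b[:2] for b in back.bonds} == {b[:2] for b in g.bonds}
        assert back.symbols == g.symbols

    def test_bond_index_beyond_atoms(self, tmp_path):
        sdf = (
            "bad\n  prog\n\n"
            "  5  1  0  0  0  0  0  0  0  0999 V2000\n"
            + "    0.0000    0.0000    0.0000 C   0  0\n" * 5
            + "  1  9  1  0\n"
            "M  END\n$$$$\n"
        )
        p = tmp_path / "bad.sdf"
        p.write_text(sdf)
        with pytest.raises(ValueError, match=r"record 1: bond references atom 9 of 5"):
            read_structures(p)

    def test_2d_only_rejected(self, tmp_path):
        sdf = (
            "flat\n  prog          2D\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.5000    0.0000    0.0000 C   0  0\n"
            "  1  2  1  0\nM  END\n$$$$\n"
        )
        p = tmp_path / "flat.sdf"
        p.write_text(sdf)
        with pytest.raises(ValueError, match="2D"):
            read_structures(p)
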