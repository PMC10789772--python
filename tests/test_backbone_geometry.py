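import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from confdiff.backbone_geometry import (
    DegenerateGeometryError,
    backbone_dihedrals,
    coordinate_rmsd,
    dihedral,
    interdomain_angle,
    kabsch_superpose,
    min_sidechain_distance,
    rotation_angle,
)
from confdiff.structure_io import StructureModel
from confdiff.synthetic_structures import BackboneSpec, build_backbone


def oracle_dihedral(p1, p2, p3, p4):
    """Independent atan2-of-cross/dot formulation (kept deliberately separate
    from the implementation under test)."""
    b0 = np.subtract(p1, p2)
    b1 = np.subtract(p3, p2)
    b2 = np.subtract(p4, p3)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def random_rigid(rng):
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-10, 10, 3)


def circ_diff(a, b):
    """Absolute angular difference on the circle, degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        pts = [(1, 1, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0)]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        pts = [(1, 1, 0), (0, 0, 0), (1, 0, 0), (2, -1, 0)]
        assert abs(dihedral(*pts)) == pytest.approx(180.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        pts = [(1, 1, 0), (0, 0, 0), (1, 0, 0), (2, -1, 1)]
        expect = oracle_dihedral(*pts)
        assert dihedral(*pts) == pytest.approx(expect, abs=1e-9)
        for _ in range(50):
            q = rng.normal(size=(4, 3)) * 3
            try:
                got = dihedral(*q)
            except DegenerateGeometryError:
                continue
            assert circ_diff(got, oracle_dihedral(*q)) < 1e-9

    def test_matches_mdanalysis(self, rng):
        """Cross-check against an established MD analysis library."""
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(20):
            q = rng.normal(size=(4, 3)) * 3
            ref = np.degrees(
                calc_dihedrals(
                    q[0][None], q[1][None], q[2][None], q[3][None]
                )
            )[0]
            # MDAnalysis evaluates in single precision
            assert circ_diff(dihedral(*q), ref) < 1e-4

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_motion_invariant_reflection_negates(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(4, 3)) * 3
        try:
            base = dihedral(*q)
        except DegenerateGeometryError:
            return
        R, t = random_rigid(rng)
        moved = q @ R.T + t
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = q * np.array([1.0, 1.0, -1.0])
        got = dihedral(*mirrored)
        if abs(base) == pytest.approx(180.0):
            assert abs(got) == pytest.approx(180.0, abs=1e-9)
        else:
            assert got == pytest.approx(-base, abs=1e-9)

    def test_degenerate_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0))
        with pytest.raises(DegenerateGeometryError):
            dihedral((2, 0, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0))  # collinear 1-2-3


class TestBackboneDihedrals:
    def test_round_trip_recovers_helix_angles(self):
        s = build_backbone(BackboneSpec.uniform(15, phi=-57.0, psi=-47.0))
        dh = backbone_dihedrals(s)
        for rid in dh.residues[1:-1]:
            e = dh[rid.key]
            assert e["phi"] == pytest.approx(-57.0, abs=1e-6)
            assert e["psi"] == pytest.approx(-47.0, abs=1e-6)
            assert abs(e["omega"]) == pytest.approx(180.0, abs=1e-6)

    def test_two_residue_chain_defines_only_psi1_phi2_omega2(self):
        s = build_backbone(BackboneSpec.uniform(2, phi=-57.0, psi=-47.0))
        dh = backbone_dihedrals(s)
        r1, r2 = dh.residues
        assert dh[r1.key]["phi"] is None and dh[r1.key]["omega"] is None
        assert dh[r1.key]["psi"] is not None
        assert dh[r2.key]["phi"] is not None and dh[r2.key]["omega"] is not None
        assert dh[r2.key]["psi"] is None

    def test_rotated_structure_has_identical_dihedrals(self, helix20, rng):
        moved = copy.deepcopy(helix20)
        R, t = random_rigid(rng)
        for res in moved.residues:
            for a in res.atoms:
                a.coords = R @ a.coords + t
        d0, d1 = backbone_dihedrals(helix20), backbone_dihedrals(moved)
        for rid in d0.residues:
            for k in ("phi", "psi", "omega"):
                a0, a1 = d0[rid.key][k], d1[rid.key][k]
                if a0 is None:
                    assert a1 is None
                else:
                    assert circ_diff(a0, a1) < 1e-9

    def test_chain_break_yields_missing_angles(self, helix20):
        broken = copy.deepcopy(helix20)
        for res in broken.residues[10:]:
            for a in res.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="chain break"):
            dh = backbone_dihedrals(broken)
        k10, k11 = broken.residues[9].id.key, broken.residues[10].id.key
        assert dh[k10]["psi"] is None
        assert dh[k11]["phi"] is None and dh[k11]["omega"] is None


class TestKabsch:
    def test_identity_on_self(self, rng):
        x = rng.normal(size=(12, 3)) * 4
        sup = kabsch_superpose(x, x)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.abs(sup.rotation - np.eye(3)).max() < 1e-9

    def test_recovers_applied_transform(self, rng):
        x = rng.normal(size=(10, 3)) * 5
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        moved = x @ R.T + t
        sup = kabsch_superpose(x, moved)
        assert np.abs(sup.rotation - R).max() < 1e-9
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_always(self, rng):
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.abs(sup.rotation @ sup.rotation.T - np.eye(3)).max() < 1e-9

    def test_optimal_among_random_rigid_transforms(self, rng):
        a = rng.normal(size=(8, 3)) * 3
        b = a + rng.normal(size=(8, 3)) * 0.5
        best = kabsch_superpose(a, b).rmsd
        for _ in range(200):
            R, t = random_rigid(rng)
            moved = a @ R.T + t
            rmsd = np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_matches_mdanalysis_rmsd(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        a = rng.normal(size=(20, 3)) * 4
        b = a + rng.normal(size=(20, 3)) * 0.8
        ours = kabsch_superpose(a, b).rmsd
        theirs = mda_rmsd(a, b, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_shape_errors(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestInterdomainAngle:
    @staticmethod
    def rotate_tail(model, first_tail, angle_deg, axis, rng=None):
        out = copy.deepcopy(model)
        tail = [r for r in out.residues if r.id.seq_number >= first_tail]
        cas = np.array([r.atom("CA").coords for r in tail])
        cen = cas.mean(axis=0)
        R = Rotation.from_rotvec(
            np.deg2rad(angle_deg) * np.asarray(axis) / np.linalg.norm(axis)
        ).as_matrix()
        for r in tail:
            for a in r.atoms:
                a.coords = R @ (a.coords - cen) + cen
        return out

    def test_identical_structures_give_zero(self, helix20):
        assert interdomain_angle(
            helix20, helix20, ("A", 1, 10), ("A", 11, 20)
        ) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [25.0, 180.0])
    def test_recovers_constructed_rotation(self, helix20, angle):
        b = self.rotate_tail(helix20, 11, angle, axis=(1.0, 2.0, 3.0))
        got = interdomain_angle(helix20, b, ("A", 1, 10), ("A", 11, 20))
        assert got == pytest.approx(angle, abs=1e-6)

    def test_symmetric_in_the_two_structures(self, helix20):
        b = self.rotate_tail(helix20, 11, 40.0, axis=(0.0, 1.0, 1.0))
        ab = interdomain_angle(helix20, b, ("A", 1, 10), ("A", 11, 20))
        ba = interdomain_angle(b, helix20, ("A", 1, 10), ("A", 11, 20))
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_empty_domain_is_an_error(self, helix20):
        with pytest.raises(ValueError):
            interdomain_angle(helix20, helix20, ("A", 100, 110), ("A", 11, 20))


class TestMinSidechainDistance:
    def test_constructed_4A_separation(self, helix20):
        s = copy.deepcopy(helix20)
        r1, r2 = s.residues[0], s.residues[10]
        cb1, cb2 = r1.atom("CB"), r2.atom("CB")
        cb2.coords = cb1.coords + np.array([4.0, 0.0, 0.0])
        contact = min_sidechain_distance(s, r1.id, r2.id)
        assert contact.distance == pytest.approx(4.0, abs=1e-9)
        assert {contact.atom_1, contact.atom_2} == {"CB"}

    def test_same_residue_is_zero_with_warning(self, helix20):
        with pytest.warns(UserWarning):
            contact = min_sidechain_distance(
                helix20, helix20.residues[3].id, helix20.residues[3].id
            )
        assert contact.distance == 0.0

    def test_matches_exhaustive_pair_minimum(self, helix20, rng):
        s = copy.deepcopy(helix20)
        r1, r2 = s.residues[2], s.residues[9]
        # give the residues 3- and 2-atom synthetic side chains
        from confdiff.structure_io import AtomRecord

        r1.atoms = [a for a in r1.atoms if a.atom_name in ("N", "CA", "C", "O")]
        r2.atoms = [a for a in r2.atoms if a.atom_name in ("N", "CA", "C", "O")]
        for i, name in enumerate(["CB", "CG", "CD"]):
            r1.atoms.append(AtomRecord(name, "C", rng.normal(size=3) * 3))
        for i, name in enumerate(["CB", "CG"]):
            r2.atoms.append(AtomRecord(name, "C", rng.normal(size=3) * 3 + 5))
        contact = min_sidechain_distance(s, r1.id, r2.id)
        brute = min(
            np.linalg.norm(x.coords - y.coords)
            for x in r1.atoms if x.atom_name not in ("N", "CA", "C", "O")
            for y in r2.atoms if y.atom_name not in ("N", "CA", "C", "O")
        )
        assert contact.distance == pytest.approx(brute, abs=1e-12)

    def test_glycine_falls_back_to_ca(self):
        s = build_backbone(
            BackboneSpec.uniform(5, phi=-57.0, psi=-47.0, residue_name="GLY", with_cbeta=False)
        )
        contact = min_sidechain_distance(s, s.residues[0].id, s.residues[4].id)
        assert contact.atom_1 == "CA" and contact.atom_2 == "CA"

    def test_absent_residue_is_an_error(self, helix20):
        from confdiff.structure_io import ResidueId

        with pytest.raises(KeyError):
            min_sidechain_distance(
                helix20, helix20.residues[0].id, ResidueId("A", 99, "", "ALA")
            )


def test_rotation_angle_clamps_trace_noise():
    R = np.eye(3) * (1 + 1e-15)
    assert rotation_angle(R) == 0.0


def test_coordinate_rmsd_raw_vs_superposed(rng):
    a = rng.normal(size=(10, 3))
    b = a + np.array([3.0, 0.0, 0.0])
    assert coordinate_rmsd(a, b, superpose=False) == pytest.approx(3.0)
    assert coordinate_rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-9)
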