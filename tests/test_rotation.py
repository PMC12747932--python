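import numpy as np
import pytest

from wins7.rotation import (
    GeometryError,
    chi_angles,
    dihedral,
    plane_angle,
    ring_plane_normal,
    sidechain_rotation,
)
from wins7.structures import Atom, Residue
from wins7.superpose import SuperpositionResult, superpose_chains
from wins7.synthetic import (
    build_tyrosine,
    make_rigid_copy,
    make_tyrosine_pair,
    rotation_about_axis,
)


def _brute_dihedral(p0, p1, p2, p3):
    """Independent oracle: projection onto the plane normal to the central bond."""
    b = p2 - p1
    b = b / np.linalg.norm(b)
    u = (p0 - p1) - np.dot(p0 - p1, b) * b
    v = (p3 - p2) - np.dot(p3 - p2, b) * b
    ang = np.degrees(
        np.arctan2(np.dot(np.cross(u, v), b), np.dot(u, v))
    )
    return -ang  # IUPAC sign: clockwise positive looking down p1->p2


class TestDihedral:
    def test_cis_is_zero(self):
        pts = [np.array(p, float) for p in
               [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]]
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_case(self):
        pts = [np.array(p, float) for p in
               [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]]
        got = dihedral(*pts)
        assert abs(got) == pytest.approx(90.0, abs=1e-9)
        assert got == pytest.approx(_brute_dihedral(*pts), abs=1e-9)

    def test_matches_brute_oracle_on_random_quads(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = list(rng.normal(0, 3, (4, 3)))
            assert dihedral(*pts) == pytest.approx(
                _brute_dihedral(*pts), abs=1e-8
            )


@pytest.mark.parametrize("chi1,chi2", [(-60.0, 90.0), (180.0, 30.0), (62.5, -45.0)])
def test_chi_construction_round_trip(chi1, chi2):
    tyr = build_tyrosine(chi1=chi1, chi2=chi2)
    got1, got2 = chi_angles(tyr)
    assert got1 == pytest.approx(chi1, abs=1e-6)
    assert got2 == pytest.approx(chi2, abs=1e-6)


def test_chi_missing_atom_names_the_atom():
    tyr = build_tyrosine()
    tyr.atoms = [a for a in tyr.atoms if a.name != "CG"]
    with pytest.raises(GeometryError, match="CG"):
        chi_angles(tyr)


def _flat_hexagon(z_rotation_deg=0.0, tilt_axis=None, tilt_deg=0.0):
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = []
    rot = np.eye(3)
    if tilt_axis is not None:
        rot = rotation_about_axis(np.asarray(tilt_axis, float), tilt_deg)
    for i, name in enumerate(names):
        th = np.radians(60 * i + z_rotation_deg)
        p = rot @ np.array([1.39 * np.cos(th), 1.39 * np.sin(th), 0.0])
        atoms.append(Atom(name, "C", p))
    return Residue("A", 1, "PHE", atoms)


class TestRingPlaneNormal:
    def test_flat_hexagon_normal_is_z(self):
        n = ring_plane_normal(_flat_hexagon())
        assert abs(n[2]) == pytest.approx(1.0, abs=1e-12)

    def test_tilted_hexagon(self):
        n0 = ring_plane_normal(_flat_hexagon())
        n30 = ring_plane_normal(_flat_hexagon(tilt_axis=(1, 0, 0), tilt_deg=30.0))
        assert plane_angle(n0, n30) == pytest.approx(30.0, abs=1e-9)

    def test_ring_label_swap_invariance(self):
        res = _flat_hexagon(tilt_axis=(0, 1, 0), tilt_deg=17.0)
        swapped = Residue("A", 1, "PHE", [
            Atom({"CD1": "CD2", "CD2": "CD1", "CE1": "CE2", "CE2": "CE1"}.get(
                a.name, a.name), "C", a.coords.copy())
            for a in res.atoms
        ])
        assert plane_angle(
            ring_plane_normal(res), ring_plane_normal(swapped)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_missing_ring_atom(self):
        res = _flat_hexagon()
        res.atoms = res.atoms[:-1]
        with pytest.raises(GeometryError):
            ring_plane_normal(res)


class TestSidechainRotation:
    def test_identity_pair(self):
        st, _ = make_tyrosine_pair(seed=4)
        rep = sidechain_rotation(
            st, st, ("A", 191), ("A", 191), SuperpositionResult.identity()
        )
        # arccos loses ~sqrt(eps) precision for near-parallel normals
        assert rep.ring_plane_angle == pytest.approx(0.0, abs=1e-5)
        assert rep.delta_chi1 == pytest.approx(0.0, abs=1e-9)
        assert rep.delta_chi2 == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [5.0, 15.0, 30.0, 60.0, 85.0])
    def test_monotone_recovery_of_applied_rotation(self, theta):
        sa, sb = make_tyrosine_pair(ring_rotation_deg=theta, seed=4)
        frame = superpose_chains(sb, sa, "A", "A", resi_range=(1, 10))
        rep = sidechain_rotation(sa, sb, ("A", 191), ("A", 191), frame)
        assert rep.ring_plane_angle == pytest.approx(theta, abs=0.5)
        assert 0.0 <= rep.ring_plane_angle <= 90.0

    def test_symmetric_in_structure_order(self):
        sa, sb = make_tyrosine_pair(ring_rotation_deg=40.0, seed=4)
        f_ab = superpose_chains(sb, sa, "A", "A", resi_range=(1, 10))
        f_ba = superpose_chains(sa, sb, "A", "A", resi_range=(1, 10))
        ab = sidechain_rotation(sa, sb, ("A", 191), ("A", 191), f_ab)
        ba = sidechain_rotation(sb, sa, ("A", 191), ("A", 191), f_ba)
        assert ab.ring_plane_angle == pytest.approx(ba.ring_plane_angle, abs=1e-9)

    def test_invariant_to_joint_rigid_motion(self):
        sa, sb = make_tyrosine_pair(ring_rotation_deg=33.0, seed=4)
        rep0 = sidechain_rotation(
            sa, sb, ("A", 191), ("A", 191),
            superpose_chains(sb, sa, "A", "A", resi_range=(1, 10)),
        )
        sa2 = make_rigid_copy(sa, 25.0, (1, 1, 0), (8, -4, 2))
        sb2 = make_rigid_copy(sb, 25.0, (1, 1, 0), (8, -4, 2))
        rep1 = sidechain_rotation(
            sa2, sb2, ("A", 191), ("A", 191),
            superpose_chains(sb2, sa2, "A", "A", resi_range=(1, 10)),
        )
        assert rep1.ring_plane_angle == pytest.approx(rep0.ring_plane_angle, abs=1e-8)

    def test_tyr_vs_phe_comparison_works(self):
        """Ring comparison must not require the hydroxyl (Y191F case)."""
        sa, sb = make_tyrosine_pair(ring_rotation_deg=17.0, seed=4)
        tyr_b = sb.chain("A").residue(191)
        tyr_b.res_name = "PHE"
        tyr_b.atoms = [a for a in tyr_b.atoms if a.name != "OH"]
        frame = superpose_chains(sb, sa, "A", "A", resi_range=(1, 10))
        rep = sidechain_rotation(sa, sb, ("A", 191), ("A", 191), frame)
        assert rep.ring_plane_angle == pytest.approx(17.0, abs=0.5)

    def test_non_aromatic_rejected(self):
        st, _ = make_tyrosine_pair(seed=4)
        with pytest.raises(GeometryError):
            sidechain_rotation(
                st, st, ("A", 1), ("A", 1), SuperpositionResult.identity()
            )
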