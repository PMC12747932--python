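"""Side-chain rotation metrics for the Tyr191 switch.

The observable quantifying how far a tyrosine (or phenylalanine) ring has
swung between two structures is the angle between the least-squares planes of
the six ring carbons, measured after both structures are placed in a common
β-propeller frame. The plane-normal angle is folded into [0, 90]°, which makes
it invariant both to the sign of the normal and to the crystallographic
CD1/CD2–CE1/CE2 ring-label ambiguity. IUPAC χ1/χ2 deltas are reported as
secondary descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Residue, Structure, StructureError
from .superpose import SuperpositionResult

RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
AROMATIC_RES = {"TYR", "PHE"}


class GeometryError(Exception):
    pass


@dataclass
class RotationReport:
    """Ring rotation of one residue between two superposed structures."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    ring_plane_angle: float  # degrees, folded to [0, 90]
    delta_chi1: float        # degrees in (-180, 180]
    delta_chi2: float        # degrees folded to [0, 90] (ring 2-fold symmetry)
    frame: str = ""

    def to_dict(self) -> dict:
        return {
            "residue_a": list(self.residue_a),
            "residue_b": list(self.residue_b),
            "ring_plane_angle_deg": self.ring_plane_angle,
            "delta_chi1_deg": self.delta_chi1,
            "delta_chi2_deg": self.delta_chi2,
            "frame": self.frame,
        }


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def chi_angles(residue: Residue) -> tuple[float, float]:
    """(χ1, χ2) of a Tyr/Phe side chain: N-CA-CB-CG and CA-CB-CG-CD1."""
    for name in ("N", "CA", "CB", "CG", "CD1"):
        if not residue.has_atom(name):
            raise GeometryError(
                f"atom {name} missing from {residue.res_name} "
                f"{residue.chain_id}{residue.seq_id}"
            )
    n, ca, cb, cg, cd1 = (
        residue.coord(a) for a in ("N", "CA", "CB", "CG", "CD1")
    )
    return dihedral(n, ca, cb, cg), dihedral(ca, cb, cg, cd1)


def ring_plane_normal(residue: Residue) -> np.ndarray:
    """Unit normal of the least-squares plane through the six ring carbons.

    The sign is arbitrary (smallest right singular vector of the centred ring
    coordinates); callers must use it only up to ±.
    """
    coords = []
    for name in RING_ATOMS:
        if not residue.has_atom(name):
            raise GeometryError(
                f"ring atom {name} missing from {residue.res_name} "
                f"{residue.chain_id}{residue.seq_id}"
            )
        coords.append(residue.coord(name))
    pts = np.array(coords)
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    normal = vt[2]
    return normal / np.linalg.norm(normal)


def plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two plane normals folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _wrap180(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if np.isclose(a, -180.0) else a


def _fold_ring_delta(delta: float) -> float:
    """Fold a χ2 difference under the aromatic ring's 2-fold symmetry."""
    d = abs(_wrap180(delta)) % 180.0
    return min(d, 180.0 - d)


def sidechain_rotation(
    struct_a: Structure,
    struct_b: Structure,
    residue_id_a: tuple[str, int],
    residue_id_b: tuple[str, int],
    frame: SuperpositionResult,
    frame_label: str = "",
) -> RotationReport:
    """Ring rotation of residue B relative to residue A after mapping B into
    A's propeller frame.

    ``frame`` must be the superposition of structure B's propeller onto
    structure A's (B-coordinates in, A-frame out). For Tyr-vs-Phe comparisons
    the six ring carbons common to both suffice.
    """
    res_a = struct_a.chain(residue_id_a[0]).residue(residue_id_a[1])
    res_b = struct_b.chain(residue_id_b[0]).residue(residue_id_b[1])
    for res in (res_a, res_b):
        if res.res_name not in AROMATIC_RES:
            raise GeometryError(
                f"unsupported residue {res.res_name}; ring rotation is defined "
                "for Tyr/Phe"
            )
    normal_a = ring_plane_normal(res_a)
    # rotate B's normal into A's frame (normals transform by R only)
    normal_b = frame.rotation @ ring_plane_normal(res_b)
    chi1_a, chi2_a = chi_angles(res_a)
    chi1_b, chi2_b = chi_angles(res_b)
    return RotationReport(
        residue_a=(res_a.chain_id, res_a.seq_id, res_a.res_name),
        residue_b=(res_b.chain_id, res_b.seq_id, res_b.res_name),
        ring_plane_angle=plane_angle(normal_a, normal_b),
        delta_chi1=_wrap180(chi1_b - chi1_a),
        delta_chi2=_fold_ring_delta(chi2_b - chi2_a),
        frame=frame_label or f"superposition(n={frame.n_atoms}, rmsd={frame.rmsd:.3f})",
    )
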