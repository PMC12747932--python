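"""Synthetic structure and thermogram generators for the full test surface.

Everything the package measures on deposited crystal structures can be
exercised on constructions with known ground truth: tyrosine pairs with a
prescribed ring rotation, interface geometries with prescribed hydrogen-bond /
salt-bridge / cation-π / water-bridge content, rigid copies with a known
transform and coordinate noise, hollow shells with an analytic cavity volume,
and single-site thermograms with stated (N, K_D, ΔH). Residue geometry is
idealized (standard bond lengths and angles, built by internal-coordinate
chaining); seeds are explicit arguments and fixed seeds give byte-identical
output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .itc import Thermogram, TitrationSetup, simulate_thermogram
from .structures import Atom, Chain, Model, Residue, Structure, write_structure

# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with |CD| = bond, ∠BCD = angle and
    dihedral(A,B,C,D) = dihedral (natural-extension reference frame)."""
    angle = np.radians(angle_deg)
    tors = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(tors),
        -bond * np.sin(angle) * np.sin(tors),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# idealized residues
# ---------------------------------------------------------------------------

def _mkatom(name: str, element: str, coords) -> Atom:
    return Atom(name=name, element=element, coords=np.asarray(coords, dtype=float))


def build_tyrosine(chain_id: str = "A", seq_id: int = 191,
                   chi1: float = -60.0, chi2: float = 90.0,
                   res_name: str = "TYR") -> Residue:
    """Idealized Tyr (or Phe) with prescribed χ1 (N-CA-CB-CG) and
    χ2 (CA-CB-CG-CD1), backbone at the origin frame."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    # CB in the xy-plane with tetrahedral-ish N-CA-CB angle
    ang = np.radians(110.5)
    cb = ca + 1.530 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    cg = nerf(n, ca, cb, 1.512, 113.9, chi1)
    cd1 = nerf(ca, cb, cg, 1.389, 120.8, chi2)
    cd2 = nerf(ca, cb, cg, 1.389, 120.8, chi2 + 180.0)
    ce1 = nerf(cb, cg, cd1, 1.389, 120.3, 180.0)
    ce2 = nerf(cb, cg, cd2, 1.389, 120.3, 180.0)
    cz = nerf(cg, cd1, ce1, 1.389, 119.8, 0.0)
    c = nerf(cb, n, ca, 1.525, 111.0, -122.0)
    o = nerf(n, ca, c, 1.231, 120.5, 0.0)
    atoms = [
        _mkatom("N", "N", n), _mkatom("CA", "C", ca), _mkatom("C", "C", c),
        _mkatom("O", "O", o), _mkatom("CB", "C", cb), _mkatom("CG", "C", cg),
        _mkatom("CD1", "C", cd1), _mkatom("CD2", "C", cd2),
        _mkatom("CE1", "C", ce1), _mkatom("CE2", "C", ce2),
        _mkatom("CZ", "C", cz),
    ]
    if res_name == "TYR":
        oh = nerf(cd1, ce1, cz, 1.376, 119.9, 180.0)
        atoms.append(_mkatom("OH", "O", oh))
    return Residue(chain_id=chain_id, seq_id=seq_id, res_name=res_name, atoms=atoms)


def _alanine(chain_id: str, seq_id: int, origin: np.ndarray) -> Residue:
    """Minimal idealized alanine translated to ``origin`` (scaffold filler)."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    ang = np.radians(110.5)
    cb = ca + 1.530 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    c = nerf(cb, n, ca, 1.525, 111.0, -122.0)
    o = nerf(n, ca, c, 1.231, 120.5, 0.0)
    atoms = [
        _mkatom("N", "N", n + origin), _mkatom("CA", "C", ca + origin),
        _mkatom("C", "C", c + origin), _mkatom("O", "O", o + origin),
        _mkatom("CB", "C", cb + origin),
    ]
    return Residue(chain_id=chain_id, seq_id=seq_id, res_name="ALA", atoms=atoms)


def _structure_from_residues(sid: str, residues: list[Residue]) -> Structure:
    chains: dict[str, Chain] = {}
    for res in residues:
        chains.setdefault(res.chain_id, Chain(chain_id=res.chain_id)).residues.append(res)
    return Structure(id=sid, models=[Model(chains=list(chains.values()))])


# ---------------------------------------------------------------------------
# fixture generators
# ---------------------------------------------------------------------------

RING_MOBILE_ATOMS = ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")


def make_tyrosine_pair(
    chi1: float = -60.0,
    chi2: float = 90.0,
    ring_rotation_deg: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """Two structures sharing a rigid 10-residue scaffold, the second with its
    tyrosine ring rotated ``ring_rotation_deg`` about the CB–CG axis.

    Because the CB–CG axis lies in the (ideally planar) ring, the ring-plane
    normal rotates by exactly the applied angle, which is the ground truth
    for the rotation metric.
    """
    rng = np.random.default_rng(seed)
    offset = np.array([0.0, 18.0, 0.0])  # keep scaffold clear of the side chain
    scaffold = [
        _alanine("A", i + 1, offset + np.array([3.8 * i, 0.0, 0.0]) +
                 rng.normal(0, 0.2, 3))
        for i in range(10)
    ]

    def build(rot_deg: float) -> Structure:
        tyr = build_tyrosine("A", 191, chi1=chi1, chi2=chi2)
        if rot_deg:
            axis = tyr.coord("CG") - tyr.coord("CB")
            rot = rotation_about_axis(axis, rot_deg)
            pivot = tyr.coord("CG")
            for atom in tyr.atoms:
                if atom.name in RING_MOBILE_ATOMS:
                    atom.coords = rot @ (atom.coords - pivot) + pivot
        residues = [
            Residue(r.chain_id, r.seq_id, r.res_name,
                    [Atom(a.name, a.element, a.coords.copy()) for a in r.atoms])
            for r in scaffold
        ] + [tyr]
        return _structure_from_residues(f"tyr_pair_{rot_deg:g}", residues)

    return build(0.0), build(ring_rotation_deg)


class FixtureError(Exception):
    pass


def make_interaction_fixture(
    kind: str,
    distance: float = 2.8,
    angle: float = 90.0,
    seed: int = 0,
) -> Structure:
    """Minimal two-group structure with an exactly prescribed contact geometry.

    Kinds: ``hbond_pair`` (Ser OG donor vs backbone carbonyl O at
    ``distance``), ``salt_bridge_pair`` (Arg guanidinium vs Asp carboxylate,
    NH1–OD1 = NH2–OD2 = ``distance``), ``cation_pi`` (Arg CZ at ``distance``
    from a Phe ring centroid, elevation ``angle`` degrees above the plane) and
    ``water_bridge`` (one water with O at ``distance`` from both a peptide
    carbonyl O and a protein amide N).
    """
    if distance <= 0:
        raise FixtureError("distance must be positive")
    if kind == "hbond_pair":
        ser = Residue("A", 1, "SER", [
            _mkatom("CB", "C", [-1.43, 0.0, 0.0]),
            _mkatom("OG", "O", [0.0, 0.0, 0.0]),
        ])
        # acceptor placed at `distance` along a direction making `angle`
        # with the OG->CB antecedent bond
        direction = np.array([np.cos(np.radians(180.0 - angle)),
                              np.sin(np.radians(180.0 - angle)), 0.0])
        acc = distance * direction
        gly = Residue("B", 2, "GLY", [
            _mkatom("C", "C", acc + np.array([1.23, 0.0, 0.0])),
            _mkatom("O", "O", acc),
        ])
        return _structure_from_residues("hbond_pair", [ser, gly])
    if kind == "salt_bridge_pair":
        # guanidinium plane in xy; carboxylate facing it a `distance` away
        cz = np.array([0.0, 0.0, 0.0])
        nh1 = np.array([0.65, 1.15, 0.0])
        nh2 = np.array([0.65, -1.15, 0.0])
        ne = np.array([-1.33, 0.0, 0.0])
        arg = Residue("A", 1, "ARG", [
            _mkatom("CD", "C", ne + np.array([-0.8, 1.2, 0.0])),
            _mkatom("NE", "N", ne), _mkatom("CZ", "C", cz),
            _mkatom("NH1", "N", nh1), _mkatom("NH2", "N", nh2),
        ])
        # splay the carboxylate slightly so only the facing pairs
        # (NH1-OD1, NH2-OD2) sit at `distance`; the cross pairs fall outside
        # the default cutoff
        splay = np.radians(15.0)
        od1 = nh1 + distance * np.array([np.cos(splay), np.sin(splay), 0.0])
        od2 = nh2 + distance * np.array([np.cos(splay), -np.sin(splay), 0.0])
        cg = (od1 + od2) / 2 + np.array([0.7, 0.0, 0.0])
        asp = Residue("B", 2, "ASP", [
            _mkatom("CB", "C", cg + np.array([1.52, 0.0, 0.0])),
            _mkatom("CG", "C", cg),
            _mkatom("OD1", "O", od1), _mkatom("OD2", "O", od2),
        ])
        return _structure_from_residues("salt_bridge_pair", [arg, asp])
    if kind == "cation_pi":
        # Phe ring centred at the origin in the xy-plane
        ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = []
        for i, name in enumerate(ring_names):
            theta = np.radians(60.0 * i)
            atoms.append(_mkatom(name, "C", [1.39 * np.cos(theta),
                                             1.39 * np.sin(theta), 0.0]))
        atoms.append(_mkatom("CB", "C", [2.91 * np.cos(0), 2.91 * np.sin(0), 0.0]))
        phe = Residue("A", 1, "PHE", atoms)
        elev = np.radians(angle)
        cz_pos = distance * np.array([np.cos(elev), 0.0, np.sin(elev)])
        arg = Residue("B", 2, "ARG", [
            _mkatom("NE", "N", cz_pos + np.array([-1.33, 0.0, 0.0])),
            _mkatom("CZ", "C", cz_pos),
            _mkatom("NH1", "N", cz_pos + np.array([0.65, 1.15, 0.0])),
            _mkatom("NH2", "N", cz_pos + np.array([0.65, -1.15, 0.0])),
        ])
        return _structure_from_residues("cation_pi", [phe, arg])
    if kind == "water_bridge":
        # water O equidistant (``distance``) from a peptide carbonyl O and a
        # protein backbone N
        half = distance * np.cos(np.radians(35.0))
        rise = distance * np.sin(np.radians(35.0))
        pep_o = np.array([-half, 0.0, 0.0])
        prot_n = np.array([half, 0.0, 0.0])
        water_o = np.array([0.0, rise, 0.0])
        pep = Residue("P", 1, "GLY", [
            _mkatom("C", "C", pep_o + np.array([-1.23, 0.0, 0.0])),
            _mkatom("O", "O", pep_o),
        ])
        prot = Residue("A", 2, "GLY", [
            _mkatom("N", "N", prot_n),
            _mkatom("CA", "C", prot_n + np.array([1.458, 0.0, 0.0])),
        ])
        wat = Residue("W", 501, "HOH", [_mkatom("O", "O", water_o)],
                      is_hetero=True)
        return _structure_from_residues("water_bridge", [pep, prot, wat])
    raise FixtureError(f"unknown fixture kind: {kind!r}")


def make_rigid_copy(
    structure: Structure,
    rotation_deg: float = 0.0,
    axis=(0.0, 0.0, 1.0),
    translation=(0.0, 0.0, 0.0),
    coord_noise_sd: float = 0.0,
    seed: int = 0,
) -> Structure:
    """Rigidly transformed copy with optional isotropic Gaussian coordinate
    noise (per-axis sd ``coord_noise_sd`` Å)."""
    rng = np.random.default_rng(seed)
    rot = rotation_about_axis(np.asarray(axis, dtype=float), rotation_deg)
    t = np.asarray(translation, dtype=float)
    out = structure.copy()
    out.id = structure.id + "_copy"
    for _, atom in out.atoms():
        atom.coords = rot @ atom.coords + t
        if coord_noise_sd > 0:
            atom.coords = atom.coords + rng.normal(0.0, coord_noise_sd, 3)
    return out


def make_hollow_shell(
    interior_radius: float = 3.0,
    n_atoms: int = 400,
    seed: int = 0,
) -> Structure:
    """Closed carbon shell whose probe-accessible interior cavity has the
    given radius (atom centres sit at interior_radius + r_vdw(C) + r_probe).

    The analytic cavity volume 4/3·π·interior_radius³ is the oracle for the
    grid cavity scanner.
    """
    shell_radius = interior_radius + 1.70 + 1.4
    rng = np.random.default_rng(seed)
    # Fibonacci sphere: near-uniform coverage, deterministic
    idx = np.arange(n_atoms) + 0.5
    phi = np.arccos(1 - 2 * idx / n_atoms)
    theta = np.pi * (1 + 5 ** 0.5) * idx
    pts = shell_radius * np.stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ], axis=1)
    pts = pts + rng.normal(0, 1e-3, pts.shape)  # break exact grid alignment
    res = Residue("S", 1, "SHL", [
        _mkatom(f"C{i+1}", "C", p) for i, p in enumerate(pts)
    ], is_hetero=True)
    return _structure_from_residues("hollow_shell", [res])


def make_s7_microsite(gate_deg: float = 0.0, seed: int = 0) -> Structure:
    """Synthetic miniature of the WIN-adjacent hydrophobic subsite.

    A cup of scaffold alanine pseudo-residues encloses a cavity around the
    origin with a mouth along +z. Anchor residues named like the real subsite
    (Phe133, Phe149, Pro173, Tyr191) sit on the rim so the site-definition
    arithmetic applies unchanged. The tyrosine ring covers the mouth at
    ``gate_deg`` = 0 (closed gate) and swings out of the cavity as the ring
    rotates about its CB–CG axis, so cavity volume grows monotonically with
    the gate angle. This is a synthetic stand-in for the deposited open/closed
    reference structures, used for calibration and unit tests.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    # --- cup wall: dense pseudo-atom shell minus a polar cap (mouth at +z)
    shell_radius = 6.6
    n_wall = 320
    idx = np.arange(n_wall) + 0.5
    phi = np.arccos(1 - 2 * idx / n_wall)
    theta = np.pi * (1 + 5 ** 0.5) * idx
    pts = shell_radius * np.stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ], axis=1)
    mouth_half_angle = np.radians(40.0)
    wall = pts[np.arccos(np.clip(pts[:, 2] / shell_radius, -1, 1)) > mouth_half_angle]
    wall = wall + rng.normal(0, 1e-3, wall.shape)
    atoms_per_res = 12
    seq = 300
    for start in range(0, len(wall), atoms_per_res):
        block = wall[start:start + atoms_per_res]
        residues.append(Residue("A", seq, "ALA", [
            _mkatom(f"C{i+1}", "C", p) for i, p in enumerate(block)
        ]))
        seq += 1

    # --- anchors on the rim; placed so their centroid sits near the origin
    def ring_at(center: np.ndarray, normal: np.ndarray, seq_id: int) -> Residue:
        normal = normal / np.linalg.norm(normal)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        atoms = []
        for i, name in enumerate(names):
            th = np.radians(60.0 * i)
            atoms.append(_mkatom(name, "C",
                                 center + 1.39 * (np.cos(th) * u + np.sin(th) * v)))
        atoms.append(_mkatom("CB", "C", center + 2.5 * normal))
        return Residue("A", seq_id, "PHE", atoms)

    residues.append(ring_at(np.array([-7.8, 0.0, 1.0]), np.array([-1.0, 0.0, 0.5]), 133))
    residues.append(ring_at(np.array([7.8, 0.0, 1.0]), np.array([1.0, 0.0, 0.5]), 149))
    residues.append(Residue("A", 173, "PRO", [
        _mkatom("N", "N", [0.0, -7.9, 0.3]),
        _mkatom("CA", "C", [0.0, -8.4, -1.0]),
        _mkatom("CB", "C", [0.4, -9.8, -1.0]),
    ]))

    # --- the tyrosine gate: CB-CG axis along x, ring hanging over the mouth
    tyr = build_tyrosine("A", 191, chi1=-60.0, chi2=90.0)
    # move it so CG sits above the rim and the ring covers the mouth (+z cap)
    cg0 = tyr.coord("CG")
    cb0 = tyr.coord("CB")
    axis0 = cg0 - cb0
    # rotate the residue so the CB->CG axis is +x and the ring normal is +z
    normal0 = _ring_normal(tyr)
    rot1 = _frame_rotation(axis0, normal0)
    for atom in tyr.atoms:
        atom.coords = rot1 @ (atom.coords - cg0)
    shift = np.array([-2.1, 0.0, 4.6])
    for atom in tyr.atoms:
        atom.coords = atom.coords + shift
    # base the gate on the ring-in-pocket state: at gate 0 the ring dips
    # through the mouth and occupies the cavity (closed, as the real switch
    # residue does); increasing gate_deg swings it out above the rim (open)
    axis = tyr.coord("CG") - tyr.coord("CB")
    rot = rotation_about_axis(axis, 90.0 - gate_deg)
    pivot = tyr.coord("CG")
    for atom in tyr.atoms:
        if atom.name in RING_MOBILE_ATOMS:
            atom.coords = rot @ (atom.coords - pivot) + pivot
    residues.append(tyr)
    residues.sort(key=lambda r: r.seq_id)
    return _structure_from_residues(f"s7_microsite_{gate_deg:g}", residues)


def _ring_normal(res: Residue) -> np.ndarray:
    pts = np.array([res.coord(n) for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")])
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    return vt[2]


def _frame_rotation(axis_from: np.ndarray, normal_from: np.ndarray) -> np.ndarray:
    """Rotation taking ``axis_from`` to +x and ``normal_from`` (⊥ component)
    to +z."""
    x = axis_from / np.linalg.norm(axis_from)
    z = normal_from - np.dot(normal_from, x) * x
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    return np.linalg.inv(np.stack([x, y, z], axis=1))


def make_thermogram(
    path: str | Path,
    setup: TitrationSetup | None = None,
    n: float = 0.91,
    k_d: float = 0.78e-6,
    dh: float = -15.7,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """Simulate a single-site titration and serialize it as TSV.

    Defaults reproduce the wild-type WDR5–Kif2A titration conditions
    (0.05 mM cell, ~1 mM syringe, 1 μL + 19 × 2 μL schedule, 20 °C).
    """
    setup = setup or TitrationSetup()
    tg = simulate_thermogram(setup, n=n, k_d=k_d, dh=dh, noise_sd=noise_sd, seed=seed)
    tg.to_tsv(path)
    return tg


def make_all_fixtures(directory: str | Path, seed: int = 0) -> list[Path]:
    """Materialize the full fixture corpus (PDB files + thermogram TSVs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(structure: Structure, name: str) -> None:
        p = directory / f"{name}.pdb"
        write_structure(structure, p, format="pdb")
        written.append(p)

    ref, rot = make_tyrosine_pair(ring_rotation_deg=25.0, seed=seed)
    save(ref, "tyrosine_ref")
    save(rot, "tyrosine_rot25")
    for kind in ("hbond_pair", "salt_bridge_pair", "cation_pi", "water_bridge"):
        save(make_interaction_fixture(kind, seed=seed), kind)
    save(make_hollow_shell(seed=seed), "hollow_shell")
    save(make_s7_microsite(0.0, seed=seed), "s7_gate_closed")
    save(make_s7_microsite(80.0, seed=seed), "s7_gate_open")
    tsv = directory / "thermogram_wt.tsv"
    make_thermogram(tsv, seed=seed)
    written.append(tsv)
    return written
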