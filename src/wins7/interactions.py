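"""Typed protein–peptide interaction enumeration.

Detects hydrogen bonds, salt bridges, cation-π contacts, van der Waals
contacts and water-mediated bridges between two atom selections using
heavy-atom geometric criteria (the deposited structures are ~1.6–1.9 Å and
carry no hydrogens). Thresholds live in :class:`InteractionCriteria` and are
deliberately standard; every finder is symmetric in its two selections and
monotone in its distance cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import Atom, Residue, Selection, Structure, select

RING_DEFS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# side-chain polar atom roles per standard residue
_SIDECHAIN_ROLES = {
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TYR": {"OH": "both"},
    "CYS": {"SG": "donor"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "LYS": {"NZ": "donor"},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "HIS": {"ND1": "both", "NE2": "both"},
    "TRP": {"NE1": "donor"},
    "MET": {"SD": "acceptor"},
}
_STANDARD_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# donor heavy atom -> antecedent used for the angle rule
_ANTECEDENTS = {
    "N": "CA",
    "OG": "CB", "OG1": "CB", "OH": "CZ", "SG": "CB",
    "ND2": "CG", "NE2": "CD", "NZ": "CE",
    "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "ND1": "CG", "NE1": "CE2",
}
# His NE2 antecedent differs from Gln's
_ANTECEDENTS_BY_RES = {("HIS", "NE2"): "CD2", ("HIS", "ND1"): "CG"}

CATIONIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ANIONIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
# cationic group centres for cation-π
CATION_CENTERS = {"ARG": "CZ", "LYS": "NZ"}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


@dataclass
class InteractionCriteria:
    """Heavy-atom geometric thresholds (Å / degrees) for contact typing."""

    hbond_max_da: float = 3.5
    hbond_min_angle: float = 90.0
    salt_bridge_max: float = 4.0
    vdw_max: float = 4.0
    vdw_min: float = 3.0
    cation_pi_max_centroid: float = 6.0
    cation_pi_min_elevation: float = 45.0
    water_contact_max: float = 3.5
    water_aromatic_max: float = 3.6
    site_radius: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "hbond_max_da", "salt_bridge_max", "vdw_max", "vdw_min",
            "cation_pi_max_centroid", "water_contact_max", "site_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vdw_min >= self.vdw_max:
            raise ValueError("vdw_min must be below vdw_max")


@dataclass
class InteractionRecord:
    """One typed contact between two fully-qualified atoms."""

    kind: str  # hbond | salt_bridge | cation_pi | vdw | water_bridge
    partner_a: str
    partner_b: str
    distance: float
    waters: list[str] = field(default_factory=list)
    geometry_notes: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "partner_a": self.partner_a,
            "partner_b": self.partner_b,
            "distance": round(self.distance, 3),
            "waters": ";".join(self.waters),
            "geometry_notes": self.geometry_notes,
        }


def atom_id(res: Residue, atom: Atom) -> str:
    return f"{res.chain_id}/{res.res_name}{res.seq_id}/{atom.name}"


def _ordered(id_a: str, id_b: str) -> tuple[str, str]:
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


def donors_acceptors(residue: Residue) -> dict[str, str]:
    """Map each polar heavy atom of a residue to 'donor', 'acceptor' or 'both'.

    Covers the standard amino acids (backbone N donor except proline, carbonyl
    O and terminal OXT acceptors, the usual side-chain polar atoms) and water
    (O is both). Nonstandard residues trigger a warning and contribute nothing.
    """
    if residue.is_water:
        return {"O": "both"} if residue.has_atom("O") else {}
    if residue.res_name not in _STANDARD_RES:
        warnings.warn(
            f"no donor/acceptor typing for residue {residue.res_name}; skipped",
            stacklevel=2,
        )
        return {}
    roles: dict[str, str] = {}
    if residue.has_atom("N") and residue.res_name != "PRO":
        roles["N"] = "donor"
    if residue.has_atom("O"):
        roles["O"] = "acceptor"
    if residue.has_atom("OXT"):
        roles["OXT"] = "acceptor"
    for name, role in _SIDECHAIN_ROLES.get(residue.res_name, {}).items():
        if residue.has_atom(name):
            roles[name] = role
    return roles


def _antecedent_coord(res: Residue, donor_name: str) -> np.ndarray | None:
    name = _ANTECEDENTS_BY_RES.get((res.res_name, donor_name)) or _ANTECEDENTS.get(
        donor_name
    )
    if name is None or not res.has_atom(name):
        return None
    return res.coord(name)


def _polar_atoms(pairs: list[tuple[Residue, Atom]]):
    """(residue, atom, role) triples for polar heavy atoms of a selection."""
    out = []
    seen_residues: dict[tuple, dict[str, str]] = {}
    for res, atom in pairs:
        key = res.key + (res.res_name,)
        if key not in seen_residues:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seen_residues[key] = donors_acceptors(res)
        role = seen_residues[key].get(atom.name)
        if role is not None:
            out.append((res, atom, role))
    return out


def _resolve(structure: Structure, sel) -> list[tuple[Residue, Atom]]:
    if isinstance(sel, (str, Selection)):
        sel = select(structure, sel)
    return [(r, a) for r, a in sel if a.element.upper() not in ("H", "D")]


def find_hbonds(
    structure: Structure, sel_a, sel_b, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Donor–acceptor heavy-atom pairs within ``hbond_max_da``.

    The angle rule requires antecedent–donor–acceptor ≥ ``hbond_min_angle``
    and is skipped when the donor has no antecedent (water). Output is
    symmetric in the two selections.
    """
    criteria = criteria or InteractionCriteria()
    polar_a = _polar_atoms(_resolve(structure, sel_a))
    polar_b = _polar_atoms(_resolve(structure, sel_b))
    records: dict[tuple[str, str], InteractionRecord] = {}
    for donors, acceptors, swapped in (
        (polar_a, polar_b, False),
        (polar_b, polar_a, True),
    ):
        don = [(r, a) for r, a, role in donors if role in ("donor", "both")]
        acc = [(r, a) for r, a, role in acceptors if role in ("acceptor", "both")]
        if not don or not acc:
            continue
        tree = cKDTree(np.array([a.coords for _, a in acc]))
        for res_d, atom_d in don:
            for j in tree.query_ball_point(atom_d.coords, criteria.hbond_max_da):
                res_a_, atom_a_ = acc[j]
                if res_d.key == res_a_.key:
                    continue
                dist = float(np.linalg.norm(atom_d.coords - atom_a_.coords))
                ante = _antecedent_coord(res_d, atom_d.name)
                if ante is not None:
                    ang = _angle(ante, atom_d.coords, atom_a_.coords)
                    if ang < criteria.hbond_min_angle:
                        continue
                    note = f"donor={atom_id(res_d, atom_d)} angle={ang:.1f}"
                else:
                    note = f"donor={atom_id(res_d, atom_d)}"
                ids = _ordered(atom_id(res_d, atom_d), atom_id(res_a_, atom_a_))
                if ids not in records or dist < records[ids].distance:
                    records[ids] = InteractionRecord(
                        kind="hbond",
                        partner_a=ids[0],
                        partner_b=ids[1],
                        distance=dist,
                        geometry_notes=note,
                    )
    return sorted(records.values(), key=lambda r: (r.partner_a, r.partner_b))


def _angle(p_ante: np.ndarray, p_donor: np.ndarray, p_acc: np.ndarray) -> float:
    v1 = p_ante - p_donor
    v2 = p_acc - p_donor
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def find_salt_bridges(
    structure: Structure, sel_a, sel_b, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Cationic-nitrogen vs carboxylate-oxygen pairs within ``salt_bridge_max``."""
    criteria = criteria or InteractionCriteria()
    atoms_a = _resolve(structure, sel_a)
    atoms_b = _resolve(structure, sel_b)
    records: dict[tuple[str, str], InteractionRecord] = {}
    for cations, anions in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        cat = [
            (r, a) for r, a in cations
            if a.name in CATIONIC_ATOMS.get(r.res_name, ())
        ]
        ani = [
            (r, a) for r, a in anions
            if a.name in ANIONIC_ATOMS.get(r.res_name, ()) or a.name == "OXT"
        ]
        for res_c, atom_c in cat:
            for res_n, atom_n in ani:
                dist = float(np.linalg.norm(atom_c.coords - atom_n.coords))
                if dist <= criteria.salt_bridge_max:
                    ids = _ordered(atom_id(res_c, atom_c), atom_id(res_n, atom_n))
                    if ids not in records:
                        records[ids] = InteractionRecord(
                            kind="salt_bridge",
                            partner_a=ids[0],
                            partner_b=ids[1],
                            distance=dist,
                        )
    return sorted(records.values(), key=lambda r: (r.partner_a, r.partner_b))


def ring_centroid_normal(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    names = RING_DEFS.get(res.res_name)
    if names is None or not all(res.has_atom(n) for n in names):
        return None
    pts = np.array([res.coord(n) for n in names])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2] / np.linalg.norm(vt[2])


def find_cation_pi(
    structure: Structure, sel_a, sel_b, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Cationic group centres near aromatic ring faces.

    A contact requires the centre (Arg CZ for the guanidinium, Lys NZ) within
    ``cation_pi_max_centroid`` of the ring centroid and an elevation above the
    ring plane of at least ``cation_pi_min_elevation`` degrees.
    """
    criteria = criteria or InteractionCriteria()
    atoms_a = _resolve(structure, sel_a)
    atoms_b = _resolve(structure, sel_b)
    records: dict[tuple[str, str], InteractionRecord] = {}
    for cations, aromatics in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        cat = [
            (r, a) for r, a in cations
            if CATION_CENTERS.get(r.res_name) == a.name
        ]
        ring_residues: dict[tuple, Residue] = {}
        for r, _ in aromatics:
            if r.res_name in RING_DEFS:
                ring_residues.setdefault(r.key + (r.res_name,), r)
        for res_c, atom_c in cat:
            for res_r in ring_residues.values():
                geom = ring_centroid_normal(res_r)
                if geom is None:
                    continue
                centroid, normal = geom
                v = atom_c.coords - centroid
                dist = float(np.linalg.norm(v))
                if dist > criteria.cation_pi_max_centroid or dist == 0:
                    continue
                elevation = float(
                    np.degrees(np.arcsin(np.clip(abs(np.dot(v, normal)) / dist, 0, 1)))
                )
                if elevation < criteria.cation_pi_min_elevation:
                    continue
                ring_id = f"{res_r.chain_id}/{res_r.res_name}{res_r.seq_id}/ring"
                ids = _ordered(atom_id(res_c, atom_c), ring_id)
                if ids not in records:
                    records[ids] = InteractionRecord(
                        kind="cation_pi",
                        partner_a=ids[0],
                        partner_b=ids[1],
                        distance=dist,
                        geometry_notes=f"elevation={elevation:.1f}",
                    )
    return sorted(records.values(), key=lambda r: (r.partner_a, r.partner_b))


def find_vdw_contacts(
    structure: Structure, sel_a, sel_b, criteria: InteractionCriteria | None = None
) -> list[InteractionRecord]:
    """Apolar (C/S) heavy-atom pairs with distance in [vdw_min, vdw_max],
    deduplicated per residue pair keeping the closest atom pair."""
    criteria = criteria or InteractionCriteria()
    apolar_a = [(r, a) for r, a in _resolve(structure, sel_a) if a.element.upper() in ("C", "S")]
    apolar_b = [(r, a) for r, a in _resolve(structure, sel_b) if a.element.upper() in ("C", "S")]
    if not apolar_a or not apolar_b:
        return []
    tree = cKDTree(np.array([a.coords for _, a in apolar_b]))
    best: dict[tuple, InteractionRecord] = {}
    for res_a_, atom_a_ in apolar_a:
        for j in tree.query_ball_point(atom_a_.coords, criteria.vdw_max):
            res_b_, atom_b_ = apolar_b[j]
            if res_a_.key == res_b_.key:
                continue
            dist = float(np.linalg.norm(atom_a_.coords - atom_b_.coords))
            if dist < criteria.vdw_min:
                continue
            res_pair = tuple(sorted([res_a_.key + (res_a_.res_name,),
                                     res_b_.key + (res_b_.res_name,)]))
            pa, pb = _ordered(atom_id(res_a_, atom_a_), atom_id(res_b_, atom_b_))
            rec = InteractionRecord(kind="vdw", partner_a=pa, partner_b=pb, distance=dist)
            if res_pair not in best or dist < best[res_pair].distance:
                best[res_pair] = rec
    return sorted(best.values(), key=lambda r: (r.partner_a, r.partner_b))


def find_water_bridges(
    structure: Structure,
    sel_a,
    sel_b,
    site_center: np.ndarray,
    criteria: InteractionCriteria | None = None,
) -> list[InteractionRecord]:
    """Ordered waters inside the site sphere that stitch the interface together.

    A water qualifies when its oxygen lies within ``site_radius`` of
    ``site_center`` and makes at least two polar contacts
    (≤ ``water_contact_max``) to non-water atoms, at least one of them inside
    the two selections. Site membership, not strict a↔b bridging, drives the
    census: waters linking peptide atoms to each other, or sitting on an
    aromatic face, belong to the network. Water–aromatic proximity
    (O ≤ ``water_aromatic_max`` from a ring centroid) is recorded as a
    geometry note.
    """
    criteria = criteria or InteractionCriteria()
    site_center = np.asarray(site_center, dtype=float)
    waters = [
        res for res in structure.residues()
        if res.is_water and res.has_atom("O")
        and np.linalg.norm(res.coord("O") - site_center) <= criteria.site_radius
    ]
    if not any(res.is_water for res in structure.residues()):
        warnings.warn("structure contains no waters; empty bridge list", stacklevel=2)
        return []
    sel_atoms = _resolve(structure, sel_a) + _resolve(structure, sel_b)
    sel_ids = {id(a) for _, a in sel_atoms}
    polar = [
        (res, atom)
        for res, atom, _role in _polar_atoms(
            [(r, a) for r, a in structure.atoms() if not r.is_water]
        )
    ]
    if not polar:
        return []
    tree = cKDTree(np.array([a.coords for _, a in polar]))
    # ring geometry for the aromatic-face note
    rings = []
    for res in structure.residues():
        geom = ring_centroid_normal(res)
        if geom is not None:
            rings.append((res, geom[0]))
    records = []
    for water in waters:
        ow = water.coord("O")
        contacts = []
        for j in tree.query_ball_point(ow, criteria.water_contact_max):
            res_p, atom_p = polar[j]
            contacts.append((res_p, atom_p, float(np.linalg.norm(ow - atom_p.coords))))
        if len(contacts) < 2:
            continue
        if not any(id(atom_p) in sel_ids for _, atom_p, _ in contacts):
            continue
        contacts.sort(key=lambda c: c[2])
        bridged = [atom_id(r, a) for r, a, _ in contacts]
        notes = []
        for res_r, centroid in rings:
            d_ring = float(np.linalg.norm(ow - centroid))
            if d_ring <= criteria.water_aromatic_max:
                notes.append(
                    f"aromatic-face {res_r.res_name}{res_r.seq_id} at {d_ring:.2f} Å"
                )
        water_id = f"{water.chain_id}/HOH{water.seq_id}"
        records.append(
            InteractionRecord(
                kind="water_bridge",
                partner_a=bridged[0],
                partner_b=bridged[1],
                distance=contacts[0][2],
                waters=[water_id],
                geometry_notes="; ".join(
                    [f"bridges {len(bridged)} polar atoms"] + notes
                ),
            )
        )
    return sorted(records, key=lambda r: r.waters[0])


class InteractionTable:
    """Union of all typed contacts, serialisable as a tidy table."""

    def __init__(self, records: list[InteractionRecord]):
        self.records = records

    @property
    def df(self) -> pd.DataFrame:
        cols = ["kind", "partner_a", "partner_b", "distance", "waters", "geometry_notes"]
        if not self.records:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([r.to_dict() for r in self.records])[cols]

    def by_kind(self, kind: str) -> list[InteractionRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.df.to_json(path, orient="records", indent=2)

    def __len__(self) -> int:
        return len(self.records)


def fingerprint(
    structure: Structure,
    sel_a,
    sel_b,
    criteria: InteractionCriteria | None = None,
    site_center: np.ndarray | None = None,
) -> InteractionTable:
    """Full interface fingerprint: union of every contact kind, sorted by
    partner then kind. Water bridges are included when a site centre is given."""
    criteria = criteria or InteractionCriteria()
    records: list[InteractionRecord] = []
    records += find_hbonds(structure, sel_a, sel_b, criteria)
    records += find_salt_bridges(structure, sel_a, sel_b, criteria)
    records += find_cation_pi(structure, sel_a, sel_b, criteria)
    records += find_vdw_contacts(structure, sel_a, sel_b, criteria)
    if site_center is not None:
        records += find_water_bridges(structure, sel_a, sel_b, site_center, criteria)
    records.sort(key=lambda r: (r.partner_a, r.kind, r.partner_b))
    return InteractionTable(records)
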