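"""Residue matching and Kabsch least-squares rigid-body superposition.

All side-chain rotation comparisons in this package are made in a common
β-propeller frame obtained by superposing Cα atoms of matched WDR5 residues
(author range 31–334 by default, the modelled propeller). Superposition is
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structures import Chain, Structure, StructureError

# default Cα superposition window: the modelled WDR5 propeller
PROPELLER_RANGE = (31, 334)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class SuperpositionError(Exception):
    pass


@dataclass
class ResiduePairList:
    """One-to-one residue correspondence between two chains."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    scheme: str = "by_author_number"


@dataclass
class SuperpositionResult:
    """Rigid transform x ↦ R·x + t mapping frame A onto frame B, with fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    n_atoms: int
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise SuperpositionError("rotation matrix is not proper orthogonal")

    def transform_points(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "SuperpositionResult":
        rot_inv = self.rotation.T
        return SuperpositionResult(
            rotation=rot_inv,
            translation=-rot_inv @ self.translation,
            n_atoms=self.n_atoms,
            rmsd=self.rmsd,
        )

    @classmethod
    def identity(cls) -> "SuperpositionResult":
        return cls(np.eye(3), np.zeros(3), 0, 0.0)

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "n_atoms": self.n_atoms,
            "rmsd": self.rmsd,
        }


def match_residues(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str,
    chain_b: str,
    scheme: str = "by_author_number",
) -> ResiduePairList:
    """Pair residues of two chains, either by shared author numbers or by
    global sequence alignment (identity scoring, affine gaps; only aligned
    identical positions are kept)."""
    ca = struct_a.chain(chain_a)
    cb = struct_b.chain(chain_b)
    if scheme == "by_author_number":
        ids_b = {r.seq_id for r in cb.residues if not r.is_water}
        pairs = [
            ((chain_a, r.seq_id), (chain_b, r.seq_id))
            for r in ca.residues
            if not r.is_water and r.seq_id in ids_b
        ]
    elif scheme == "by_alignment":
        pairs = _align_pairs(ca, cb, chain_a, chain_b)
    else:
        raise SuperpositionError(f"unknown matching scheme: {scheme!r}")
    if not pairs:
        raise SuperpositionError(
            f"no residues in common between {chain_a} and {chain_b}"
        )
    return ResiduePairList(pairs=pairs, scheme=scheme)


def _align_pairs(ca: Chain, cb: Chain, id_a: str, id_b: str):
    res_a = [r for r in ca.residues if r.res_name in THREE_TO_ONE]
    res_b = [r for r in cb.residues if r.res_name in THREE_TO_ONE]
    seq_a = "".join(THREE_TO_ONE[r.res_name] for r in res_a)
    seq_b = "".join(THREE_TO_ONE[r.res_name] for r in res_b)
    if not seq_a or not seq_b:
        return []
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            if seq_a[i] == seq_b[j]:
                pairs.append(((id_a, res_a[i].seq_id), (id_b, res_b[j].seq_id)))
    return pairs


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid transform of point set A onto point set B (SVD solution).

    Returns the proper rotation R and translation t minimising
    RMSD(R·A + t, B), together with the minimised RMSD. Requires at least
    three non-collinear points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError("coordinate arrays must both be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    a0 = a - cen_a
    b0 = b - cen_b
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    # points collinear (or coincident) when two singular values vanish
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise SuperpositionError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cen_b - rot @ cen_a
    rmsd = float(np.sqrt(np.mean(np.sum((a0 @ rot.T - b0) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, n_atoms=n, rmsd=rmsd)


def apply_transform(structure: Structure, result: SuperpositionResult) -> Structure:
    """Return a copy with every atom mapped through the rigid transform."""
    out = structure.copy()
    for _, atom in out.atoms():
        atom.coords = result.rotation @ atom.coords + result.translation
    return out


def superpose_chains(
    struct_a: Structure,
    struct_b: Structure,
    chain_a: str,
    chain_b: str,
    resi_range: tuple[int, int] | None = PROPELLER_RANGE,
    scheme: str = "by_author_number",
    atom_name: str | None = "CA",
) -> SuperpositionResult:
    """Cα superposition of matched residues of two chains (A onto B).

    ``atom_name=None`` uses every atom name shared by a residue pair instead
    of a single atom type (useful for non-peptidic or reduced models).
    """
    pairs = match_residues(struct_a, struct_b, chain_a, chain_b, scheme=scheme)
    ca = struct_a.chain(chain_a)
    cb = struct_b.chain(chain_b)
    pts_a, pts_b = [], []
    for (_, seq_a), (_, seq_b) in pairs.pairs:
        if resi_range is not None and not (resi_range[0] <= seq_a <= resi_range[1]):
            continue
        ra, rb = ca.residue(seq_a), cb.residue(seq_b)
        if atom_name is None:
            names_b = {a.name for a in rb.atoms}
            for atom in ra.atoms:
                if atom.name in names_b:
                    pts_a.append(atom.coords)
                    pts_b.append(rb.coord(atom.name))
        elif ra.has_atom(atom_name) and rb.has_atom(atom_name):
            pts_a.append(ra.coord(atom_name))
            pts_b.append(rb.coord(atom_name))
    if len(pts_a) < 3:
        raise SuperpositionError("fewer than 3 matched atoms for superposition")
    return kabsch(np.array(pts_a), np.array(pts_b))


def best_copy_superposition(
    struct_a: Structure,
    struct_b: Structure,
    chains_a: list[str],
    chains_b: list[str],
    **kwargs,
) -> tuple[tuple[str, str], SuperpositionResult, dict[tuple[str, str], SuperpositionResult]]:
    """Superpose every chain-pair between two structures with multiple
    receptor copies; the headline pair is the one minimising RMSD, and all
    pairs are reported alongside."""
    results: dict[tuple[str, str], SuperpositionResult] = {}
    for a_id in chains_a:
        for b_id in chains_b:
            try:
                results[(a_id, b_id)] = superpose_chains(
                    struct_a, struct_b, a_id, b_id, **kwargs
                )
            except SuperpositionError:
                continue
    if not results:
        raise SuperpositionError("no chain pair could be superposed")
    best = min(results, key=lambda k: results[k].rmsd)
    return best, results[best], results
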