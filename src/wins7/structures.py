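"""Coordinate data model and PDB/mmCIF I/O.

A deliberately small hierarchy (Structure -> Model -> Chain -> Residue -> Atom)
holds exactly what the downstream geometry needs: author residue numbering,
altlocs with occupancies, element symbols and Cartesian coordinates in Å.
Parsing and serialisation are delegated to gemmi; this module owns the
in-memory representation and the selection language.

Waters are first-class residues — the water-network analysis depends on them —
and are never dropped on read. Hydrogens, when present, are kept, but every
geometric criterion elsewhere in the package is defined on heavy atoms.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Raised for unreadable files, unknown formats or malformed selections."""


@dataclass
class Atom:
    """One atom site. Coordinates are Å, occupancy a fraction in [0, 1]."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}"
            )


@dataclass
class Residue:
    """A residue addressed by author numbering (chain id, seq id, insertion code)."""

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    is_hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def atom(self, name: str) -> Atom:
        """Return the named atom; raises if absent (geometry code relies on this)."""
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(
            f"atom {name} missing from {self.res_name} {self.chain_id}{self.seq_id}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord(self, name: str) -> np.ndarray:
        return self.atom(name).coords

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_id: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id and r.insertion_code == insertion_code:
                return r
        raise StructureError(f"residue {seq_id}{insertion_code} not in chain {self.chain_id}")

    def has_residue(self, seq_id: int, insertion_code: str = "") -> bool:
        return any(
            r.seq_id == seq_id and r.insertion_code == insertion_code for r in self.residues
        )


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"chain {chain_id} not present")

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError("duplicate chain ids within a model")


@dataclass
class Structure:
    """Hierarchical coordinate model: models -> chains -> residues -> atoms."""

    id: str
    models: list[Model] = field(default_factory=list)
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            self.models = [Model()]

    @property
    def first_model(self) -> Model:
        return self.models[0]

    def chain(self, chain_id: str) -> Chain:
        return self.first_model.chain(chain_id)

    def residues(self) -> Iterator[Residue]:
        for model in self.models:
            for chain in model.chains:
                yield from chain.residues

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

@dataclass
class Selection:
    """Declarative atom filter; combining criteria is conjunctive.

    Built either directly from fields or parsed from a compact expression,
    e.g. ``"chain A and resi 114-122 and name CA"``, ``"water"``,
    ``"protein and element C"``. Applying a selection twice is idempotent
    because it is a pure filter.
    """

    chain: str | None = None
    resi: list[tuple[int, int]] | None = None  # inclusive ranges
    res_name: str | None = None
    atom_name: str | None = None
    element: str | None = None
    water: bool | None = None
    hetero: bool | None = None

    @classmethod
    def parse(cls, expression: str) -> "Selection":
        sel = cls()
        expression = expression.strip()
        if not expression or expression == "all":
            return sel
        for token in re.split(r"\s+and\s+", expression):
            token = token.strip()
            parts = token.split()
            if token == "water":
                sel.water = True
            elif token == "not water":
                sel.water = False
            elif token == "protein":
                sel.water = False
                sel.hetero = False
            elif token == "hetero":
                sel.hetero = True
            elif len(parts) == 2 and parts[0] in {"chain", "resn", "name", "element", "resi"}:
                key, value = parts
                if key == "chain":
                    sel.chain = value
                elif key == "resn":
                    sel.res_name = value.upper()
                elif key == "name":
                    sel.atom_name = value.upper()
                elif key == "element":
                    sel.element = value.upper()
                else:
                    sel.resi = _parse_ranges(value)
            else:
                raise StructureError(f"malformed selection token: {token!r}")
        return sel

    def matches(self, res: Residue, atom: Atom) -> bool:
        if self.chain is not None and res.chain_id != self.chain:
            return False
        if self.resi is not None and not any(lo <= res.seq_id <= hi for lo, hi in self.resi):
            return False
        if self.res_name is not None and res.res_name != self.res_name:
            return False
        if self.atom_name is not None and atom.name != self.atom_name:
            return False
        if self.element is not None and atom.element.upper() != self.element:
            return False
        if self.water is not None and res.is_water != self.water:
            return False
        if self.hetero is not None and (res.is_hetero and not res.is_water) != self.hetero:
            return False
        return True


def _parse_ranges(ranges_str: str) -> list[tuple[int, int]]:
    ranges = []
    for part in ranges_str.split(","):
        if "-" in part[1:]:  # allow negative seq ids
            lo_s, hi_s = part.rsplit("-", 1)
            ranges.append((int(lo_s), int(hi_s)))
        else:
            v = int(part)
            ranges.append((v, v))
    return ranges


def select(structure: Structure, selection: Selection | str) -> list[tuple[Residue, Atom]]:
    """Atoms (with residue context) matching the selection, in file order."""
    if isinstance(selection, str):
        selection = Selection.parse(selection)
    return [(res, atom) for res, atom in structure.atoms() if selection.matches(res, atom)]


# ---------------------------------------------------------------------------
# I/O via gemmi
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the package hierarchy.

    Author numbering is preserved as the canonical addressing scheme and
    waters are retained. ``format`` may be ``pdb``, ``mmcif`` or ``auto``
    (extension-based detection).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    fmt = _coord_format(format, path)
    try:
        gst = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    gst.setup_entities()
    return _from_gemmi(gst, path.stem)


def _coord_format(format: str, path: Path) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        return gemmi.CoorFormat.Detect
    raise StructureError(f"unknown coordinate format: {format!r}")


def _from_gemmi(gst: gemmi.Structure, fallback_id: str) -> Structure:
    models = []
    for gmodel in gst:
        chains = []
        for gchain in gmodel:
            residues = []
            for gres in gchain:
                res = Residue(
                    chain_id=gchain.name,
                    seq_id=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or " ").strip(),
                    res_name=gres.name,
                    is_hetero=gres.het_flag == "H",
                )
                for gatom in gres:
                    res.atoms.append(
                        Atom(
                            name=gatom.name,
                            element=gatom.element.name,
                            coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                            occupancy=min(max(gatom.occ, 0.0), 1.0),
                            altloc=gatom.altloc.strip("\x00") if gatom.altloc else "",
                            b_factor=gatom.b_iso,
                        )
                    )
                residues.append(res)
            chains.append(Chain(chain_id=gchain.name, residues=residues))
        models.append(Model(chains=chains))
    sid = gst.name.strip() or fallback_id
    title = gst.info["_struct.title"] if "_struct.title" in gst.info else ""
    return Structure(id=sid, models=models, metadata=title)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    gst = gemmi.Structure()
    gst.name = structure.id
    for i, model in enumerate(structure.models, start=1):
        gmodel = gemmi.Model(i)
        for chain in model.chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
                gres.het_flag = "H" if (res.is_hetero or res.is_water) else "A"
                for atom in res.atoms:
                    gatom = gemmi.Atom()
                    gatom.name = atom.name
                    gatom.element = gemmi.Element(atom.element)
                    gatom.pos = gemmi.Position(*atom.coords)
                    gatom.occ = atom.occupancy
                    gatom.altloc = atom.altloc or "\x00"
                    gatom.b_iso = atom.b_factor
                    gres.add_atom(gatom)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        gst.add_model(gmodel)
    gst.setup_entities()
    return gst


def write_structure(structure: Structure, path: str | Path, format: str = "auto") -> None:
    """Write PDB (coords to 3 decimals; hybrid-36 serials past 99999 atoms)
    or mmCIF (full precision)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    gst = _to_gemmi(structure)
    if format == "pdb":
        gst.write_pdb(str(path))
    elif format in ("mmcif", "cif"):
        doc = gst.make_mmcif_document()
        doc.write_file(str(path))
    else:
        raise StructureError(f"unknown coordinate format: {format!r}")


def resolve_altlocs(structure: Structure, policy: str = "highest_occupancy") -> Structure:
    """Collapse alternate locations to a single conformer per atom.

    The surviving location is the one with the highest occupancy; exact ties
    are broken by altloc letter order (A beats B). Atoms without altlocs pass
    through untouched.
    """
    if policy != "highest_occupancy":
        raise StructureError(f"unknown altloc policy: {policy!r}")
    out = structure.copy()
    for res in out.residues():
        best: dict[str, Atom] = {}
        order: list[str] = []
        for atom in res.atoms:
            if atom.name not in best:
                best[atom.name] = atom
                order.append(atom.name)
            else:
                cur = best[atom.name]
                if (atom.occupancy, _altloc_rank(atom)) > (cur.occupancy, _altloc_rank(cur)):
                    best[atom.name] = atom
        for atom in best.values():
            atom.altloc = ""
            atom.occupancy = 1.0 if atom.occupancy > 0 else atom.occupancy
        res.atoms = [best[name] for name in order]
    return out


def _altloc_rank(atom: Atom) -> int:
    # 'A' must outrank 'B' when occupancies tie, so invert the letter order
    return -ord(atom.altloc) if atom.altloc else 0


def heavy_atoms(structure: Structure) -> list[tuple[Residue, Atom]]:
    """All non-hydrogen atoms with residue context."""
    return [(r, a) for r, a in structure.atoms() if a.element.upper() not in ("H", "D")]
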