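"""WIN / S7 site geometry and open-closed classification.

The S7 subsite of the WDR5 β-propeller is a cryptic hydrophobic pocket walled
by Phe133, Phe149, Pro173 and Tyr191; it opens when Tyr191 swings away and
closes when the ring swings back. The publications describing it show the
pocket only as rendered surfaces, so this module uses a deterministic,
oracle-checkable quantitative proxy: probe-accessible cavity volume on a grid
inside a site-anchored sphere, with a ray-casting burial test. Classification
is a volume threshold calibrated as the midpoint between an open and a closed
reference structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .interactions import VDW_RADII, ring_centroid_normal
from .rotation import sidechain_rotation
from .structures import Selection, Structure, StructureError, select
from .superpose import SuperpositionError, superpose_chains

DEFAULT_PROBE_RADIUS = 1.4     # Å, water probe
DEFAULT_GRID_SPACING = 0.5     # Å
BURIAL_MIN_BLOCKED = 4         # of 6 axis-aligned rays
S7_RADIUS = 6.0                # Å, scan sphere for the S7 subsite
WIN_RADIUS = 4.0               # Å, the arginine channel is narrow


class SiteError(Exception):
    pass


@dataclass
class SiteDefinition:
    name: str
    anchor_residues: list[tuple[int, str]]
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise SiteError("site center must be finite")


def site_definition(structure: Structure, name: str, chain_id: str | None = None) -> SiteDefinition:
    """Geometric definition of the WIN or S7 site from its anchor residues.

    S7: centroid of {Phe133 ring centroid, Phe149 ring centroid, Pro173 CA,
    Tyr191 CB}. WIN: centroid of the backbone carbonyl O of Ser91, Phe133 and
    Cys261 (the atoms that coordinate the WIN-motif arginine).
    """
    if name == "S7":
        anchors = [(133, "ring"), (149, "ring"), (173, "CA"), (191, "CB")]
        radius = S7_RADIUS
    elif name == "WIN":
        anchors = [(91, "O"), (133, "O"), (261, "O")]
        radius = WIN_RADIUS
    else:
        raise SiteError(f"unknown site name: {name!r}")
    chain = _resolve_chain(structure, chain_id, anchors)
    points = []
    used = []
    for seq_id, what in anchors:
        if not chain.has_residue(seq_id):
            raise SiteError(f"anchor residue {seq_id} missing from chain {chain.chain_id}")
        res = chain.residue(seq_id)
        if what == "ring":
            geom = ring_centroid_normal(res)
            if geom is None:
                raise SiteError(f"anchor residue {seq_id} has no complete ring")
            points.append(geom[0])
        else:
            if not res.has_atom(what):
                raise SiteError(f"anchor atom {what} missing from residue {seq_id}")
            points.append(res.coord(what))
        used.append((seq_id, res.res_name))
    return SiteDefinition(
        name=name,
        anchor_residues=used,
        center=np.mean(points, axis=0),
        radius=radius,
    )


def _resolve_chain(structure: Structure, chain_id: str | None, anchors):
    if chain_id is not None:
        return structure.chain(chain_id)
    want = {seq for seq, _ in anchors}
    for chain in structure.first_model.chains:
        have = {r.seq_id for r in chain.residues}
        if want <= have:
            return chain
    raise SiteError("no chain carries all anchor residues")


def pocket_volume(
    structure: Structure,
    site: SiteDefinition,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    exclude_selection: Selection | str | None = "water",
) -> float:
    """Probe-accessible, buried cavity volume (Å³) inside the site sphere.

    A grid point counts toward the cavity when (a) it lies inside the site
    sphere, (b) no retained heavy atom is closer than its van der Waals
    radius plus ``probe_radius``, and (c) it is buried — an axis-aligned ray
    test finds it blocked by protein in at least 4 of the 6 directions.
    Peptide ligands, compounds and waters should be excluded via
    ``exclude_selection`` so the measurement reflects the protein pocket, not
    its occupancy. The grid is anchored to the site centre, making the volume
    invariant to rigid motions of the whole structure.
    """
    excluded: set[int] = set()
    if exclude_selection is not None:
        excluded = {id(a) for _, a in select(structure, exclude_selection)}
    atoms = [
        (res, a) for res, a in structure.atoms()
        if a.element.upper() not in ("H", "D") and id(a) not in excluded
    ]
    if not atoms:
        warnings.warn("no atoms retained for the cavity scan", stacklevel=2)
        return 0.0
    coords = np.array([a.coords for _, a in atoms])
    radii = np.array([VDW_RADII.get(a.element.upper(), 1.7) for _, a in atoms])

    # restrict the ray test to atoms near the site; rays are cast far enough
    # to see the whole retained molecule
    near = np.linalg.norm(coords - site.center, axis=1) < (site.radius + 30.0)
    coords_near = coords[near]
    radii_near = radii[near]

    # site-anchored grid
    n_side = int(np.floor(site.radius / grid_spacing))
    axis = np.arange(-n_side, n_side + 1) * grid_spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + site.center
    pts = pts[np.linalg.norm(pts - site.center, axis=1) <= site.radius]
    if pts.size == 0:
        warnings.warn("site sphere contains no grid points", stacklevel=2)
        return 0.0

    # (b) empty: no atom within vdw + probe
    tree = cKDTree(coords)
    max_reach = radii.max() + probe_radius
    empty = np.ones(len(pts), dtype=bool)
    for i, p in enumerate(pts):
        for j in tree.query_ball_point(p, max_reach):
            if np.linalg.norm(p - coords[j]) < radii[j] + probe_radius:
                empty[i] = False
                break
    candidates = pts[empty]
    if candidates.size == 0:
        return 0.0

    # (c) burial by 6-ray occlusion
    blocked_counts = np.zeros(len(candidates), dtype=int)
    directions = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]
    ], dtype=float)
    for d in directions:
        # atom blocks the ray when it lies ahead of the point and its centre
        # is within its vdw radius of the ray line
        rel = coords_near[None, :, :] - candidates[:, None, :]   # (npts, natoms, 3)
        along = rel @ d                                          # (npts, natoms)
        perp_sq = np.einsum("ijk,ijk->ij", rel, rel) - along ** 2
        hits = (along > 0) & (perp_sq < (radii_near ** 2)[None, :])
        blocked_counts += hits.any(axis=1).astype(int)
    buried = blocked_counts >= BURIAL_MIN_BLOCKED
    return float(buried.sum()) * grid_spacing ** 3


# ---------------------------------------------------------------------------
# calibration and classification
# ---------------------------------------------------------------------------

@dataclass
class Calibration:
    """Open/closed reference volumes and the midpoint decision threshold."""

    open_volume: float
    closed_volume: float
    open_id: str = ""
    closed_id: str = ""

    @property
    def threshold(self) -> float:
        return (self.open_volume + self.closed_volume) / 2.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "open_volume_A3": self.open_volume,
            "closed_volume_A3": self.closed_volume,
            "threshold_A3": self.threshold,
            "open_id": self.open_id,
            "closed_id": self.closed_id,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        d = json.loads(Path(path).read_text())
        return cls(
            open_volume=d["open_volume_A3"],
            closed_volume=d["closed_volume_A3"],
            open_id=d.get("open_id", ""),
            closed_id=d.get("closed_id", ""),
        )


def calibrate(
    open_structure: Structure,
    closed_structure: Structure,
    exclude_selection: Selection | str | None = "water",
    **volume_kwargs,
) -> Calibration:
    """Compute the midpoint threshold from an open and a closed reference.

    With local copies of the deposited open (Kif2A-bound) and closed
    (arginine-bound) entries this recomputes the shipped constants; it works
    identically on the synthetic gate fixtures.
    """
    vols = {}
    for role, structure in (("open", open_structure), ("closed", closed_structure)):
        site = site_definition(structure, "S7")
        vols[role] = pocket_volume(
            structure, site, exclude_selection=exclude_selection, **volume_kwargs
        )
    return Calibration(
        open_volume=vols["open"],
        closed_volume=vols["closed"],
        open_id=open_structure.id,
        closed_id=closed_structure.id,
    )


@lru_cache(maxsize=1)
def synthetic_calibration() -> Calibration:
    """Calibration from the package's own synthetic tyrosine-gate microsite
    (open gate at 80°, closed at 0°). Synthetic stand-in for the deposited
    references; recompute with :func:`calibrate` when local copies exist."""
    from .synthetic import make_s7_microsite

    return calibrate(make_s7_microsite(80.0), make_s7_microsite(0.0))


@dataclass
class PocketReport:
    volume: float
    state: str
    tyr191_rotation_vs_reference: float
    reference_id: str
    threshold: float
    structure_id: str = ""

    def to_dict(self) -> dict:
        return {
            "structure": self.structure_id,
            "volume_A3": round(self.volume, 2),
            "state": self.state,
            "tyr191_rotation_vs_reference_deg": round(
                self.tyr191_rotation_vs_reference, 2
            ),
            "reference": self.reference_id,
            "threshold_A3": round(self.threshold, 2),
        }


def classify_s7(
    structure: Structure,
    reference_structure: Structure,
    calibration: Calibration | None = None,
    chain_id: str | None = None,
    reference_chain_id: str | None = None,
    switch_residue: int = 191,
    exclude_selection: Selection | str | None = "water",
    **volume_kwargs,
) -> PocketReport:
    """Open/closed call for the S7 site plus the switch-residue rotation
    against the (closed) reference structure.

    ``state`` is "open" iff the cavity volume exceeds the calibration
    midpoint. The rotation is measured in the common propeller frame obtained
    by Cα superposition of the reference onto the structure.
    """
    if reference_structure is None:
        raise SiteError("classification requires a closed reference structure")
    calibration = calibration or synthetic_calibration()
    site = site_definition(structure, "S7", chain_id=chain_id)
    volume = pocket_volume(
        structure, site, exclude_selection=exclude_selection, **volume_kwargs
    )
    state = "open" if volume > calibration.threshold else "closed"

    chain = _resolve_chain(structure, chain_id, [(switch_residue, "")])
    ref_chain = _resolve_chain(reference_structure, reference_chain_id,
                               [(switch_residue, "")])
    rotation = 0.0
    if structure is reference_structure and chain is ref_chain:
        rotation = 0.0
    else:
        try:
            try:
                frame = superpose_chains(
                    reference_structure, structure,
                    ref_chain.chain_id, chain.chain_id,
                    resi_range=None,
                )
            except SuperpositionError:
                # reduced models without enough Cα: use all shared atoms
                frame = superpose_chains(
                    reference_structure, structure,
                    ref_chain.chain_id, chain.chain_id,
                    resi_range=None, atom_name=None,
                )
            report = sidechain_rotation(
                structure, reference_structure,
                (chain.chain_id, switch_residue),
                (ref_chain.chain_id, switch_residue),
                frame,
            )
            rotation = report.ring_plane_angle
        except (SuperpositionError, StructureError) as exc:
            warnings.warn(f"rotation vs reference unavailable: {exc}", stacklevel=2)
            rotation = float("nan")
    return PocketReport(
        volume=volume,
        state=state,
        tyr191_rotation_vs_reference=rotation,
        reference_id=reference_structure.id,
        threshold=calibration.threshold,
        structure_id=structure.id,
    )
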