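"""Hydrogen-bond role assignment, minimal hydrogen placement, and
geometric hydrogen-bond detection.

A hydrogen bond is accepted when the donor-heavy-atom to
acceptor-heavy-atom distance is at most ``distDA`` and, in
``with-hydrogens`` mode, some hydrogen covalently attached to the donor
gives a donor-H-acceptor angle inside the applicable range.  All three
angle ranges (``anglePDWA``, ``anglePAWD``, ``angleWW``) are measured at
the hydrogen, between the H->donor and H->acceptor vectors, so an ideal
linear D-H...A bond scores 180 deg.  Each water oxygen may donate and
accept at most two hydrogen bonds; excess bonds are pruned longest
first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Structure, select

logger = logging.getLogger(__name__)

__all__ = [
    "Criteria",
    "HydrogenBond",
    "assign_roles",
    "place_missing_hydrogens",
    "detect_hbond",
    "hbond_graph",
    "attached_hydrogens",
]

#: Covalent O-H / N-H bond-length ceiling used to associate hydrogens
#: with their heavy atom (Å).
COVALENT_H_CUTOFF = 1.25

# donor/acceptor chemistry of the standard amino acids; backbone entries
# apply to every residue.  Side-chain hydroxyls/amines with rotatable,
# typically unresolved hydrogens are listed separately so that H-free
# inputs can fall back to distance-only acceptance for those atoms.
_BACKBONE_ROLES = {"N": "donor", "O": "acceptor", "OXT": "acceptor"}
_SIDECHAIN_ROLES: dict[tuple[str, str], str] = {
    ("SER", "OG"): "both",
    ("THR", "OG1"): "both",
    ("TYR", "OH"): "both",
    ("ASP", "OD1"): "acceptor",
    ("ASP", "OD2"): "acceptor",
    ("GLU", "OE1"): "acceptor",
    ("GLU", "OE2"): "acceptor",
    ("LYS", "NZ"): "donor",
    ("ARG", "NE"): "donor",
    ("ARG", "NH1"): "donor",
    ("ARG", "NH2"): "donor",
    ("HIS", "ND1"): "both",
    ("HIS", "NE2"): "both",
    ("ASN", "OD1"): "acceptor",
    ("ASN", "ND2"): "donor",
    ("GLN", "OE1"): "acceptor",
    ("GLN", "NE2"): "donor",
    ("CYS", "SG"): "both",
    ("MET", "SD"): "acceptor",
    ("TRP", "NE1"): "donor",
}
_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
#: Donor atoms whose hydrogens are rotatable and usually absent from
#: crystal structures; they are accepted on distance alone when no
#: hydrogen is present.
ROTATABLE_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"),
}


def _angle_range(value) -> tuple[float, float]:
    lo, hi = float(value[0]), float(value[1])
    lo, hi = lo % 360.0, hi % 360.0
    if lo > 180.0 or hi > 180.0:
        raise ValueError("angle range must lie within [0, 180] degrees")
    if lo > hi:
        raise ValueError("angle range lower bound exceeds upper bound")
    return (lo, hi)


@dataclass(frozen=True)
class Criteria:
    """Geometric thresholds and mode flags for bridge detection.

    distDA : Å, maximum donor to acceptor heavy-atom distance.
    distWR : Å, maximum water-oxygen to protein-polar-atom distance
        defining the residue-water interaction shell (reporting only;
        bridge edges use distDA).
    anglePDWA / anglePAWD / angleWW : degree ranges for protein-donor ->
        water-acceptor, water-donor -> protein-acceptor and water ->
        water bonds, measured at the hydrogen.
    maxDepth : maximum number of waters in a bridging path.
    angle_mode : "with-hydrogens", "angle-free", or "auto" (resolved to
        with-hydrogens when the input carries any hydrogen).
    """

    distDA: float = 3.5
    distWR: float = 4.0
    anglePDWA: tuple[float, float] = (100.0, 180.0)
    anglePAWD: tuple[float, float] = (100.0, 180.0)
    angleWW: tuple[float, float] = (140.0, 180.0)
    maxDepth: int = 2
    angle_mode: str = "auto"
    max_donated_per_water: int = 2
    max_accepted_per_water: int = 2

    def __post_init__(self) -> None:
        if self.distDA <= 0 or self.distWR <= 0:
            raise ValueError("distDA and distWR must be positive")
        if self.maxDepth < 1:
            raise ValueError("maxDepth must be at least 1")
        if self.angle_mode not in ("auto", "with-hydrogens", "angle-free"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")
        for name in ("anglePDWA", "anglePAWD", "angleWW"):
            object.__setattr__(self, name, _angle_range(getattr(self, name)))

    def resolve(self, structure: Structure) -> "Criteria":
        """Fix angle_mode='auto' based on whether hydrogens exist."""
        if self.angle_mode != "auto":
            return self
        has_h = any(a.is_hydrogen for a in structure.atoms)
        return replace(
            self, angle_mode="with-hydrogens" if has_h else "angle-free"
        )


@dataclass(frozen=True)
class HydrogenBond:
    """One accepted donor->acceptor contact with its geometry."""

    donor_atom: int
    acceptor_atom: int
    distance_DA: float
    hydrogen_atom: int | None = None
    angle_DHA: float | None = None
    kind: str = "protein-water"  # or water-water / protein-protein


_warned_resnames: set[str] = set()


def assign_roles(structure: Structure) -> list[str]:
    """Per-atom donor/acceptor role: 'donor', 'acceptor', 'both' or 'none'.

    Water oxygens are both; protein N/O/S atoms follow the built-in
    residue chemistry table.  N/O/S atoms of residues absent from the
    table are conservatively assigned 'both' (logged once per residue
    name).
    """
    roles: list[str] = []
    for atom in structure.atoms:
        if atom.is_hydrogen:
            roles.append("none")
            continue
        if atom.is_water:
            roles.append("both" if atom.element == "O" else "none")
            continue
        if atom.element not in ("N", "O", "S"):
            roles.append("none")
            continue
        resname = atom.resname.upper()
        role = _SIDECHAIN_ROLES.get((resname, atom.name))
        if role is None:
            role = _BACKBONE_ROLES.get(atom.name)
        if role is None:
            if resname in _STANDARD_RESNAMES:
                role = "none"  # e.g. a mislabeled carbon; stay silent
            else:
                if resname not in _warned_resnames:
                    _warned_resnames.add(resname)
                    logger.warning(
                        "unknown residue %s: assigning donor+acceptor to "
                        "its N/O/S atoms", resname,
                    )
                role = "both"
        roles.append(role)
    return roles


def attached_hydrogens(
    structure: Structure, frame: np.ndarray | int = 0
) -> dict[int, list[int]]:
    """Map heavy-atom index -> covalently attached hydrogen indices.

    Attachment means: same residue and within 1.25 Å in the given frame.
    """
    coords = structure.coords[frame] if isinstance(frame, int) else frame
    heavy_by_res: dict[tuple, list[int]] = {}
    h_by_res: dict[tuple, list[int]] = {}
    for i, atom in enumerate(structure.atoms):
        key = (atom.chain, atom.resnum, atom.resname)
        (h_by_res if atom.is_hydrogen else heavy_by_res).setdefault(
            key, []
        ).append(i)
    out: dict[int, list[int]] = {}
    for key, hydrogens in h_by_res.items():
        heavies = heavy_by_res.get(key, [])
        if not heavies:
            continue
        for h in hydrogens:
            d = np.linalg.norm(coords[heavies] - coords[h], axis=1)
            j = int(np.argmin(d))
            if d[j] <= COVALENT_H_CUTOFF:
                out.setdefault(heavies[j], []).append(h)
    return out


def _dha_angle(coords: np.ndarray, donor: int, h: int, acceptor: int) -> float:
    """Angle at the hydrogen between H->donor and H->acceptor (degrees)."""
    v1 = coords[donor] - coords[h]
    v2 = coords[acceptor] - coords[h]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _bond_kind(d_atom: Atom, a_atom: Atom) -> str:
    if d_atom.is_water and a_atom.is_water:
        return "water-water"
    if d_atom.is_water or a_atom.is_water:
        return "protein-water"
    return "protein-protein"


def _applicable_range(kind: str, d_atom: Atom, criteria: Criteria):
    if kind == "water-water":
        return criteria.angleWW
    if kind == "protein-water":
        return criteria.anglePAWD if d_atom.is_water else criteria.anglePDWA
    return criteria.anglePDWA


def detect_hbond(
    structure: Structure,
    donor: int,
    acceptor: int,
    frame: np.ndarray | int = 0,
    criteria: Criteria | None = None,
    h_map: dict[int, list[int]] | None = None,
) -> HydrogenBond | None:
    """Evaluate one donor->acceptor pair against the criteria.

    Returns the accepted :class:`HydrogenBond` (reporting the hydrogen
    with the largest D-H-A angle) or ``None``.  Donor and acceptor must
    belong to different residues.  In with-hydrogens mode a donor with
    no attached hydrogen is rejected with a logged notice, except for
    rotatable side-chain donors (Ser/Thr/Tyr OH, Lys NZ) which fall back
    to distance-only acceptance.
    """
    coords = structure.coords[frame] if isinstance(frame, int) else frame
    crit = (criteria or Criteria()).resolve(structure)
    d_atom, a_atom = structure.atoms[donor], structure.atoms[acceptor]
    if (d_atom.chain, d_atom.resnum) == (a_atom.chain, a_atom.resnum):
        return None
    dist = float(np.linalg.norm(coords[donor] - coords[acceptor]))
    if dist > crit.distDA:
        return None
    kind = _bond_kind(d_atom, a_atom)
    if crit.angle_mode == "angle-free":
        return HydrogenBond(donor, acceptor, dist, kind=kind)
    if h_map is None:
        h_map = attached_hydrogens(structure, coords)
    hydrogens = h_map.get(donor, [])
    if not hydrogens:
        if (d_atom.resname.upper(), d_atom.name) in ROTATABLE_DONORS:
            return HydrogenBond(donor, acceptor, dist, kind=kind)
        logger.debug(
            "donor %s %s%d %s has no attached hydrogen; pair rejected",
            d_atom.resname, d_atom.chain, d_atom.resnum, d_atom.name,
        )
        return None
    lo, hi = _applicable_range(kind, d_atom, crit)
    best: tuple[float, int] | None = None
    for h in hydrogens:
        ang = _dha_angle(coords, donor, h, acceptor)
        if lo <= ang <= hi and (best is None or ang > best[0]):
            best = (ang, h)
    if best is None:
        return None
    return HydrogenBond(
        donor, acceptor, dist, hydrogen_atom=best[1], angle_DHA=best[0],
        kind=kind,
    )


def hbond_graph(
    structure: Structure,
    frame: int = 0,
    criteria: Criteria | None = None,
) -> list[HydrogenBond]:
    """All hydrogen bonds among protein polar atoms and water oxygens.

    Candidate pairs within ``distDA`` are found with a k-d tree (no
    all-pairs scan), each direction evaluated independently, then the
    per-water valence cap (at most 2 donated and 2 accepted per water
    oxygen) is enforced by discarding the longest excess bonds.
    Protein-protein bonds are kept in the list, flagged by their
    ``kind``; they are not bridge edges.
    """
    crit = (criteria or Criteria()).resolve(structure)
    coords = structure.coords[frame]
    roles = assign_roles(structure)
    h_map = (
        attached_hydrogens(structure, coords)
        if crit.angle_mode == "with-hydrogens"
        else {}
    )
    candidates = sorted(
        set(select(structure, "protein-polar-heavy"))
        | set(select(structure, "water-oxygen"))
    )
    candidates = [i for i in candidates if roles[i] != "none"]
    if not candidates:
        return []
    tree = cKDTree(coords[candidates])
    pairs = tree.query_pairs(r=crit.distDA, output_type="ndarray")
    bonds: list[HydrogenBond] = []
    for ia, ib in pairs:
        i, j = candidates[int(ia)], candidates[int(ib)]
        for donor, acceptor in ((i, j), (j, i)):
            if roles[donor] not in ("donor", "both"):
                continue
            if roles[acceptor] not in ("acceptor", "both"):
                continue
            hb = detect_hbond(
                structure, donor, acceptor, coords, crit, h_map=h_map
            )
            if hb is not None:
                bonds.append(hb)
    bonds.sort(key=lambda b: (b.donor_atom, b.acceptor_atom))
    return _prune_water_valence(structure, bonds, crit)


def _prune_water_valence(
    structure: Structure, bonds: list[HydrogenBond], criteria: Criteria
) -> list[HydrogenBond]:
    """Keep at most 2 donated and 2 accepted bonds per water oxygen.

    Candidates per water are ranked by distance ascending (ties by the
    partner atom index); excess bonds are removed entirely.
    """
    donated: dict[int, list[HydrogenBond]] = {}
    accepted: dict[int, list[HydrogenBond]] = {}
    for hb in bonds:
        if structure.atoms[hb.donor_atom].is_water:
            donated.setdefault(hb.donor_atom, []).append(hb)
        if structure.atoms[hb.acceptor_atom].is_water:
            accepted.setdefault(hb.acceptor_atom, []).append(hb)
    drop: set[int] = set()
    for group, cap, partner in (
        (donated, criteria.max_donated_per_water, lambda b: b.acceptor_atom),
        (accepted, criteria.max_accepted_per_water, lambda b: b.donor_atom),
    ):
        for hbs in group.values():
            if len(hbs) <= cap:
                continue
            ranked = sorted(hbs, key=lambda b: (b.distance_DA, partner(b)))
            drop.update(id(b) for b in ranked[cap:])
    return [b for b in bonds if id(b) not in drop]


# ---------------------------------------------------------------------------
# minimal hydrogen placement

_WATER_OH = 0.96  # Å
_WATER_HOH = math.radians(104.5)


def _water_h_positions(
    o_pos: np.ndarray, toward: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if toward is None or np.linalg.norm(toward - o_pos) < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = toward - o_pos
        u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = ref - np.dot(ref, u) * u
    w = w / np.linalg.norm(w)
    h1 = o_pos + _WATER_OH * u
    h2 = o_pos + _WATER_OH * (math.cos(_WATER_HOH) * u + math.sin(_WATER_HOH) * w)
    return h1, h2


def place_missing_hydrogens(structure: Structure) -> Structure:
    """Add two hydrogens to every water that lacks them.

    O-H = 0.96 Å, H-O-H = 104.5 deg; the first hydrogen points toward
    the nearest acceptor heavy atom within ``distDA`` when one exists
    (per frame), otherwise along a fixed arbitrary direction.  Protein
    donors are never modified; structures that already carry water
    hydrogens are returned unchanged.
    """
    roles = assign_roles(structure)
    h_count: dict[tuple, int] = {}
    water_o: dict[tuple, int] = {}
    for i, atom in enumerate(structure.atoms):
        if not atom.is_water:
            continue
        key = (atom.chain, atom.resnum, atom.resname)
        if atom.is_hydrogen:
            h_count[key] = h_count.get(key, 0) + 1
        elif atom.element == "O":
            water_o[key] = i
    bare = [
        (key, oi) for key, oi in water_o.items() if h_count.get(key, 0) == 0
    ]
    if not bare:
        return structure

    crit = Criteria()
    acceptor_idx = np.array(
        [
            i
            for i, a in enumerate(structure.atoms)
            if roles[i] in ("acceptor", "both")
        ],
        dtype=int,
    )
    atoms = list(structure.atoms)
    n_frames = structure.n_frames
    new_cols: list[tuple[int, Atom, np.ndarray]] = []  # (insert-after, atom, coords)
    serial = max((a.serial for a in atoms), default=0)
    for key, oi in sorted(bare, key=lambda kv: kv[1]):
        o_atom = structure.atoms[oi]
        h_coords = np.empty((2, n_frames, 3))
        for f in range(n_frames):
            coords = structure.coords[f]
            others = acceptor_idx[acceptor_idx != oi]
            toward = None
            if others.size:
                d = np.linalg.norm(coords[others] - coords[oi], axis=1)
                j = int(np.argmin(d))
                if d[j] <= crit.distDA:
                    toward = coords[others[j]]
            h1, h2 = _water_h_positions(coords[oi], toward)
            h_coords[0, f], h_coords[1, f] = h1, h2
        for k in range(2):
            serial += 1
            new_cols.append(
                (
                    oi,
                    Atom(
                        serial=serial,
                        name=f"H{k + 1}",
                        element="H",
                        resname=o_atom.resname,
                        resnum=o_atom.resnum,
                        chain=o_atom.chain,
                        is_water=True,
                        is_hydrogen=True,
                    ),
                    h_coords[k],
                )
            )

    # splice the new atoms in right after their oxygens
    insert_after: dict[int, list[tuple[Atom, np.ndarray]]] = {}
    for oi, atom, xyz in new_cols:
        insert_after.setdefault(oi, []).append((atom, xyz))
    out_atoms: list[Atom] = []
    out_cols: list[np.ndarray] = []
    for i, atom in enumerate(atoms):
        out_atoms.append(atom)
        out_cols.append(structure.coords[:, i, :])
        for new_atom, xyz in insert_after.get(i, []):
            out_atoms.append(new_atom)
            out_cols.append(xyz)
    coords = np.stack(out_cols, axis=1)
    return Structure(out_atoms, coords, structure.frame_labels)
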