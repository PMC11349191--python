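"""Structure and trajectory I/O with a uniform atom/coordinate data model.

PDB and mmCIF files are parsed through :mod:`gemmi`; multi-MODEL files
become multi-frame :class:`Structure` objects sharing one atom table.
Binary DCD trajectories (NAMD/CHARMM layout) are read and written
directly, honouring the 4-byte Fortran record markers and accepting both
byte orders.  Coordinates are always in Å.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ParseError",
    "WATER_RESNAMES",
    "parse_pdb",
    "parse_mmcif",
    "write_pdb",
    "read_dcd",
    "write_dcd",
    "select",
    "residue_id",
]

#: Residue names recognised as water (PDB plus common MD force-field
#: conventions); matching is case-insensitive.
WATER_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP", "TIP3", "TIP4", "SPC", "SOL", "H2O"}
)

#: Polar heavy elements considered hydrogen-bond capable on the protein side.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology.

    ``resnum`` and ``chain`` are preserved verbatim from the input for
    reporting; atom indexing is 0-based internally.
    """

    serial: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_water: bool = False
    is_hydrogen: bool = False


@dataclass
class Structure:
    """An atom table plus one or more coordinate frames sharing it.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å.
    """

    atoms: list[Atom]
    coords: np.ndarray
    frame_labels: list[int] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate frames carry {self.coords.shape[1]} atoms, "
                f"atom table has {len(self.atoms)}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("at least one coordinate frame is required")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, index: int) -> np.ndarray:
        return self.coords[index]

    def with_frames(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atoms, np.asarray(coords), self.frame_labels)


@dataclass
class Trajectory:
    """A topology plus lazily iterable coordinate frames.

    ``timestep`` is the time between stored frames in ps when known.
    """

    topology: Structure
    _frame_reader: Callable[[], Iterator[np.ndarray]]
    n_frames: int
    timestep: float | None = None

    def frames(self) -> Iterator[np.ndarray]:
        n_atoms = self.topology.n_atoms
        for i, frame in enumerate(self._frame_reader()):
            if frame.shape[0] != n_atoms:
                raise ParseError(
                    f"frame {i} has {frame.shape[0]} atoms, topology has {n_atoms}"
                )
            yield frame

    def __iter__(self) -> Iterator[np.ndarray]:
        return self.frames()

    def to_structure(self) -> Structure:
        """Materialise all frames into a multi-frame Structure."""
        coords = np.stack(list(self.frames()))
        return Structure(self.topology.atoms, coords)


def residue_id(atom: Atom) -> tuple[str, int, str]:
    """Hashable residue identity (chain, resnum, resname) of an atom."""
    return (atom.chain, atom.resnum, atom.resname)


# ---------------------------------------------------------------------------
# parsing via gemmi


def _element_of(gatom: gemmi.Atom) -> str:
    el = gatom.element.name.strip()
    if el and el != "X":
        return el.upper()
    # infer from the atom name: first alphabetic character, honouring the
    # PDB convention that names starting with a digit (e.g. 1H) are hydrogens
    name = gatom.name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _is_water_name(resname: str) -> bool:
    return resname.strip().upper() in WATER_RESNAMES


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, gemmi.Atom] = {}
    for gatom in residue:
        prev = by_name.get(gatom.name)
        if prev is None:
            by_name[gatom.name] = gatom
        else:
            key_new = (-gatom.occ, gatom.altloc or "~")
            key_old = (-prev.occ, prev.altloc or "~")
            if key_new < key_old:
                by_name[gatom.name] = gatom
    # preserve original atom order within the residue
    seen: set[str] = set()
    out = []
    for gatom in residue:
        if gatom.name in seen:
            continue
        seen.add(gatom.name)
        out.append(by_name[gatom.name])
    return out


def _structure_from_gemmi(gst: gemmi.Structure, source: str) -> Structure:
    if len(gst) == 0:
        raise ParseError(f"no ATOM/HETATM records found in {source} input")
    atoms: list[Atom] = []
    frames: list[np.ndarray] = []
    labels: list[int] = []
    first_model = gst[0]
    for chain in first_model:
        for residue in chain:
            resname = residue.name.strip()
            water = _is_water_name(resname)
            for gatom in _dedupe_altlocs(residue):
                element = _element_of(gatom)
                altloc = gatom.altloc if gatom.altloc.isalnum() else ""
                atoms.append(
                    Atom(
                        serial=gatom.serial,
                        name=gatom.name.strip(),
                        element=element,
                        resname=resname,
                        resnum=residue.seqid.num,
                        chain=chain.name,
                        altloc=altloc,
                        occupancy=float(gatom.occ),
                        bfactor=float(gatom.b_iso),
                        is_water=water,
                        is_hydrogen=element in ("H", "D"),
                    )
                )
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records found in {source} input")
    for model in gst:
        xyz = []
        for chain in model:
            for residue in chain:
                for gatom in _dedupe_altlocs(residue):
                    xyz.append([gatom.pos.x, gatom.pos.y, gatom.pos.z])
        if len(xyz) != len(atoms):
            raise ParseError(
                f"model {model.num} has {len(xyz)} atoms, "
                f"first model has {len(atoms)}"
            )
        frames.append(np.asarray(xyz, dtype=np.float64))
        labels.append(model.num)
    return Structure(atoms, np.stack(frames), frame_labels=labels)


def parse_pdb(text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Multi-MODEL files produce one coordinate frame per model; all models
    must share the first model's atom count.  Alternate locations are
    reduced to the highest-occupancy conformer (ties broken by altloc
    letter order).
    """
    if not any(
        line.startswith(("ATOM", "HETATM")) for line in text.splitlines()
    ):
        raise ParseError("no ATOM/HETATM records found in PDB input")
    gst = gemmi.read_pdb_string(text)
    return _structure_from_gemmi(gst, "PDB")


def _cif_column(block: gemmi.cif.Block, *names: str):
    for name in names:
        col = block.find_loop(f"_atom_site.{name}")
        values = list(col)
        if values:
            return values
    return None


def parse_mmcif(text: str) -> Structure:
    """Parse an mmCIF ``atom_site`` loop into a :class:`Structure`.

    Only the minimal atom_site columns (atom/residue/chain identity,
    model number, xyz, occupancy, B) are consumed; dictionary validation
    is out of scope.  ``pdbx_PDB_model_num`` groups rows into frames.
    """
    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"mmCIF parse failure: {exc}") from exc
    required = {
        "Cartn_x": _cif_column(block, "Cartn_x"),
        "Cartn_y": _cif_column(block, "Cartn_y"),
        "Cartn_z": _cif_column(block, "Cartn_z"),
        "label_atom_id": _cif_column(block, "label_atom_id", "auth_atom_id"),
        "label_comp_id": _cif_column(block, "label_comp_id", "auth_comp_id"),
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ParseError(
            "mmCIF atom_site loop is missing mandatory columns: "
            + ", ".join(f"_atom_site.{c}" for c in missing)
        )
    n = len(required["Cartn_x"])

    def col(*names, default=None):
        values = _cif_column(block, *names)
        if values is None:
            return [default] * n
        return values

    ids = col("id", default="0")
    atom_names = required["label_atom_id"]
    comps = required["label_comp_id"]
    asyms = col("auth_asym_id", "label_asym_id", default="A")
    seqs = col("auth_seq_id", "label_seq_id", default="1")
    alts = col("label_alt_id", default=".")
    occs = col("occupancy", default="1.0")
    bs = col("B_iso_or_equiv", default="0.0")
    elements = col("type_symbol", default="")
    models = col("pdbx_PDB_model_num", default="1")

    def _num(v, default=0):
        try:
            return int(v)
        except (TypeError, ValueError):
            return default

    # group rows by model, resolving altlocs within each residue+name
    model_order: list[str] = []
    rows_by_model: dict[str, list[int]] = {}
    for i in range(n):
        m = models[i]
        if m not in rows_by_model:
            rows_by_model[m] = []
            model_order.append(m)
        rows_by_model[m].append(i)

    def best_rows(rows: list[int]) -> list[int]:
        by_key: dict[tuple, int] = {}
        order: list[tuple] = []
        for i in rows:
            key = (asyms[i], seqs[i], comps[i], atom_names[i])
            if key not in by_key:
                by_key[key] = i
                order.append(key)
            else:
                j = by_key[key]
                new = (-float(occs[i] or 1.0), alts[i])
                old = (-float(occs[j] or 1.0), alts[j])
                if new < old:
                    by_key[key] = i
        return [by_key[k] for k in order]

    first_rows = best_rows(rows_by_model[model_order[0]])
    atoms: list[Atom] = []
    for i in first_rows:
        name = atom_names[i].strip('"')
        resname = comps[i].strip().upper()
        element = (elements[i] or "").strip().upper()
        if not element or element == "X":
            element = next((c for c in name if c.isalpha()), "C").upper()
        water = resname in WATER_RESNAMES
        atoms.append(
            Atom(
                serial=_num(ids[i], i + 1),
                name=name,
                element=element,
                resname=resname,
                resnum=_num(seqs[i], 1),
                chain=asyms[i],
                altloc="" if alts[i] in (".", "?", "") else alts[i],
                occupancy=float(occs[i] or 1.0),
                bfactor=float(bs[i] or 0.0),
                is_water=water,
                is_hydrogen=element in ("H", "D"),
            )
        )
    frames = []
    labels = []
    for m in model_order:
        rows = best_rows(rows_by_model[m])
        if len(rows) != len(atoms):
            raise ParseError(
                f"model {m} has {len(rows)} atoms, first model has "
                f"{len(atoms)}"
            )
        frames.append(
            np.array(
                [
                    [
                        float(required["Cartn_x"][i]),
                        float(required["Cartn_y"][i]),
                        float(required["Cartn_z"][i]),
                    ]
                    for i in rows
                ]
            )
        )
        labels.append(_num(m, len(labels) + 1))
    return Structure(atoms, np.stack(frames), frame_labels=labels)


# ---------------------------------------------------------------------------
# PDB writing


def _pdb_atom_name(name: str, element: str) -> str:
    # PDB v3.3 alignment: element right-justified in columns 13-14 for
    # one-letter elements with short names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(
    structure: Structure,
    frame: int | str = 0,
    bfactor_override: Sequence[float] | None = None,
) -> str:
    """Render a Structure as fixed-column PDB text.

    ``frame`` selects one coordinate frame, or ``"all"`` to emit every
    frame wrapped in MODEL/ENDMDL blocks.  ``bfactor_override`` replaces
    the B-factor column with per-atom values (used for 0-1 frequency
    colour coding).
    """
    if bfactor_override is not None:
        bfactor_override = list(bfactor_override)
        if len(bfactor_override) != structure.n_atoms:
            raise ValueError(
                f"bfactor_override has {len(bfactor_override)} values for "
                f"{structure.n_atoms} atoms"
            )
    if frame == "all":
        frame_indices = list(range(structure.n_frames))
    else:
        idx = int(frame)
        if not -structure.n_frames <= idx < structure.n_frames:
            raise IndexError(f"frame {idx} out of range")
        frame_indices = [idx]
    multi = len(frame_indices) > 1
    lines: list[str] = []
    for out_i, fi in enumerate(frame_indices):
        if multi:
            label = (
                structure.frame_labels[fi]
                if structure.frame_labels is not None
                else out_i + 1
            )
            lines.append(f"MODEL     {label:4d}")
        xyz = structure.coords[fi]
        for i, atom in enumerate(structure.atoms):
            record = "HETATM" if atom.is_water or atom.resname == "DUM" else "ATOM  "
            b = bfactor_override[i] if bfactor_override is not None else atom.bfactor
            serial = atom.serial if 0 < atom.serial < 100000 else (i + 1) % 100000
            lines.append(
                f"{record}{serial:5d} {_pdb_atom_name(atom.name, atom.element)}"
                f"{atom.altloc[:1] or ' '}{atom.resname:<3s} {atom.chain[:1] or 'A'}"
                f"{atom.resnum:4d}    "
                f"{xyz[i, 0]:8.3f}{xyz[i, 1]:8.3f}{xyz[i, 2]:8.3f}"
                f"{atom.occupancy:6.2f}{b:6.2f}          "
                f"{atom.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# DCD trajectories

_AKMA_PS = 0.04888821  # 1 AKMA time unit in ps


def _read_record(fh, endian: str) -> bytes:
    head = fh.read(4)
    if len(head) < 4:
        raise ParseError("truncated DCD file: missing record marker")
    (nbytes,) = struct.unpack(endian + "i", head)
    data = fh.read(nbytes)
    tail = fh.read(4)
    if len(data) < nbytes or len(tail) < 4:
        raise ParseError("truncated DCD record")
    (nbytes2,) = struct.unpack(endian + "i", tail)
    if nbytes2 != nbytes:
        raise ParseError("corrupt DCD record markers")
    return data


def read_dcd(path: str, topology: Structure) -> Trajectory:
    """Read a binary DCD trajectory (NAMD/CHARMM layout).

    Both little- and big-endian files are accepted; CHARMM unit-cell
    blocks are read and ignored.  Frames are yielded lazily in file
    order, in Å.
    """
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise ParseError("truncated DCD file: empty header")
        endian = "<"
        (marker,) = struct.unpack("<i", head)
        if marker != 84:
            (marker_be,) = struct.unpack(">i", head)
            if marker_be != 84:
                raise ParseError("not a DCD file: bad header record size")
            endian = ">"
        fh.seek(0)
        header = _read_record(fh, endian)
        if header[:4] != b"CORD":
            raise ParseError("not a DCD file: missing CORD magic")
        icntrl = struct.unpack(endian + "20i", header[4:84])
        n_frames = icntrl[0]
        nsavc = icntrl[2] or 1
        charmm_version = icntrl[19]
        has_cell = charmm_version != 0 and icntrl[10] != 0
        if charmm_version != 0:
            (delta,) = struct.unpack(endian + "f", header[4 + 9 * 4: 4 + 10 * 4])
        else:
            (delta,) = struct.unpack(endian + "d", header[4 + 9 * 4: 4 + 11 * 4])
        _read_record(fh, endian)  # title block
        natom_rec = _read_record(fh, endian)
        (n_atoms,) = struct.unpack(endian + "i", natom_rec[:4])
        if n_atoms != topology.n_atoms:
            raise ParseError(
                f"DCD carries {n_atoms} atoms but topology has "
                f"{topology.n_atoms}"
            )
        body_offset = fh.tell()
    timestep = delta * nsavc * _AKMA_PS if delta else None
    dtype = np.dtype(endian + "f4")

    def reader() -> Iterator[np.ndarray]:
        with open(path, "rb") as fh:
            fh.seek(body_offset)
            for fidx in range(n_frames):
                try:
                    if has_cell:
                        _read_record(fh, endian)
                    xs = np.frombuffer(_read_record(fh, endian), dtype=dtype)
                    ys = np.frombuffer(_read_record(fh, endian), dtype=dtype)
                    zs = np.frombuffer(_read_record(fh, endian), dtype=dtype)
                except ParseError as exc:
                    raise ParseError(
                        f"truncated DCD frame {fidx}: {exc}"
                    ) from exc
                if not len(xs) == len(ys) == len(zs) == n_atoms:
                    raise ParseError(f"truncated DCD frame {fidx}")
                yield np.stack(
                    [xs, ys, zs], axis=1
                ).astype(np.float64)

    return Trajectory(topology, reader, n_frames, timestep)


def write_dcd(
    path: str,
    coords: np.ndarray,
    timestep_ps: float | None = None,
    endian: str = "<",
) -> None:
    """Write frames (n_frames, n_atoms, 3) as a CHARMM-flavoured DCD file.

    Used by the fixture generator and tests; coordinates are stored in
    single precision, no unit-cell blocks.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    n_frames, n_atoms, _ = coords.shape
    delta = (timestep_ps / _AKMA_PS) if timestep_ps else 0.0

    def rec(payload: bytes) -> bytes:
        return struct.pack(endian + "i", len(payload)) + payload + struct.pack(
            endian + "i", len(payload)
        )

    icntrl = [0] * 20
    icntrl[0] = n_frames
    icntrl[1] = 1  # first step
    icntrl[2] = 1  # save interval
    icntrl[3] = n_frames
    icntrl[19] = 24  # CHARMM version flag
    header = b"CORD" + struct.pack(endian + "9i", *icntrl[:9])
    header += struct.pack(endian + "f", delta)
    header += struct.pack(endian + "10i", *icntrl[10:])
    title = b"* written by aquabridge".ljust(80)
    title_block = struct.pack(endian + "i", 1) + title
    with open(path, "wb") as fh:
        fh.write(rec(header))
        fh.write(rec(title_block))
        fh.write(rec(struct.pack(endian + "i", n_atoms)))
        dtype = np.dtype(endian + "f4")
        for frame in coords:
            for axis in range(3):
                fh.write(rec(frame[:, axis].astype(dtype).tobytes()))


# ---------------------------------------------------------------------------
# selections

_SELECTORS = (
    "protein-polar-heavy",
    "water-oxygen",
    "water-all",
    "hydrogens",
)


def select(
    structure: Structure,
    what: str | Callable[[Atom], bool],
) -> list[int]:
    """Return ascending atom indices matching a named selector.

    ``protein-polar-heavy`` selects N/O/S heavy atoms of non-water
    residues; a callable acts as a custom per-atom predicate.
    """
    if callable(what):
        pred = what
    elif what == "protein-polar-heavy":
        def pred(a: Atom) -> bool:
            return (
                not a.is_water
                and not a.is_hydrogen
                and a.element in POLAR_ELEMENTS
            )
    elif what == "water-oxygen":
        def pred(a: Atom) -> bool:
            return a.is_water and a.element == "O"
    elif what == "water-all":
        def pred(a: Atom) -> bool:
            return a.is_water
    elif what == "hydrogens":
        def pred(a: Atom) -> bool:
            return a.is_hydrogen
    else:
        raise ValueError(
            f"unknown selector {what!r}; expected one of {_SELECTORS} "
            "or a predicate"
        )
    return [i for i, a in enumerate(structure.atoms) if pred(a)]
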