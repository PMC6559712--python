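"""Peptide topology and trajectory data model with multi-model PDB I/O.

The model is deliberately small: a single peptide chain (residues numbered
from 1, matching the conventional Asp1...Lys16/Ala42 amyloid-beta labels)
plus at most one metal ion carried as a single-atom HETATM residue.
Coordinates are in angstroms, times in nanoseconds, and there is no
periodic box anywhere (implicit-solvent ensembles), so no distance ever
needs imaging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack, stack as _biotite_stack
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Frame",
    "Trajectory",
    "StructureError",
    "FormatError",
    "SelectionError",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "select",
]


class StructureError(ValueError):
    """Inconsistent molecular structure (e.g. atom counts differ between models)."""


class FormatError(ValueError):
    """Unparseable file content."""


class SelectionError(ValueError):
    """Invalid atom-selection expression."""


BACKBONE_NAMES = ("N", "CA", "C", "O")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# Side-chain polar atoms relevant to salt bridges and ion coordination.
ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_NITROGENS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "AL": 26.982, "FE": 55.845, "CU": 63.546, "ZN": 65.38,
}


def element_mass(element: str) -> float:
    return _MASSES.get(element.upper(), 12.011)


def guess_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB atom name (peptide + common ions)."""
    name = atom_name.strip()
    if name.upper() in ("AL", "FE", "CU", "ZN", "NA", "MG", "CL"):
        return name.upper().capitalize()
    stripped = name.lstrip("0123456789")
    return stripped[0].upper() if stripped else "C"


@dataclass(frozen=True)
class Atom:
    index: int                 # 0-based, unique within topology
    name: str                  # PDB atom name, e.g. CA, OD1
    element: str
    mass: float                # Da
    residue_index: int         # 1-based
    is_backbone: bool
    is_ion: bool = False


@dataclass
class Residue:
    index: int                 # 1-based
    name3: str
    charge_class: str = field(init=False)      # acidic | basic | neutral
    sidechain_polar_atoms: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name3 in ACIDIC_OXYGENS:
            self.charge_class = "acidic"
        elif self.name3 in BASIC_NITROGENS:
            self.charge_class = "basic"
        else:
            # His is deliberately neutral: only Asp/Glu vs Arg/Lys pairs
            # reproduce the 8 (16-mer) and 18 (40/42-mer) possible bridges.
            self.charge_class = "neutral"

    @property
    def label(self) -> str:
        """Conventional residue label, e.g. 'Glu11'."""
        return f"{self.name3.capitalize()}{self.index}"


class Topology:
    """Ordered residues and atoms of one peptide chain plus an optional ion."""

    def __init__(self, residues: list[Residue], atoms: list[Atom]):
        self.residues = residues
        self.atoms = atoms
        self._validate()
        self._index = {(a.residue_index, a.name): a.index for a in atoms}
        for res in self.residues:
            if res.name3 in ACIDIC_OXYGENS:
                names = ACIDIC_OXYGENS[res.name3]
            elif res.name3 in BASIC_NITROGENS:
                names = BASIC_NITROGENS[res.name3]
            else:
                continue
            res.sidechain_polar_atoms = [
                self._index[(res.index, n)]
                for n in names
                if (res.index, n) in self._index
            ]

    def _validate(self) -> None:
        indices = [r.index for r in self.residues]
        if indices != list(range(1, len(indices) + 1)):
            raise StructureError("residues must be contiguous and 1-based")
        known = set(indices)
        for atom in self.atoms:
            if atom.residue_index not in known:
                raise StructureError(
                    f"atom {atom.name} refers to missing residue {atom.residue_index}"
                )
            if atom.mass <= 0:
                raise StructureError(f"atom {atom.name} has non-positive mass")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        """Number of peptide residues (single-atom ion residues excluded)."""
        return len(self.peptide_residues)

    @property
    def peptide_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.name3 in AA_3TO1]

    @property
    def sequence(self) -> str:
        return "".join(AA_3TO1[r.name3] for r in self.peptide_residues)

    @property
    def ion_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_ion]

    def atom_index(self, residue_index: int, name: str) -> int:
        try:
            return self._index[(residue_index, name)]
        except KeyError:
            raise StructureError(
                f"no atom named {name!r} in residue {residue_index}"
            ) from None

    def residue(self, index: int) -> Residue:
        return self.residues[index - 1]

    def masses(self, indices=None) -> np.ndarray:
        atoms = self.atoms if indices is None else [self.atoms[i] for i in indices]
        return np.array([a.mass for a in atoms])

    def select(self, spec: str) -> list[int]:
        return select(self, spec)


@dataclass
class Frame:
    """One conformation: per-atom coordinates in angstroms."""

    coords: np.ndarray          # (n_atoms, 3)
    frame_index: int = 0
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("frame contains non-finite coordinates")


class Trajectory:
    """Ordered frames on a fixed topology with a time axis in nanoseconds."""

    def __init__(self, topology: Topology, coords: np.ndarray, dt_ns: float = 0.1,
                 times_ns: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError("trajectory coordinates must have shape (F, n_atoms, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise StructureError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        self.topology = topology
        self.coords = coords
        self.dt_ns = float(dt_ns)
        if times_ns is None:
            times_ns = np.arange(coords.shape[0]) * dt_ns
        self.times_ns = np.asarray(times_ns, dtype=float)
        if len(self.times_ns) != len(coords):
            raise StructureError("one time per frame required")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], frame_index=i, time_ns=self.times_ns[i])

    @property
    def frames(self):
        return [self.frame(i) for i in range(self.n_frames)]

    def slice_frames(self, mask_or_indices) -> "Trajectory":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Trajectory(self.topology, self.coords[idx], self.dt_ns,
                          times_ns=self.times_ns[idx])

    @classmethod
    def from_frames(cls, topology: Topology, frames: list[Frame], dt_ns: float = 0.1):
        coords = np.stack([f.coords for f in frames])
        times = np.array([f.time_ns for f in frames])
        return cls(topology, coords, dt_ns, times_ns=times)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = {"backbone", "ca", "heavy", "ion", "sidechain-o", "sidechain-n", "all"}


def _primitive(topology: Topology, token: str, args: list[str]) -> set[int]:
    atoms = topology.atoms
    if token == "backbone":
        return {a.index for a in atoms if a.is_backbone}
    if token == "ca":
        return {a.index for a in atoms if a.name == "CA" and not a.is_ion}
    if token == "heavy":
        return {a.index for a in atoms if a.element != "H"}
    if token == "ion":
        return {a.index for a in atoms if a.is_ion}
    if token == "sidechain-o":
        return {
            i for r in topology.residues if r.charge_class == "acidic"
            for i in r.sidechain_polar_atoms
        }
    if token == "sidechain-n":
        return {
            i for r in topology.residues if r.charge_class == "basic"
            for i in r.sidechain_polar_atoms
        }
    if token == "all":
        return {a.index for a in atoms}
    if token == "resid":
        wanted: set[int] = set()
        for arg in args:
            m = re.fullmatch(r"(\d+)-(\d+)", arg)
            if m:
                wanted.update(range(int(m.group(1)), int(m.group(2)) + 1))
            elif arg.isdigit():
                wanted.add(int(arg))
            else:
                raise SelectionError(f"bad resid token {arg!r}")
        if not args:
            raise SelectionError("'resid' requires at least one residue number")
        return {a.index for a in atoms if a.residue_index in wanted}
    if token == "name":
        if not args:
            raise SelectionError("'name' requires at least one atom name")
        names = {a.upper() for a in args}
        return {a.index for a in atoms if a.name.upper() in names}
    raise SelectionError(f"unknown selection token {token!r}")


def _parse_primitive(topology: Topology, part: list[str]) -> set[int]:
    if not part:
        raise SelectionError("empty selection clause")
    token = part[0].lower()
    return _primitive(topology, token, part[1:])


def select(topology: Topology, spec: str) -> list[int]:
    """Resolve a selection expression to a sorted, duplicate-free index list.

    Grammar: ``backbone | ca | heavy | ion | sidechain-O | sidechain-N |
    resid <n> [<n>|<a>-<b> ...] | name <NAME> [...] | all``, combinable with
    ``and`` (intersection, binds tighter) and ``or`` (union).
    """
    tokens = spec.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    clauses: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "or":
            clauses.append([])
        else:
            clauses[-1].append(tok)
    result: set[int] = set()
    for clause in clauses:
        parts: list[list[str]] = [[]]
        for tok in clause:
            if tok.lower() == "and":
                parts.append([])
            else:
                parts[-1].append(tok)
        sub: set[int] | None = None
        for part in parts:
            s = _parse_primitive(topology, part)
            sub = s if sub is None else (sub & s)
        result |= sub if sub is not None else set()
    return sorted(result)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (parsing/writing delegated to biotite)
# ---------------------------------------------------------------------------

_DT_REMARK = re.compile(r"^REMARK\s+250\s+DT_NS\s*[:=]?\s*([0-9.eE+-]+)")


def _prescan_pdb(path) -> float | None:
    """Validate per-model atom counts and coordinate fields; return dt if noted."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    dt = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            m = _DT_REMARK.match(line)
            if m:
                dt = float(m.group(1))
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi]
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise FormatError(
                            f"line {lineno}: unparseable coordinate field {fieldtxt!r}"
                        ) from None
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:
        counts.append(current)
    if not counts or counts[0] == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    for model_no, n in enumerate(counts[1:], start=2):
        if n != counts[0]:
            raise StructureError(
                f"model {model_no} has {n} atoms; expected {counts[0]} (model 1)"
            )
    return dt


def _topology_from_atom_array(arr: AtomArray) -> Topology:
    residues: list[Residue] = []
    atoms: list[Atom] = []
    res_seen: dict[int, str] = {}
    order: list[int] = []
    for i in range(arr.array_length()):
        rid = int(arr.res_id[i])
        if rid not in res_seen:
            res_seen[rid] = arr.res_name[i].strip()
            order.append(rid)
    remap = {rid: k + 1 for k, rid in enumerate(sorted(order))}
    for rid in sorted(order):
        residues.append(Residue(index=remap[rid], name3=res_seen[rid]))
    for i in range(arr.array_length()):
        name = arr.atom_name[i].strip()
        rid = remap[int(arr.res_id[i])]
        resname = res_seen[int(arr.res_id[i])]
        element = arr.element[i].strip().upper() if arr.element[i].strip() else ""
        if not element:
            element = guess_element(name).upper()
        is_ion = bool(arr.hetero[i]) and resname not in AA_3TO1
        atoms.append(Atom(
            index=i,
            name=name,
            element=element.capitalize() if len(element) > 1 else element,
            mass=element_mass(element),
            residue_index=rid,
            is_backbone=(name in BACKBONE_NAMES and resname in AA_3TO1),
            is_ion=is_ion,
        ))
    return Topology(residues, atoms)


def read_pdb_trajectory(path, dt_ns: float | None = None) -> Trajectory:
    """Read a (multi-model) PDB file as a trajectory.

    A file without MODEL records is a one-frame trajectory.  HETATM records
    whose residue is not a standard amino acid are mapped to ion atoms.
    ``dt_ns`` overrides the frame spacing; otherwise a ``REMARK 250 DT_NS``
    header (written by :func:`write_pdb_trajectory`) or the 0.1 ns default
    applies.
    """
    noted_dt = _prescan_pdb(path)
    if dt_ns is None:
        dt_ns = noted_dt if noted_dt is not None else 0.1
    pdb = PDBFile.read(str(path))
    structure = pdb.get_structure(model=None)
    if isinstance(structure, AtomArray):
        structure = _biotite_stack([structure])  # pragma: no cover
    topology = _topology_from_atom_array(structure[0])
    coords = np.asarray(structure.coord, dtype=float)
    return Trajectory(topology, coords, dt_ns=dt_ns)


def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write one MODEL/ENDMDL block per frame in fixed-column PDB format."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    top = traj.topology
    n = top.n_atoms
    arr = AtomArray(n)
    arr.coord = np.zeros((n, 3))
    for atom in top.atoms:
        res = top.residue(atom.residue_index)
        arr.chain_id[atom.index] = "A"
        arr.res_id[atom.index] = atom.residue_index
        arr.res_name[atom.index] = res.name3
        arr.atom_name[atom.index] = atom.name
        arr.element[atom.index] = atom.element.upper()
        arr.hetero[atom.index] = atom.is_ion
    stack = _biotite_stack([arr] * traj.n_frames)
    stack.coord = traj.coords.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.lines.insert(0, f"REMARK 250 DT_NS {traj.dt_ns:g}")
    pdb.write(str(path))
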