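"""Structure and trajectory containers, PDB I/O, and atom selections.

The in-memory model is deliberately small: an ordered list of :class:`Atom`
records inside a :class:`Structure`, a :class:`SegmentAnnotation` naming
labelled residue ranges (TM helices, loops) with their extracellular (EC) /
intracellular (IC) half assignment, and a :class:`Trajectory` of coordinate
frames over a constant atom roster.

Coordinate convention: z is the membrane normal with the EC side at positive
z.  The z origin is ``Structure.frame_axis_origin``, settable from the
centroid of any selection (default: whole structure).

Only fixed-column PDB (ATOM/HETATM/MODEL/ENDMDL) is supported.  Alternate
locations and insertion codes are rejected with an explicit error rather than
silently dropped; multi-model files become trajectories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_VDW_RADIUS, VDW_RADII, WATER_RESNAMES
from .errors import EmptyInputError, PDBParseError, SelectionError

__all__ = [
    "Atom",
    "SegmentAnnotation",
    "Structure",
    "Selection",
    "Trajectory",
    "read_pdb",
    "write_pdb",
    "select",
]


@dataclass
class Atom:
    """One atom record; coordinates in Å."""

    serial: int
    name: str
    element: str
    resid: int
    resname: str
    chain: str
    coords: np.ndarray
    vdw_radius: float = DEFAULT_VDW_RADIUS
    is_water: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.resid,
                    self.resname, self.chain, self.coords.copy(),
                    self.vdw_radius, self.is_water)


@dataclass
class SegmentAnnotation:
    """Labelled residue ranges and their EC/IC half assignment.

    ``segments`` maps a label (e.g. ``"TM1"``) to ``(chain, start, end)``
    with 1-based inclusive residue indices; ``half_assignment`` maps the same
    labels to ``"EC"``, ``"IC"`` or ``"both"``.
    """

    segments: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    half_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for label, (chain, start, end) in self.segments.items():
            if start > end:
                raise ValueError(f"segment {label}: start {start} > end {end}")
            by_chain.setdefault(chain, []).append((start, end, label))
        for chain, ranges in by_chain.items():
            ranges.sort()
            for (s1, e1, l1), (s2, e2, l2) in zip(ranges, ranges[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"segments {l1} and {l2} overlap on chain {chain}")

    @property
    def labels(self) -> list[str]:
        return list(self.segments)

    def residues_of(self, label: str) -> tuple[str, range]:
        chain, start, end = self.segments[label]
        return chain, range(start, end + 1)

    def copy(self) -> "SegmentAnnotation":
        return SegmentAnnotation(dict(self.segments), dict(self.half_assignment))


class Structure:
    """An ordered collection of atoms with segment annotation."""

    def __init__(self, atoms: list[Atom],
                 annotation: SegmentAnnotation | None = None,
                 frame_axis_origin: np.ndarray | None = None,
                 validate: bool = True):
        self.atoms = list(atoms)
        self.annotation = annotation if annotation is not None else SegmentAnnotation()
        if frame_axis_origin is None:
            frame_axis_origin = np.zeros(3)
        self.frame_axis_origin = np.asarray(frame_axis_origin, dtype=float)
        if validate:
            self._validate()

    def _validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique")
        last: dict[str, int] = {}
        for a in self.atoms:
            if a.resid < last.get(a.chain, -10**9):
                raise ValueError(
                    f"residue indices decrease within chain {a.chain} "
                    f"at atom serial {a.serial}")
            last[a.chain] = a.resid

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape ({len(self.atoms)}, 3), "
                             f"got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz.copy()

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(coords)
        return out

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.annotation.copy(),
                         self.frame_axis_origin.copy(), validate=False)

    def set_frame_origin(self, selection: "Selection | None" = None) -> None:
        """Set the z-convention origin to a selection's centroid.

        With no selection, the whole-structure centroid is used.
        """
        coords = self.coords
        if selection is not None:
            coords = coords[selection.indices]
        if coords.shape[0] == 0:
            raise EmptyInputError("cannot set frame origin from empty selection")
        self.frame_axis_origin = coords.mean(axis=0)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resid) keys."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain, a.resid), None)
        return list(seen)


@dataclass(frozen=True)
class Selection:
    """Ordered, unique atom positions into a structure."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1:
            raise ValueError("selection indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def complement(self, n_atoms: int) -> "Selection":
        mask = np.ones(n_atoms, dtype=bool)
        mask[self.indices] = False
        return Selection(np.flatnonzero(mask))


class Trajectory:
    """Ordered coordinate frames over a constant atom roster.

    ``template`` carries the atom metadata (names, residues, radii) shared by
    every frame; ``times`` are simulation timestamps (strictly increasing).
    """

    def __init__(self, frames: np.ndarray, times: np.ndarray,
                 template: Structure | None = None):
        frames = np.asarray(frames, dtype=float)
        times = np.asarray(times, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[0] == 0:
            raise EmptyInputError("trajectory has no frames")
        if times.shape != (frames.shape[0],):
            raise ValueError("times must match the number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if template is not None and template.n_atoms != frames.shape[1]:
            raise ValueError("template atom count does not match frames")
        self.frames = frames
        self.times = times
        self.template = template

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        if self.template is None:
            raise ValueError("trajectory has no template structure")
        return self.template.with_coords(self.frames[i])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _element_from_fields(element_field: str, name: str) -> str:
    el = element_field.strip()
    if el:
        return el.upper()
    # Fall back to the atom name: strip digits, take the leading letters.
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_RADII and stripped[0].isalpha():
        # Two-letter element only when the name cannot be e.g. "CA" (calcium
        # vs C-alpha); protein atom names resolve to their first letter.
        pass
    return stripped[0].upper()


def read_pdb(path, model_policy: str = "first") -> Structure | Trajectory:
    """Read a (possibly multi-model) PDB file.

    Parameters
    ----------
    path:
        File to read.
    model_policy:
        ``"first"`` returns a :class:`Structure` from the first MODEL block;
        ``"all"`` returns a :class:`Trajectory` whose frames are the MODEL
        blocks (times are the model numbers).
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    models: list[list[Atom]] = []
    model_numbers: list[float] = []
    current: list[Atom] | None = None
    saw_model_records = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec == "MODEL ":
                saw_model_records = True
                if current is not None and current:
                    models.append(current)
                current = []
                try:
                    model_numbers.append(float(raw[6:].split()[0]))
                except (IndexError, ValueError):
                    model_numbers.append(len(models) + 1.0)
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    current = None
                if model_policy == "first" and models:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = []
                    if saw_model_records:
                        model_numbers.append(len(models) + 1.0)
                try:
                    serial = int(raw[6:11])
                    name = raw[12:16].strip()
                    altloc = raw[16].strip()
                    resname = raw[17:20].strip() or raw[17:21].strip()
                    chain = raw[21].strip() or "A"
                    resid = int(raw[22:26])
                    icode = raw[26].strip()
                    x = float(raw[30:38])
                    y = float(raw[38:46])
                    z = float(raw[46:54])
                    element_field = raw[76:78] if len(raw) >= 78 else ""
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"{path}: malformed {rec.strip()} record at line "
                        f"{lineno}: {exc}") from exc
                if altloc:
                    raise PDBParseError(
                        f"{path}: alternate location {altloc!r} at line "
                        f"{lineno} is not supported; resolve altlocs first")
                if icode:
                    raise PDBParseError(
                        f"{path}: insertion code {icode!r} at line {lineno} "
                        f"is not supported; renumber residues first")
                element = _element_from_fields(element_field, name)
                is_water = resname.upper() in WATER_RESNAMES
                current.append(Atom(
                    serial=serial, name=name, element=element, resid=resid,
                    resname=resname, chain=chain, coords=np.array([x, y, z]),
                    vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                    is_water=is_water))
    if current is not None and current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    if model_policy == "first":
        return Structure(models[0])
    template = Structure(models[0])
    n = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n:
            raise PDBParseError(
                f"{path}: MODEL {i + 1} has {len(m)} atoms, expected {n}")
    frames = np.stack([np.stack([a.coords for a in m]) for m in models])
    if len(model_numbers) == len(models) and np.all(np.diff(model_numbers) > 0):
        times = np.asarray(model_numbers, dtype=float)
    else:
        times = np.arange(1, len(models) + 1, dtype=float)
    return Trajectory(frames, times, template=template)


def _format_atom_line(atom: Atom, serial: int, coords: np.ndarray) -> str:
    record = "HETATM" if atom.is_water else "ATOM  "
    name = atom.name
    # Standard PDB alignment: 1-3 character names start in column 14.
    if len(name) < 4:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    if not (-999 < coords[0] < 9999 and -999 < coords[1] < 9999
            and -999 < coords[2] < 9999):
        raise ValueError(f"coordinates out of PDB range for atom {atom.serial}")
    if atom.resid > 9999 or atom.resid < -999:
        raise ValueError(f"residue index {atom.resid} exceeds PDB columns")
    return (f"{record}{serial % 100000:5d} {name}{'':1s}{atom.resname:<4s}"
            f"{atom.chain[:1]:1s}{atom.resid:4d}    "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n")


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a structure or trajectory as fixed-column PDB.

    Trajectories are written as MODEL/ENDMDL blocks over the template roster.
    """
    if isinstance(obj, Structure):
        if obj.n_atoms == 0:
            raise EmptyInputError("refusing to write a structure with no atoms")
        with open(path, "w") as fh:
            for i, atom in enumerate(obj.atoms, start=1):
                fh.write(_format_atom_line(atom, i, atom.coords))
            fh.write("END\n")
        return
    if isinstance(obj, Trajectory):
        if obj.template is None:
            raise ValueError("trajectory without a template cannot be written")
        if obj.n_frames == 0:
            raise EmptyInputError("refusing to write an empty trajectory")
        with open(path, "w") as fh:
            for f in range(obj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for i, atom in enumerate(obj.template.atoms, start=1):
                    fh.write(_format_atom_line(atom, i, obj.frames[f, i - 1]))
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Selection expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"and", "or", "not", "(", ")"}


class _QueryParser:
    """Recursive-descent parser for the small selection grammar.

    Grammar::

        expr    := and_expr ('or' and_expr)*
        and_expr:= unary ('and' unary)*
        unary   := 'not' unary | '(' expr ')' | predicate

    Predicates: ``all``, ``water``, ``protein``, ``heavy``,
    ``name N[,N...]``, ``element E[,...]``, ``resname R[,...]``,
    ``chain C[,...]``, ``resid A[..B][,...]``, ``segment L[..L2][,...]``,
    ``half EC|IC``.
    """

    def __init__(self, query: str, structure: Structure):
        self.tokens = _TOKEN_RE.findall(query)
        if not self.tokens:
            raise SelectionError("empty selection expression")
        self.pos = 0
        self.structure = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.predicate()

    # -- predicates --------------------------------------------------------

    def predicate(self) -> np.ndarray:
        tok = self.next().lower()
        atoms = self.structure.atoms
        n = len(atoms)
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "water":
            return np.array([a.is_water for a in atoms])
        if tok == "protein":
            return np.array([not a.is_water for a in atoms])
        if tok == "heavy":
            return np.array([a.is_heavy for a in atoms])
        if tok == "name":
            values = self._value_list()
            return np.array([a.name in values for a in atoms])
        if tok == "element":
            values = {v.upper() for v in self._value_list()}
            return np.array([a.element.upper() in values for a in atoms])
        if tok == "resname":
            values = {v.upper() for v in self._value_list()}
            return np.array([a.resname.upper() in values for a in atoms])
        if tok == "chain":
            values = self._value_list()
            return np.array([a.chain in values for a in atoms])
        if tok == "resid":
            ranges = self._ranges()
            ok = np.zeros(n, dtype=bool)
            for lo, hi in ranges:
                ok |= np.array([lo <= a.resid <= hi for a in atoms])
            return ok
        if tok == "segment":
            return self._segment_mask()
        if tok == "half":
            side = self.next().upper()
            if side not in ("EC", "IC"):
                raise SelectionError("half must be EC or IC")
            z0 = self.structure.frame_axis_origin[2]
            z = np.array([a.coords[2] for a in atoms]) - z0
            return z >= 0 if side == "EC" else z < 0
        raise SelectionError(f"unknown selection predicate {tok!r}")

    def _value_list(self) -> set[str]:
        tok = self.next()
        if tok in _KEYWORDS:
            raise SelectionError(f"expected values, got {tok!r}")
        return set(tok.split(","))

    def _ranges(self) -> list[tuple[int, int]]:
        out = []
        for item in self.next().split(","):
            m = re.fullmatch(r"(-?\d+)(?:(?:\.\.|:)(-?\d+))?", item)
            if not m:
                raise SelectionError(f"bad resid range {item!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            out.append((lo, hi))
        return out

    def _segment_mask(self) -> np.ndarray:
        ann = self.structure.annotation
        known = ann.labels
        labels: list[str] = []
        for item in self.next().split(","):
            if ".." in item:
                a, b = item.split("..", 1)
                ma = re.fullmatch(r"([A-Za-z]+)(\d+)", a)
                mb = re.fullmatch(r"([A-Za-z]+)(\d+)", b)
                if not ma or not mb or ma.group(1) != mb.group(1):
                    raise SelectionError(f"bad segment range {item!r}")
                prefix = ma.group(1)
                for i in range(int(ma.group(2)), int(mb.group(2)) + 1):
                    labels.append(f"{prefix}{i}")
            else:
                labels.append(item)
        for label in labels:
            if label not in ann.segments:
                raise SelectionError(
                    f"unknown segment label {label!r}; known labels: "
                    f"{', '.join(known) if known else '(none)'}")
        atoms = self.structure.atoms
        mask = np.zeros(len(atoms), dtype=bool)
        for label in labels:
            chain, start, end = ann.segments[label]
            mask |= np.array([a.chain == chain and start <= a.resid <= end
                              for a in atoms])
        return mask


def select(structure: Structure, query: str) -> Selection:
    """Resolve a selection expression to an ordered :class:`Selection`.

    The result preserves atom order and is deterministic for a given
    structure and query.
    """
    mask = _QueryParser(query, structure).parse()
    return Selection(np.flatnonzero(mask))
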