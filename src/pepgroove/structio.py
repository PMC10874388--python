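"""PDB-format structure I/O, a uniform atomic model, and atom selections.

The atomic model is a thin, immutable-by-convention wrapper around a biotite
``AtomArray``; all downstream geometry consumes :class:`Structure` and
:class:`AtomSet`.  Coordinates are in Angstrom, residue numbers are 1-based
exactly as in the file and never renumbered, and only MODEL 1 of multi-model
files is read.  Alternate locations are resolved to the highest-occupancy
copy (ties: first in file).  HETATM records are retained -- the cyclic
peptides this package targets are ATOM/HETATM hybrids -- and waters are
flagged but kept.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import EmptyStructureError, PdbParseError, SelectionError

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

# Two-letter element symbols that can appear in PDB atom names; used only as
# a fallback when the element column is absent.
_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE", "CU", "NI", "CO"}
)


@dataclass(frozen=True)
class Atom:
    """A single atom record (a read-only view into a :class:`Structure`)."""

    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain: str
    resnum: int
    icode: str
    xyz: np.ndarray
    occupancy: float
    bfactor: float
    is_hetatm: bool

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


class Structure:
    """An ordered collection of atoms parsed from a PDB coordinate section.

    Parameters
    ----------
    array : biotite.structure.AtomArray
        Backing atom array.  Must carry ``occupancy`` and ``b_factor``
        annotations; ``atom_id`` is added when missing.
    id : str
        Free-text label, e.g. a PDB accession.
    """

    def __init__(self, array: struc.AtomArray, id: str = ""):
        if array.array_length() == 0:
            raise EmptyStructureError("structure contains no atoms")
        for ann, default in (("occupancy", 1.0), ("b_factor", 0.0)):
            if ann not in array.get_annotation_categories():
                array.set_annotation(ann, np.full(array.array_length(), default))
        if "atom_id" not in array.get_annotation_categories():
            array.set_annotation(
                "atom_id", np.arange(1, array.array_length() + 1, dtype=int)
            )
        if not np.all(np.isfinite(array.coord)):
            raise PdbParseError("non-finite coordinates in structure")
        self.array = array
        self.id = id

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.array.array_length()

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def coords(self) -> np.ndarray:
        return self.array.coord

    def atom(self, i: int) -> Atom:
        a = self.array
        return Atom(
            serial=int(a.atom_id[i]),
            name=str(a.atom_name[i]),
            element=str(a.element[i]),
            altloc="",
            resname=str(a.res_name[i]),
            chain=str(a.chain_id[i]),
            resnum=int(a.res_id[i]),
            icode=str(a.ins_code[i]),
            xyz=a.coord[i],
            occupancy=float(a.occupancy[i]),
            bfactor=float(a.b_factor[i]),
            is_hetatm=bool(a.hetero[i]),
        )

    def __iter__(self) -> Iterator[Atom]:
        return (self.atom(i) for i in range(len(self)))

    # -- masks --------------------------------------------------------------------
    @property
    def water_mask(self) -> np.ndarray:
        return np.isin(self.array.res_name, list(WATER_RESNAMES))

    @property
    def hydrogen_mask(self) -> np.ndarray:
        return np.isin(self.array.element, ["H", "D"])

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.hydrogen_mask

    # -- residue iteration ---------------------------------------------------------
    def residues(self) -> Iterator[tuple[tuple[str, int, str], str, np.ndarray]]:
        """Yield ``(residue key, resname, atom indices)`` per contiguous residue."""
        a = self.array
        starts = struc.get_residue_starts(a, add_exclusive_stop=True)
        for s, e in zip(starts[:-1], starts[1:]):
            key = (str(a.chain_id[s]), int(a.res_id[s]), str(a.ins_code[s]))
            yield key, str(a.res_name[s]), np.arange(s, e)

    def residue_indices(self, chain: str, resnum: int, icode: str = "") -> np.ndarray:
        a = self.array
        mask = (a.chain_id == chain) & (a.res_id == resnum) & (a.ins_code == icode)
        return np.flatnonzero(mask)

    def find_atom(
        self, chain: str, resnum: int, name: str, icode: str = ""
    ) -> int | None:
        idx = self.residue_indices(chain, resnum, icode)
        hit = idx[self.array.atom_name[idx] == name]
        return int(hit[0]) if hit.size else None

    def subset(self, indices: np.ndarray | Sequence[int], id: str | None = None) -> "Structure":
        indices = np.asarray(indices, dtype=int)
        return Structure(self.array[indices], id=id if id is not None else self.id)

    # -- output -------------------------------------------------------------------
    def to_pdb(self, path: str | Path | None = None) -> str | None:
        f = PDBFile()
        f.set_structure(self.array)
        if path is None:
            buf = io.StringIO()
            f.write(buf)
            return buf.getvalue()
        f.write(str(path))
        return None


@dataclass
class AtomSet:
    """Duplicate-free indices into a :class:`Structure`."""

    structure: Structure
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size:
            if self.indices.min() < 0 or self.indices.max() >= len(self.structure):
                raise IndexError("AtomSet indices out of range")
            if np.unique(self.indices).size != self.indices.size:
                raise ValueError("AtomSet indices contain duplicates")
        self.indices = np.sort(self.indices)

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords[self.indices]

    def atoms(self) -> Iterator[Atom]:
        return (self.structure.atom(int(i)) for i in self.indices)

    def complement(self) -> "AtomSet":
        mask = np.ones(len(self.structure), dtype=bool)
        mask[self.indices] = False
        return AtomSet(self.structure, np.flatnonzero(mask))

    def intersect_mask(self, mask: np.ndarray) -> "AtomSet":
        keep = self.indices[mask[self.indices]]
        return AtomSet(self.structure, keep)

    def union(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self.structure, np.union1d(self.indices, other.indices))

    def difference(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self.structure, np.setdiff1d(self.indices, other.indices))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in _TWO_LETTER_ELEMENTS:
        # Only trust the two-letter reading for non-peptide names; CA/CD etc.
        # in amino-acid residues are carbons, which the caller handles by
        # passing peptide atoms through the one-letter branch first.
        pass
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _locate_bad_line(text: str) -> int | None:
    """Return the 1-based line number of the first malformed coordinate record."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            int(line[22:26])
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except (ValueError, IndexError):
            return lineno
    return None


def read_structure(source: str | Path | io.TextIOBase, id: str = "") -> Structure:
    """Read a PDB-format structure (text, path, or open file).

    Returns the first MODEL only, with altlocs resolved to the
    highest-occupancy copy (ties broken by file order).  HETATM atoms and
    waters are retained.  Raises :class:`PdbParseError` naming the offending
    line for malformed fixed-width records, and :class:`EmptyStructureError`
    when the coordinate section is empty.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
        label = id
    else:
        s = str(source)
        if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "CRYST")):
            text = s
            label = id
        else:
            path = Path(source)
            text = path.read_text()
            label = id or path.stem
    # Normalise trailing whitespace and pad short coordinate records:
    # occupancy/B-factor default to 1.00/0.00 and a blank element column is
    # tolerated (the element is then derived from the atom name).
    lines = []
    for ln in text.splitlines():
        ln = ln.rstrip()
        if ln.startswith(("ATOM", "HETATM")):
            ln = ln.ljust(80)
            if ln[54:60].strip() == "":
                ln = ln[:54] + "  1.00" + ln[60:]
            if ln[60:66].strip() == "":
                ln = ln[:60] + "  0.00" + ln[66:]
        lines.append(ln)
    text = "\n".join(lines) + "\n"

    if not any(ln.startswith(("ATOM", "HETATM")) for ln in lines):
        raise EmptyStructureError("no ATOM/HETATM records in input")

    try:
        pdb = PDBFile.read(io.StringIO(text))
        array = pdb.get_structure(
            model=1,
            altloc="occupancy",
            extra_fields=["atom_id", "b_factor", "occupancy"],
        )
    except Exception as exc:  # biotite raises format-specific subclasses
        bad = _locate_bad_line(text)
        if bad is not None:
            raise PdbParseError(f"malformed coordinate record at line {bad}") from exc
        raise PdbParseError(str(exc)) from exc

    if array.array_length() == 0:
        raise EmptyStructureError("model 1 contains no atoms")

    # Element fallback when the element column was blank.
    element = np.asarray(array.element, dtype="U2")
    blank = np.array([e.strip() == "" for e in element])
    if blank.any():
        names = array.atom_name
        element = element.copy()
        for i in np.flatnonzero(blank):
            element[i] = _infer_element(str(names[i]))
        array.element = element
    return Structure(array, id=label)


def write_structure(structure: Structure, path: str | Path) -> None:
    structure.to_pdb(path)


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
#
# Grammar (case-insensitive keywords, left-to-right):
#   expr      := or_expr
#   or_expr   := and_expr ("or" and_expr)*
#   and_expr  := not_expr ("and" not_expr)*
#   not_expr  := "not" not_expr | "(" expr ")" | primitive
#   primitive := "chain" ID | "resnum" N | "resnum" N-M | "resname" NAME
#              | "name" NAME | "element" SYM | "hetatm" | "protein"
#              | "water" | "all" | "none"

_KEYWORDS = {"chain", "resnum", "resname", "name", "element",
             "hetatm", "protein", "water", "all", "none",
             "and", "or", "not", "(", ")"}


def _tokenize(spec: str) -> list[str]:
    out: list[str] = []
    for raw in spec.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.not_expr()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        a = self.s.array
        kw = self.next().lower()
        if kw == "chain":
            return a.chain_id == self.value()
        if kw == "resnum":
            val = self.value()
            try:
                if "-" in val[1:] or ":" in val:
                    sep = ":" if ":" in val else "-"
                    lo_s, hi_s = val.split(sep, 1)
                    lo, hi = int(lo_s), int(hi_s)
                    return (a.res_id >= lo) & (a.res_id <= hi)
                return a.res_id == int(val)
            except ValueError as exc:
                raise SelectionError(f"bad resnum value {val!r}") from exc
        if kw == "resname":
            return a.res_name == self.value().upper()
        if kw == "name":
            return a.atom_name == self.value().upper()
        if kw == "element":
            return a.element == self.value().upper()
        if kw == "hetatm":
            return a.hetero.astype(bool)
        if kw == "protein":
            return ~a.hetero.astype(bool) & ~np.isin(a.res_name, list(WATER_RESNAMES))
        if kw == "water":
            return np.isin(a.res_name, list(WATER_RESNAMES))
        if kw == "all":
            return np.ones(len(self.s), dtype=bool)
        if kw == "none":
            return np.zeros(len(self.s), dtype=bool)
        raise SelectionError(f"unknown selection keyword {kw!r}")

    def value(self) -> str:
        tok = self.next()
        if tok.lower() in _KEYWORDS:
            raise SelectionError(f"expected a value, got keyword {tok!r}")
        return tok


def select(structure: Structure, spec: str) -> AtomSet:
    """Evaluate a selection expression to a deterministic :class:`AtomSet`.

    Empty selections are allowed; a syntactically invalid expression raises
    :class:`SelectionError`.
    """
    tokens = _tokenize(spec)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, structure).parse()
    return AtomSet(structure, np.flatnonzero(mask))
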