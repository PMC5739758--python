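"""I/O for assigned chemical shifts, 2D peak lists, Cα coordinates and sequences.

The pipeline consumes four kinds of plain-text artifacts:

* assigned backbone shift tables (a TSV dialect, or the ``Atom_chem_shift``
  loop of an NMR-STAR 3.1 deposit such as a BMRB entry),
* Sparky ``.list`` 2D peak lists, one per titration point,
* PDB ``ATOM`` records, from which only one Cα per residue is kept,
* FASTA sequences.

All residue numbering is on the construct scale, which may start at a
negative number (an N-terminal purification tag) and passes through zero:
the scale is a plain contiguous integer range, so offsets act as a group
(``+a`` then ``+b`` equals ``+(a+b)``).

Parsers reject, they never repair: a chemical shift outside its atom-class
window or an atom a residue type cannot carry is dropped with a logged
warning (or raises, for structural violations such as duplicates) — it is
never clamped or silently kept.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import IntegrityError, LookupError_, ParseError

logger = logging.getLogger(__name__)

#: Plausibility windows (ppm) per backbone atom, used to reject corrupt rows.
ATOM_PPM_WINDOWS: dict[str, tuple[float, float]] = {
    "H": (-2.0, 14.0),
    "N": (90.0, 140.0),
    "CA": (0.0, 200.0),
    "CB": (0.0, 200.0),
    "C": (0.0, 200.0),
}

BACKBONE_ATOMS = frozenset(ATOM_PPM_WINDOWS)

#: Backbone atoms a residue type cannot carry: glycine has no Cβ and the
#: proline backbone nitrogen carries no amide proton.
_MISSING_ATOMS_BY_RESIDUE: dict[str, frozenset[str]] = {
    "G": frozenset({"CB"}),
    "P": frozenset({"H"}),
}

AMINO_ACIDS_1 = set("ACDEFGHIKLMNPQRSTVWY")

_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def valid_atom_for_residue(residue_type: str, atom_name: str) -> bool:
    """True if *residue_type* (1-letter) can carry backbone atom *atom_name*."""
    return atom_name not in _MISSING_ATOMS_BY_RESIDUE.get(residue_type, frozenset())


def ppm_in_window(atom_name: str, shift_ppm: float) -> bool:
    lo, hi = ATOM_PPM_WINDOWS[atom_name]
    return lo <= shift_ppm <= hi


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned backbone resonance: (residue, atom) → δ in ppm."""

    residue_number: int
    residue_type: str
    atom_name: str
    shift_ppm: float

    def __post_init__(self) -> None:
        if self.atom_name not in BACKBONE_ATOMS:
            raise IntegrityError(
                f"atom {self.atom_name!r} is not a backbone atom {sorted(BACKBONE_ATOMS)}"
            )
        if not ppm_in_window(self.atom_name, self.shift_ppm):
            lo, hi = ATOM_PPM_WINDOWS[self.atom_name]
            raise IntegrityError(
                f"shift {self.shift_ppm} ppm for {self.atom_name} of residue "
                f"{self.residue_number} outside window [{lo}, {hi}]"
            )


@dataclass
class ShiftTable:
    """Assigned resonances of one sample state, sorted by (residue, atom)."""

    records: list[ShiftRecord]
    state_label: str = "free"
    molar_ratio: float = 0.0

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (r.residue_number, r.atom_name)
        )
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.residue_number, rec.atom_name)
            if key in seen:
                raise IntegrityError(f"duplicate (residue, atom) entry {key}")
            seen.add(key)
        self._index = {(r.residue_number, r.atom_name): r for r in self.records}

    def get(self, residue_number: int, atom_name: str) -> ShiftRecord | None:
        return self._index.get((residue_number, atom_name))

    @property
    def residue_numbers(self) -> list[int]:
        return sorted({r.residue_number for r in self.records})

    def residue_type(self, residue_number: int) -> str | None:
        for atom in ("H", "N", "CA", "C", "CB"):
            rec = self.get(residue_number, atom)
            if rec is not None:
                return rec.residue_type
        return None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return (
            self.records == other.records
            and self.state_label == other.state_label
            and self.molar_ratio == other.molar_ratio
        )


@dataclass(frozen=True)
class Peak2D:
    """One amide cross-peak of a ¹H-¹⁵N HSQC spectrum."""

    h_ppm: float
    n_ppm: float
    intensity: float = 1.0
    assignment: int | None = None  # residue number, if assigned

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise IntegrityError(f"negative peak intensity {self.intensity}")
        if not ppm_in_window("H", self.h_ppm):
            raise IntegrityError(f"1H ppm {self.h_ppm} outside window")
        if not ppm_in_window("N", self.n_ppm):
            raise IntegrityError(f"15N ppm {self.n_ppm} outside window")


@dataclass
class StructureCA:
    """Ordered Cα trace of one chain: (residue_number, residue_type, x, y, z)."""

    residues: list[tuple[int, str, float, float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        nums = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise IntegrityError("residue numbers must be strictly increasing")
        for num, _, x, y, z in self.residues:
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise IntegrityError(f"non-finite coordinates at residue {num}")
        self._coord = {r[0]: np.array(r[2:5], dtype=float) for r in self.residues}

    @property
    def residue_numbers(self) -> list[int]:
        return [r[0] for r in self.residues]

    def coords(self, residue_numbers: Iterable[int]) -> np.ndarray:
        """(n, 3) array of Cα coordinates for the requested residues."""
        missing = [n for n in residue_numbers if n not in self._coord]
        if missing:
            raise LookupError_(f"residues without Cα in {self.label!r}: {missing}")
        return np.array([self._coord[n] for n in residue_numbers], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceRecord:
    """A 1-letter protein sequence anchored at an explicit first residue number."""

    identifier: str
    sequence: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS_1 - {"X"}
        if bad:
            raise IntegrityError(
                f"sequence {self.identifier!r} contains invalid letters {sorted(bad)}"
            )

    @property
    def residue_numbers(self) -> list[int]:
        start = self.first_residue_number
        return list(range(start, start + len(self.sequence)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _build_shift_table(
    rows: list[tuple[int, int, str, str, float]],
    state_label: str,
    molar_ratio: float,
) -> ShiftTable:
    """Validate raw rows (lineno, resnum, restype, atom, ppm) into a ShiftTable."""
    records: list[ShiftRecord] = []
    seen: set[tuple[int, str]] = set()
    n_ignored = 0
    for lineno, resnum, restype, atom, ppm in rows:
        if atom not in BACKBONE_ATOMS:
            n_ignored += 1
            continue
        if restype not in AMINO_ACIDS_1 and restype != "X":
            raise ParseError(f"line {lineno}: unknown residue type {restype!r}")
        if not valid_atom_for_residue(restype, atom):
            logger.warning(
                "line %d: residue type %s cannot carry atom %s; record dropped",
                lineno, restype, atom,
            )
            continue
        if not ppm_in_window(atom, ppm):
            logger.warning(
                "line %d: %s shift %.3f ppm outside plausibility window; record dropped",
                lineno, atom, ppm,
            )
            continue
        key = (resnum, atom)
        if key in seen:
            raise IntegrityError(f"line {lineno}: duplicate (residue, atom) {key}")
        seen.add(key)
        records.append(ShiftRecord(resnum, restype, atom, ppm))
    if n_ignored:
        logger.info("ignored %d rows for non-backbone atoms", n_ignored)
    return ShiftTable(records, state_label=state_label, molar_ratio=molar_ratio)


def read_shift_table(
    path: str | Path,
    dialect: str = "tsv",
    state_label: str = "free",
    molar_ratio: float = 0.0,
) -> ShiftTable:
    """Read an assigned shift table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` — tab-separated columns ``residue_number  residue_type
        atom_name  shift_ppm`` with an optional header line; or
        ``"nmrstar"`` — an NMR-STAR 3.1 file whose ``Atom_chem_shift`` loop
        is read (read-only subset; the full STAR grammar is out of scope).
    """
    path = Path(path)
    if dialect == "tsv":
        rows = _parse_tsv_shifts(path)
    elif dialect == "nmrstar":
        rows = _parse_nmrstar_shifts(path)
    else:
        raise ParseError(f"unknown shift-table dialect {dialect!r}")
    return _build_shift_table(rows, state_label, molar_ratio)


def _parse_tsv_shifts(path: Path) -> list[tuple[int, int, str, str, float]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts and not _is_int(parts[0]):
                continue  # header
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                resnum = int(parts[0])
                ppm = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            rows.append((lineno, resnum, parts[1].strip().upper(), parts[2].strip().upper(), ppm))
    return rows


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _parse_nmrstar_shifts(path: Path) -> list[tuple[int, int, str, str, float]]:
    """Extract the Atom_chem_shift loop from an NMR-STAR 3.1 file.

    Minimal read-only subset: finds the ``loop_`` whose tags belong to the
    ``_Atom_chem_shift`` category, then reads whitespace-separated data rows
    until ``stop_``. Quoted values and multi-line text fields are not
    supported (none occur in shift loops).
    """
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if tags and all(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_star_loop_rows(path, lines, j, tags)
        i += 1
    raise ParseError(f"{path}: no Atom_chem_shift loop found")


def _parse_star_loop_rows(
    path: Path, lines: list[str], start: int, tags: list[str]
) -> list[tuple[int, int, str, str, float]]:
    names = [t.split(".", 1)[1] for t in tags]

    def col(*candidates: str) -> int:
        for c in candidates:
            if c in names:
                return names.index(c)
        raise ParseError(f"{path}: Atom_chem_shift loop lacks any of {candidates}")

    i_seq = col("Comp_index_ID", "Seq_ID")
    i_comp = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")
    rows = []
    for lineno0, line in enumerate(lines[start:], start=start):
        stripped = line.strip()
        if stripped == "stop_":
            break
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != len(names):
            raise ParseError(
                f"{path}: line {lineno0 + 1}: expected {len(names)} fields, got {len(parts)}"
            )
        comp = parts[i_comp].upper()
        restype = _3TO1.get(comp, comp if len(comp) == 1 else "X")
        try:
            resnum = int(parts[i_seq])
            ppm = float(parts[i_val])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno0 + 1}: {exc}") from None
        rows.append((lineno0 + 1, resnum, restype, parts[i_atom].upper(), ppm))
    return rows


_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z])(-?\d+)[A-Za-z]*N(?:-|\.)?H?$")


def read_sparky_list(path: str | Path, axis_order: str = "nh") -> list[Peak2D]:
    """Read a Sparky ``.list`` peak list.

    Format: a header line, then whitespace-separated rows
    ``assignment  w1  w2  [height]``. With the default ``axis_order="nh"``
    w1 is the ¹⁵N ppm and w2 the ¹H ppm; pass ``"hn"`` for the reverse.
    Assignments like ``G21N-H`` parse to residue number 21; ``?`` marks an
    unassigned peak. A missing height column defaults to intensity 1.0.
    """
    if axis_order not in ("nh", "hn"):
        raise ParseError(f"axis_order must be 'nh' or 'hn', got {axis_order!r}")
    path = Path(path)
    peaks: list[Peak2D] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split()
            if lineno == 1 and not _looks_like_peak_row(parts):
                continue  # header
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 fields")
            try:
                w1 = float(parts[1])
                w2 = float(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric ppm field") from None
            intensity = 1.0
            if len(parts) >= 4:
                try:
                    intensity = float(parts[3])
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: non-numeric height") from None
            assignment = _parse_sparky_assignment(parts[0])
            n_ppm, h_ppm = (w1, w2) if axis_order == "nh" else (w2, w1)
            peaks.append(Peak2D(h_ppm=h_ppm, n_ppm=n_ppm, intensity=intensity,
                                assignment=assignment))
    return peaks


def _looks_like_peak_row(parts: list[str]) -> bool:
    if len(parts) < 3:
        return False
    try:
        float(parts[1]), float(parts[2])
        return True
    except ValueError:
        return False


def _parse_sparky_assignment(text: str) -> int | None:
    if text == "?" or text.startswith("?"):
        return None
    m = _SPARKY_ASSIGNMENT.match(text)
    if m:
        return int(m.group(2))
    logger.warning("unparsable Sparky assignment %r treated as unassigned", text)
    return None


def write_sparky_list(peaks: Sequence[Peak2D], path: str | Path,
                      residue_types: dict[int, str] | None = None,
                      axis_order: str = "nh") -> None:
    """Write peaks in the Sparky ``.list`` dialect that :func:`read_sparky_list` reads."""
    residue_types = residue_types or {}
    lines = ["      Assignment         w1         w2   Data Height"]
    for p in peaks:
        if p.assignment is None:
            label = "?-?"
        else:
            label = f"{residue_types.get(p.assignment, 'X')}{p.assignment}N-H"
        w1, w2 = (p.n_ppm, p.h_ppm) if axis_order == "nh" else (p.h_ppm, p.n_ppm)
        lines.append(f"{label:>16s} {w1:10.4f} {w2:10.4f} {p.intensity:12.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write the TSV dialect of :func:`read_shift_table`."""
    lines = ["residue_number\tresidue_type\tatom_name\tshift_ppm"]
    for rec in table.records:
        lines.append(
            f"{rec.residue_number}\t{rec.residue_type}\t{rec.atom_name}\t{_fmt(rec.shift_ppm)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_structure_ca(path: str | Path, chain: str = "A", model: int = 1) -> StructureCA:
    """Read one Cα per residue of *chain* from PDB ``ATOM`` records.

    Alternate locations are resolved by highest occupancy, ties by first
    encountered; multi-model files use the requested model (default 1).
    Residues without a Cα are skipped with a warning.
    """
    path = Path(path)
    current_model = 1
    # residue -> (occupancy, restype, xyz); first-encountered wins ties
    best: dict[int, tuple[float, str, tuple[float, float, float]]] = {}
    order: list[int] = []
    chains_seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                try:
                    current_model = int(line.split()[1])
                except (IndexError, ValueError):
                    raise ParseError(f"{path}: line {lineno}: malformed MODEL record") from None
                continue
            if not line.startswith(("ATOM", "HETATM")) or current_model != model:
                continue
            try:
                atom_name = line[12:16].strip()
                chain_id = line[21]
                resnum = int(line[22:26])
                restype3 = line[17:20].strip()
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                occ_field = line[54:60].strip()
                occ = float(occ_field) if occ_field else 1.0
            except (ValueError, IndexError):
                raise ParseError(f"{path}: line {lineno}: malformed ATOM record") from None
            if line.startswith("ATOM"):
                chains_seen.add(chain_id)
            if chain_id != chain or atom_name != "CA":
                continue
            restype = _3TO1.get(restype3, "X")
            if resnum not in best:
                best[resnum] = (occ, restype, (x, y, z))
                order.append(resnum)
            elif occ > best[resnum][0]:
                best[resnum] = (occ, restype, (x, y, z))
    if not best:
        raise LookupError_(
            f"{path}: chain {chain!r} not found or has no Cα (chains present: "
            f"{sorted(chains_seen)})"
        )
    residues = [
        (num, best[num][1], *best[num][2]) for num in sorted(order)
    ]
    return StructureCA(residues, label=f"{path.stem}:{chain}")


def read_fasta(path: str | Path, first_residue_number: int = 1) -> list[SequenceRecord]:
    """Read FASTA sequences; every record is anchored at *first_residue_number*."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), first_residue_number)
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# numbering
# ---------------------------------------------------------------------------

def apply_numbering_offset(obj, offset: int):
    """Shift every residue number by *offset*, preserving order.

    Works on :class:`ShiftTable`, :class:`SequenceRecord` and
    :class:`StructureCA`. Offsets compose additively and the scale passes
    through zero (a tag construct numbered from −3 is a contiguous range).
    """
    if isinstance(obj, ShiftTable):
        recs = [replace(r, residue_number=r.residue_number + offset) for r in obj.records]
        return ShiftTable(recs, state_label=obj.state_label, molar_ratio=obj.molar_ratio)
    if isinstance(obj, SequenceRecord):
        return replace(obj, first_residue_number=obj.first_residue_number + offset)
    if isinstance(obj, StructureCA):
        residues = [(n + offset, t, x, y, z) for n, t, x, y, z in obj.residues]
        return StructureCA(residues, label=obj.label)
    raise TypeError(f"cannot renumber object of type {type(obj).__name__}")


def assignment_completeness(
    table: ShiftTable,
    residue_range: tuple[int, int],
    residue_types: dict[int, str] | None = None,
) -> float:
    """Fraction of non-proline residues in *residue_range* with assigned H and N.

    How complete a backbone amide assignment is depends on the denominator
    convention — whether tag residues and termini are counted — so callers
    pass the range explicitly and may report several conventions side by
    side. Residue types known only outside the table (e.g. prolines with no
    assigned atoms at all) can be supplied via *residue_types*.
    """
    residue_types = residue_types or {}
    assigned = total = 0
    for res in range(residue_range[0], residue_range[1] + 1):
        rtype = table.residue_type(res) or residue_types.get(res)
        if rtype == "P":
            continue
        total += 1
        if table.get(res, "H") is not None and table.get(res, "N") is not None:
            assigned += 1
    return assigned / total if total else 0.0


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    """Serialize a float at 6 significant digits, deterministically."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{float(x):.6g}"


def write_report(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a finalized result object as TSV or JSON.

    Any object exposing ``to_table()`` (list of dicts with a fixed column
    order) and ``to_dict()`` can be written; floats are serialized at 6
    significant digits so repeated runs are byte-identical.
    """
    path = Path(path)
    if format == "json":
        payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
        path.write_text(json.dumps(_round_floats(payload), indent=2, sort_keys=False) + "\n",
                        encoding="utf-8")
        return
    if format != "tsv":
        raise ParseError(f"unknown report format {format!r}")
    rows = obj.to_table() if hasattr(obj, "to_table") else obj
    columns = getattr(obj, "table_columns", None)
    if columns is None:
        if not rows:
            raise ParseError("cannot write a TSV report with no declared columns")
        columns = list(rows[0].keys())
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(
            _fmt(v) if isinstance(v, float) else ("" if v is None else str(v))
            for v in (row[c] for c in columns)
        ))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(_fmt(obj)) if not math.isnan(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
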