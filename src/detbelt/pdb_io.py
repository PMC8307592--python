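"""Reading and writing membrane-oriented PDB files.

Structures are expected in the OPM/PPM convention: the z axis is normal to
the membrane plane and the coordinate origin sits at the membrane centre.
Files produced by the PPM server carry the membrane half-thickness either in
a REMARK line or implicitly as two planes of dummy marker atoms (residue
``DUM``) at z = ±half-thickness.  This module recovers both, using
fixed-column parsing per the wwPDB format; no re-orientation is attempted.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

from .errors import EmptyStructureError, InvalidThicknessError, NoHeavyAtomsError

logger = logging.getLogger(__name__)

#: Residue names marking the membrane boundary planes.
DEFAULT_DUMMY_RESIDUES = frozenset({"DUM"})

#: Residue names excluded from the heavy-atom set as solvent.
DEFAULT_SOLVENT_RESIDUES = frozenset({"HOH", "WAT"})

_TWO_LETTER_ELEMENTS = frozenset(
    {"FE", "ZN", "MG", "MN", "NA", "CL", "BR", "CA", "CU", "NI", "CO", "SE", "CD", "HG"}
)

# REMARK dialects carrying the half-thickness: the PPM/OPM output line and a
# generic keyword form.  First match wins; matching is case-insensitive.
_THICKNESS_PATTERNS = (
    re.compile(r"1/2\s+of\s+(?:the\s+)?bilayer\s+thickness:?\s*(\S+)", re.IGNORECASE),
    re.compile(r"half[\s_-]?thickness\s*[:=]?\s*(\S+)", re.IGNORECASE),
)


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record of a membrane-oriented structure."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    x: float
    y: float
    z: float
    record_kind: str = "ATOM"  # "ATOM" or "HETATM"
    is_dummy: bool = False
    is_hydrogen: bool = False


@dataclass
class OrientedStructure:
    """Parsed atoms plus the membrane half-thickness (Å), when recoverable."""

    atoms: list[AtomRecord] = field(default_factory=list)
    half_thickness: float | None = None
    source_label: str = ""
    n_skipped_records: int = 0


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Guess the element from the atom-name columns when cols 77-78 are blank.

    A name starting in column 13 can carry a two-letter element (FE, ZN, ...);
    otherwise the first alphabetic character is the element.
    """
    raw = atom_name
    stripped = raw.strip()
    if not stripped:
        return ""
    if len(raw) >= 2 and raw[0] != " ":
        two = raw[:2].strip().upper()
        # "CA" left-justified in a calcium HETATM vs the alpha carbon " CA "
        if two in _TWO_LETTER_ELEMENTS and not (
            two == "CA" and residue_name not in ("CA",)
        ):
            return two.capitalize() if len(two) > 1 else two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(
    line: str, dummy_residues: frozenset[str]
) -> AtomRecord | None:
    """Parse one fixed-column ATOM/HETATM line; None if coordinates are bad."""
    record_kind = "ATOM" if line.startswith("ATOM") else "HETATM"
    line = line.rstrip("\n").ljust(80)
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = -1
    atom_name = line[12:16]
    residue_name = line[17:20].strip()
    chain_id = line[21].strip()
    try:
        residue_number = int(line[22:26])
    except ValueError:
        residue_number = 0
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        return None
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        return None
    element = line[76:78].strip().capitalize()
    if not element:
        element = _infer_element(atom_name, residue_name)
    is_dummy = residue_name.upper() in dummy_residues
    return AtomRecord(
        serial=serial,
        atom_name=atom_name.strip(),
        element=element,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_number=residue_number,
        x=x,
        y=y,
        z=z,
        record_kind=record_kind,
        is_dummy=is_dummy,
        is_hydrogen=element.upper() in ("H", "D"),
    )


def parse_pdb(
    text: str,
    *,
    source_label: str = "",
    dummy_residues: frozenset[str] = DEFAULT_DUMMY_RESIDUES,
) -> OrientedStructure:
    """Parse a PDB-format character stream into an :class:`OrientedStructure`.

    Only the first MODEL of a multi-model file is read (the belt is computed
    on a single conformation).  Records with malformed coordinate fields are
    skipped with a logged warning; a stream with no parseable atom record at
    all raises :class:`EmptyStructureError`.
    """
    atoms: list[AtomRecord] = []
    n_skipped = 0
    model_count = 0
    in_skipped_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            model_count += 1
            if model_count > 1:
                in_skipped_model = True
            continue
        if rec == "ENDMDL":
            continue
        if in_skipped_model:
            continue
        if rec in ("ATOM", "HETATM"):
            atom = _parse_atom_line(line, dummy_residues)
            if atom is None:
                n_skipped += 1
            else:
                atoms.append(atom)
    if model_count > 1:
        logger.warning(
            "multi-model file: read MODEL 1 only (%d models present)", model_count
        )
    if n_skipped:
        logger.warning("skipped %d atom record(s) with malformed coordinates", n_skipped)
    if not atoms:
        raise EmptyStructureError("empty structure: no parseable ATOM/HETATM records")
    half = extract_half_thickness(text, atoms)
    return OrientedStructure(
        atoms=atoms,
        half_thickness=half,
        source_label=source_label,
        n_skipped_records=n_skipped,
    )


def extract_half_thickness(
    text: str, atoms: list[AtomRecord] | None = None
) -> float | None:
    """Recover the membrane half-thickness (Å) from a PDB stream.

    The first REMARK line matching a known half-thickness dialect wins.  If no
    REMARK matches, the two dummy-atom layers at z = ±half-thickness serve as
    a fallback (max |z| over dummy atoms).  Returns ``None`` when neither
    source exists; raises :class:`InvalidThicknessError` when a REMARK matched
    but its value is non-numeric or non-positive (no silent fallback).
    """
    for line in text.splitlines():
        if not line.startswith("REMARK"):
            continue
        for pat in _THICKNESS_PATTERNS:
            m = pat.search(line)
            if m is None:
                continue
            token = m.group(1)
            try:
                value = float(token)
            except ValueError:
                raise InvalidThicknessError(
                    f"invalid thickness remark: non-numeric value {token!r}"
                ) from None
            if not math.isfinite(value) or value <= 0:
                raise InvalidThicknessError(
                    f"invalid thickness remark: value {value} must be > 0"
                )
            return value
    if atoms:
        dummy_z = [abs(a.z) for a in atoms if a.is_dummy]
        if dummy_z:
            return max(dummy_z)
    return None


def protein_heavy_atoms(
    structure: OrientedStructure,
    *,
    solvent_residues: frozenset[str] = DEFAULT_SOLVENT_RESIDUES,
) -> list[AtomRecord]:
    """Protein heavy atoms: not dummy, not hydrogen, not solvent. Order kept."""
    out = [
        a
        for a in structure.atoms
        if not a.is_dummy
        and not a.is_hydrogen
        and a.residue_name.upper() not in solvent_residues
    ]
    if not out:
        raise NoHeavyAtomsError("no heavy atoms after dummy/hydrogen/solvent filtering")
    return out


def _format_atom_line(atom: AtomRecord) -> str:
    name = atom.atom_name
    # wwPDB convention: 1-3 letter names of single-letter elements start col 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name:<3s}"
    else:
        name = f"{name:<4s}"
    return (
        f"{atom.record_kind:<6s}{atom.serial:>5d} {name}"
        f" {atom.residue_name:<3s} {atom.chain_id or 'A':1s}"
        f"{atom.residue_number:>4d}    "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}"
    )


def serialize_pdb(structure: OrientedStructure) -> str:
    """Write an :class:`OrientedStructure` back to PDB text.

    Emits a generic half-thickness REMARK when the value is known, so the
    round trip through :func:`parse_pdb` preserves it.
    """
    lines = []
    if structure.source_label:
        lines.append(f"REMARK     source: {structure.source_label}")
    if structure.half_thickness is not None:
        lines.append(
            f"REMARK     1/2 of bilayer thickness:  {structure.half_thickness:7.1f}"
        )
    lines.extend(_format_atom_line(a) for a in structure.atoms)
    lines.append("END")
    return "\n".join(lines) + "\n"


def with_atoms(structure: OrientedStructure, atoms: list[AtomRecord]) -> OrientedStructure:
    """Copy of *structure* with a different atom list (metadata preserved)."""
    return replace(structure, atoms=list(atoms))
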