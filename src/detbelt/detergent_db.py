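"""Curated amphiphile database and monomer-volume accounting.

Each entry records a solubilizing amphiphile (detergent, lipid, amphipol or
bile salt): identity, chemistry (formula, MW, SMILES), critical micellar
concentration, and the nominal volume one monomer occupies in the belt.

Monomer volumes in the shipped table are additive van der Waals estimates
(atomic increments with bond and ring corrections, see
:func:`estimate_monomer_volume`), labelled ``volume_source=additive_estimate``
and overridable per run.  The belt's outer radius scales with the square root
of total volume, so the estimator's few-percent bias moves belt thickness
only modestly; provenance is kept explicit regardless.

The table format is TSV with a header, one entry per row, aliases
pipe-separated — diffable and hand-editable.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

from .errors import DatabaseValidationError, SpecValidationError, UnknownDetergentError

#: Zhao-type additive van der Waals volume scheme (Å³): atomic increments
#: minus corrections per bond and per ring.
ATOM_VOLUME_INCREMENTS: dict[str, float] = {
    "C": 20.58,
    "H": 7.24,
    "N": 15.60,
    "O": 14.71,
    "S": 24.43,
    "P": 24.87,
    "F": 13.31,
    "CL": 22.45,
    "BR": 26.52,
    "I": 32.52,
}
BOND_CORRECTION = 5.92
AROMATIC_RING_CORRECTION = 14.7
NONAROMATIC_RING_CORRECTION = 3.8

_REQUIRED_COLUMNS = (
    "id",
    "full_name",
    "family",
    "formula",
    "mw",
    "cmc_mM",
    "smiles",
    "monomer_volume_A3",
    "volume_source",
    "reference",
    "aliases",
    "color",
)


@dataclass
class DetergentEntry:
    """One database record for a belt-forming amphiphile."""

    id: str
    full_name: str
    family: str
    formula: str
    mw: float
    cmc: float | None  # mM at the cited reference condition; None = no CMC
    smiles: str
    monomer_volume: float  # Å³
    volume_source: str  # curated | additive_estimate | user_override
    reference: str
    aliases: list[str] = field(default_factory=list)
    display_color: tuple[float, float, float] = (0.5, 0.5, 0.5)


@dataclass
class BeltSpec:
    """Ordered (detergent id, monomer count) pairs describing the belt."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise SpecValidationError("belt spec is empty")
        for det_id, n in self.entries:
            if not isinstance(n, int) or isinstance(n, bool):
                raise SpecValidationError(
                    f"monomer count for {det_id!r} must be an integer, got {n!r}"
                )
            if n < 1:
                raise SpecValidationError(
                    f"monomer count must be positive, got {n} for {det_id!r}"
                )


def _parse_color(token: str) -> tuple[float, float, float]:
    parts = [float(p) for p in token.split(",")]
    if len(parts) != 3 or not all(0.0 <= p <= 1.0 for p in parts):
        raise DatabaseValidationError(f"bad color triple {token!r}")
    return (parts[0], parts[1], parts[2])


def _validate(entries: list[DetergentEntry]) -> None:
    seen_ids: dict[str, str] = {}
    dup_ids = []
    for e in entries:
        key = e.id.lower()
        if key in seen_ids:
            dup_ids.append(e.id)
        seen_ids[key] = e.id
    seen_alias: dict[str, str] = {}
    dup_alias = []
    for e in entries:
        for a in e.aliases:
            key = a.lower()
            if key in seen_alias or key in seen_ids:
                dup_alias.append(a)
            seen_alias[key] = e.id
    if dup_ids or dup_alias:
        raise DatabaseValidationError(
            "duplicate identifiers: "
            + ", ".join(sorted(set(dup_ids + dup_alias)))
        )
    for e in entries:
        if e.monomer_volume <= 0:
            raise DatabaseValidationError(f"{e.id}: monomer_volume must be > 0")
        if e.mw <= 0:
            raise DatabaseValidationError(f"{e.id}: mw must be > 0")


def _rows_to_entries(reader: csv.DictReader) -> list[DetergentEntry]:
    if reader.fieldnames is None:
        raise DatabaseValidationError("database table has no header")
    missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise DatabaseValidationError(f"missing required column(s): {missing}")
    entries = []
    for row in reader:
        for col in _REQUIRED_COLUMNS:
            if col not in ("cmc_mM", "aliases") and not (row.get(col) or "").strip():
                raise DatabaseValidationError(
                    f"row {row.get('id', '?')!r}: missing required field {col!r}"
                )
        cmc_raw = (row["cmc_mM"] or "").strip()
        entries.append(
            DetergentEntry(
                id=row["id"].strip(),
                full_name=row["full_name"].strip(),
                family=row["family"].strip(),
                formula=row["formula"].strip(),
                mw=float(row["mw"]),
                cmc=float(cmc_raw) if cmc_raw else None,
                smiles=row["smiles"].strip(),
                monomer_volume=float(row["monomer_volume_A3"]),
                volume_source=row["volume_source"].strip(),
                reference=row["reference"].strip(),
                aliases=[a for a in row["aliases"].split("|") if a.strip()],
                display_color=_parse_color(row["color"]),
            )
        )
    return entries


def load_database(source: str | None = None) -> list[DetergentEntry]:
    """Load and validate a detergent table (the packaged one by default)."""
    if source is None:
        text = (
            resources.files("detbelt").joinpath("data/detergents.tsv").read_text()
        )
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    entries = _rows_to_entries(reader)
    _validate(entries)
    return entries


def serialize_database(entries: list[DetergentEntry]) -> str:
    """Write entries back to the TSV table format."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_REQUIRED_COLUMNS)
    for e in entries:
        writer.writerow(
            [
                e.id,
                e.full_name,
                e.family,
                e.formula,
                f"{e.mw:g}",
                "" if e.cmc is None else f"{e.cmc:g}",
                e.smiles,
                f"{e.monomer_volume:g}",
                e.volume_source,
                e.reference,
                "|".join(e.aliases),
                ",".join(f"{c:g}" for c in e.display_color),
            ]
        )
    return out.getvalue()


def _edit_distance(a: str, b: str, cap: int = 3) -> int:
    """Levenshtein distance with early exit above *cap*."""
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > cap:
            return cap + 1
        prev = cur
    return prev[-1]


def lookup(query: str, db: list[DetergentEntry]) -> DetergentEntry:
    """Resolve a detergent by id, then alias, then full name (case-insensitive).

    Unknown queries raise :class:`UnknownDetergentError` carrying nearby ids
    (edit distance <= 2) as suggestions.
    """
    q = query.strip().lower()
    for e in db:
        if e.id.lower() == q:
            return e
    for e in db:
        if any(a.lower() == q for a in e.aliases):
            return e
    for e in db:
        if e.full_name.lower() == q:
            return e
    suggestions = sorted(
        (e.id for e in db if _edit_distance(q, e.id.lower(), 2) <= 2),
        key=lambda s: (_edit_distance(q, s.lower(), 2), s),
    )
    raise UnknownDetergentError(query, suggestions)


def total_volume(
    spec: BeltSpec,
    db: list[DetergentEntry],
    volume_overrides: dict[str, float] | None = None,
) -> tuple[list[tuple[str, float]], float]:
    """Per-detergent volumes (n_monomers × monomer volume) and their sum (Å³).

    ``volume_overrides`` maps detergent ids to per-run monomer volumes,
    replacing the database value for this computation only.
    """
    overrides = {k.lower(): v for k, v in (volume_overrides or {}).items()}
    per_det: list[tuple[str, float]] = []
    v_total = 0.0
    for det_id, n in spec.entries:
        entry = lookup(det_id, db)
        vol = overrides.get(entry.id.lower(), entry.monomer_volume)
        if vol <= 0:
            raise SpecValidationError(
                f"monomer volume for {entry.id} must be > 0, got {vol}"
            )
        v = n * vol
        per_det.append((entry.id, v))
        v_total += v
    return per_det, v_total


def estimate_monomer_volume(
    composition: dict[str, int],
    n_bonds: int,
    n_aromatic_rings: int = 0,
    n_nonaromatic_rings: int = 0,
) -> float:
    """Additive van der Waals volume (Å³) of a molecule.

    Sum of atomic increments minus 5.92 Å³ per bond, 14.7 Å³ per aromatic
    ring and 3.8 Å³ per non-aromatic ring.  ``composition`` maps element
    symbols to atom counts (hydrogens included).
    """
    if not composition or sum(composition.values()) < 1:
        raise ValueError("composition must contain at least one atom")
    if min(composition.values()) < 0 or n_bonds < 0:
        raise ValueError("counts must be >= 0")
    total = 0.0
    for element, count in composition.items():
        inc = ATOM_VOLUME_INCREMENTS.get(element.upper())
        if inc is None:
            raise ValueError(f"no volume increment for element {element!r}")
        total += count * inc
    total -= BOND_CORRECTION * n_bonds
    total -= AROMATIC_RING_CORRECTION * n_aromatic_rings
    total -= NONAROMATIC_RING_CORRECTION * n_nonaromatic_rings
    if total <= 0:
        raise ValueError(
            f"additive volume came out non-positive ({total:.2f} Å³); "
            "check the composition and bond count"
        )
    return total


def composition_from_smiles(smiles: str):
    """Atom counts, bond count and ring counts of a SMILES string.

    Requires the optional cheminformatics backend (rdkit); the database never
    needs this at load time — it is a convenience for curating new entries.
    Returns ``(composition, n_bonds, n_aromatic_rings, n_nonaromatic_rings)``.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "composition_from_smiles needs the 'chem' extra (rdkit)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    comp: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        comp[sym] = comp.get(sym, 0) + 1
    n_bonds = mol.GetNumBonds()
    ring_info = mol.GetRingInfo()
    n_arom = 0
    n_nonarom = 0
    for ring in ring_info.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_arom += 1
        else:
            n_nonarom += 1
    return comp, n_bonds, n_arom, n_nonarom


def estimate_from_smiles(smiles: str) -> float:
    """Additive monomer volume (Å³) straight from a SMILES string."""
    comp, n_bonds, n_arom, n_nonarom = composition_from_smiles(smiles)
    return estimate_monomer_volume(comp, n_bonds, n_arom, n_nonarom)
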