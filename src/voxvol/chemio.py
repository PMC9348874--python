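"""Structure and element-property input/output.

Reads chemical structures from XYZ or PDB text, reads element-property
tables (vdW radius and atomic weight per element symbol) and resolves
per-atom radii/weights.  Atoms are modelled as hard spheres throughout the
package; everything downstream consumes the :class:`Atom` produced here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, VoxVolError

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "ElementTable",
    "read_xyz",
    "read_pdb",
    "read_element_table",
    "default_element_table",
    "attach_elements",
    "write_xyz",
]


@dataclass(frozen=True)
class Atom:
    """One atom: a sphere at ``position`` (Å) of vdW radius ``radius`` (Å).

    ``radius`` and ``weight`` are ``None`` until resolved by
    :func:`attach_elements`.
    """

    symbol: str
    position: tuple[float, float, float]
    radius: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise VoxVolError(f"non-finite coordinates for atom {self.symbol!r}")
        if self.radius is not None and self.radius <= 0:
            raise VoxVolError(f"atom {self.symbol!r} has non-positive radius")
        if self.weight is not None and self.weight < 0:
            raise VoxVolError(f"atom {self.symbol!r} has negative weight")


@dataclass
class Structure:
    """An ordered list of atoms as read from a structure file."""

    atoms: list[Atom]
    source_format: str = "XYZ"
    hetatm_included: bool = False

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        if any(a.radius is None for a in self.atoms):
            raise VoxVolError("radii not resolved; call attach_elements first")
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_weight(self) -> float:
        if any(a.weight is None for a in self.atoms):
            raise VoxVolError("weights not resolved; call attach_elements first")
        return float(sum(a.weight for a in self.atoms))


@dataclass
class ElementTable:
    """Map of element symbol -> (vdW radius Å, atomic weight g/mol)."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def radius(self, symbol: str) -> float:
        return self.entries[symbol][0]

    def weight(self, symbol: str) -> float:
        return self.entries[symbol][1]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries


def normalize_symbol(symbol: str) -> str:
    """Case-normalize an element symbol: first letter upper, rest lower."""
    return symbol[:1].upper() + symbol[1:].lower()


def _check_symbol(symbol: str, lineno: int | None = None) -> str:
    if not symbol.isalpha():
        where = f" (line {lineno})" if lineno is not None else ""
        raise ParseError(
            f"element symbol {symbol!r} may only contain alphabetic characters{where}"
        )
    return normalize_symbol(symbol)


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(text: str) -> Structure:
    """Parse XYZ-format content: count line, comment line, then atom records.

    The comment line is ignored entirely.  Raises :class:`ParseError` naming
    the offending line on malformed records or a count mismatch.
    """
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"line 1: expected an atom count, got {lines[0]!r}") from None
    atoms: list[Atom] = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {i}: expected 'symbol x y z', got {line!r}")
        symbol = _check_symbol(parts[0], i)
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise ParseError(f"line {i}: non-numeric coordinate in {line!r}") from None
        atoms.append(Atom(symbol, (x, y, z)))
    if len(atoms) != count:
        raise ParseError(
            f"atom count mismatch: header says {count}, file contains {len(atoms)}"
        )
    if not atoms:
        raise ParseError("XYZ file contains no atoms")
    return Structure(atoms, source_format="XYZ")


def write_xyz(structure: Structure, comment: str = "") -> str:
    """Serialize a structure back to XYZ text (used for fixtures and round-trips)."""
    out = [str(len(structure.atoms)), comment.replace("\n", " ")]
    for a in structure.atoms:
        x, y, z = a.position
        out.append(f"{a.symbol} {x:.6f} {y:.6f} {z:.6f}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(text: str, include_hetatm: bool = False) -> Structure:
    """Parse fixed-column PDB ATOM/HETATM records (via gemmi).

    ATOM records are always kept; HETATM only when ``include_hetatm``.
    Alternate locations other than blank or 'A' are dropped to avoid
    double-counting.  The element is taken from the element column, falling
    back to the leading alphabetic characters of the atom name.
    """
    import gemmi

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"could not parse PDB content: {e}") from None
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ParseError("PDB content contains no ATOM/HETATM records")
    model = st[0]
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            if het and not include_hetatm:
                continue
            for at in residue:
                if at.altloc not in ("", "\x00", "A"):
                    continue
                el = at.element
                if el.is_hydrogen:
                    symbol = "H"
                elif el.name and el.name != "X":
                    symbol = normalize_symbol(el.name)
                else:
                    # no usable element column: infer from the atom-name field
                    letters = "".join(c for c in at.name if c.isalpha())
                    if not letters:
                        raise ParseError(
                            f"cannot infer element for atom {at.name!r}"
                        )
                    symbol = normalize_symbol(letters[:2] if letters[:2] in
                                              ("Cl", "Br", "Fe", "Zn", "Mg", "Na", "Ca")
                                              else letters[:1])
                    log.warning("element inferred from atom name %r -> %s",
                                at.name, symbol)
                atoms.append(Atom(symbol, (at.pos.x, at.pos.y, at.pos.z)))
    if not atoms:
        raise ParseError("PDB content contains no usable ATOM/HETATM records")
    return Structure(atoms, source_format="PDB", hetatm_included=include_hetatm)


# ---------------------------------------------------------------------------
# Element table
# ---------------------------------------------------------------------------

def read_element_table(text: str) -> ElementTable:
    """Parse a whitespace-separated table of ``symbol radius weight`` rows.

    Comment lines (#) and a header line are tolerated.  Duplicate symbols:
    last wins, with a logged warning.  Non-positive radii are an error.
    """
    entries: dict[str, tuple[float, float]] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise ParseError(f"line {i}: expected 'symbol radius weight', got {line!r}")
        try:
            radius, weight = float(parts[1]), float(parts[2])
        except ValueError:
            if i == 1:
                continue  # header line
            raise ParseError(f"line {i}: non-numeric radius/weight in {line!r}") from None
        symbol = _check_symbol(parts[0], i)
        if radius <= 0:
            raise ParseError(f"line {i}: non-positive radius {radius} for {symbol}")
        if weight < 0:
            raise ParseError(f"line {i}: negative weight {weight} for {symbol}")
        if symbol in entries:
            log.warning("duplicate element symbol %s; last entry wins", symbol)
        entries[symbol] = (radius, weight)
    if not entries:
        raise ParseError("element table contains no entries")
    return ElementTable(entries)


def default_element_table() -> ElementTable:
    """The element table shipped with the package (user-replaceable data)."""
    text = resources.files("voxvol").joinpath("data/elements.dat").read_text()
    return read_element_table(text)


def attach_elements(
    structure: Structure,
    table: ElementTable | None = None,
    overrides: Mapping[str, float] | None = None,
) -> Structure:
    """Resolve every atom's radius and weight from ``table``.

    ``overrides`` maps symbol -> radius and takes precedence over the table.
    Unknown symbols raise an error listing all offenders.  Atom count and
    order are preserved.
    """
    if table is None:
        table = default_element_table()
    overrides = {normalize_symbol(k): v for k, v in (overrides or {}).items()}
    unknown = sorted(
        {a.symbol for a in structure.atoms}
        - set(table.entries) - set(overrides)
    )
    if unknown:
        raise VoxVolError(
            "unknown element symbol(s): " + ", ".join(unknown)
            + "; add them to the element table or pass a radius override"
        )
    resolved = []
    for a in structure.atoms:
        radius = overrides.get(a.symbol, table.entries.get(a.symbol, (None, None))[0])
        weight = table.weight(a.symbol) if a.symbol in table else 0.0
        resolved.append(replace(a, radius=radius, weight=weight))
    return Structure(resolved, structure.source_format, structure.hetatm_included)
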