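"""The 16-code surface atom-type scheme.

Each surface protein atom is typed by a 3-code name: element (C/N/O/S),
hybridisation context (2 = sp2, 3 = sp3, R = aromatic ring, C =
conjugated/resonating) and electrostatics (N = nonpolar, P = polar,
V = variable, C = charged), plus the two 3-letter names PHO (phosphorus)
and MET (metal) for chemistry that needs no finer split.  The "variable"
code exists for the histidine imidazole nitrogens, which can be either
protonated or deprotonated; the tryptophan ring nitrogen shares it.

The full residue x atom table is shipped as an editable tab-separated data
file (``data/typing_table.tsv``) so disagreements with other typing
conventions can be amended without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .structure import (
    NON_SURFACE,
    MoleculeClass,
    Structure,
    STANDARD_AMINO_ACIDS,
)

__all__ = [
    "ATOM_TYPE_CODES",
    "AtomTypeTable",
    "TypingError",
    "assign_atom_types",
    "list_atom_types",
]

#: The closed set of 16 codes, in canonical (channel) order.
ATOM_TYPE_CODES: tuple[str, ...] = (
    "C2P", "C3N", "C3P", "CRP", "CRN", "CCP",
    "N3C", "NRV", "NCC", "NCP",
    "O3P", "OCC", "OCP",
    "S3N", "PHO", "MET",
)

#: Pseudo-residue key for backbone atoms shared by all standard amino acids.
_BACKBONE = "*"


class TypingError(KeyError):
    """A surface protein atom has no entry in the typing table."""


@dataclass(frozen=True)
class AtomTypeTable:
    """Lookup (residue_name, atom_name) -> atom-type code."""

    entries: dict[tuple[str, str], str]

    _default_cache = None

    @classmethod
    def from_tsv(cls, path: str | Path | None = None) -> "AtomTypeTable":
        """Load a table from a 3-column tab-separated file.

        Lines starting with ``#`` are comments; the residue column may use
        the ``*`` pseudo-residue for backbone atoms common to all standard
        amino acids.
        """
        if path is None:
            text = (
                resources.files("voxbind").joinpath("data/typing_table.tsv").read_text()
            )
        else:
            text = Path(path).read_text()
        entries: dict[tuple[str, str], str] = {}
        for lineno, ln in enumerate(text.splitlines(), start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 3:
                raise ValueError(f"typing table line {lineno}: expected 3 fields, got {ln!r}")
            res, atom, code = (p.strip() for p in parts)
            if code not in ATOM_TYPE_CODES:
                raise ValueError(f"typing table line {lineno}: unknown code {code!r}")
            entries[(res, atom)] = code
        return cls(entries=entries)

    @classmethod
    def default(cls) -> "AtomTypeTable":
        if AtomTypeTable._default_cache is None:
            AtomTypeTable._default_cache = cls.from_tsv()
        return AtomTypeTable._default_cache

    def lookup(self, residue_name: str, atom_name: str) -> str:
        """Return the code for one atom, raising :class:`TypingError` if absent."""
        key = (residue_name, atom_name)
        if key in self.entries:
            return self.entries[key]
        if residue_name in STANDARD_AMINO_ACIDS:
            bkey = (_BACKBONE, atom_name)
            if bkey in self.entries:
                return self.entries[bkey]
        raise TypingError(f"no atom type for atom {atom_name!r} in residue {residue_name!r}")

    def is_typeable(self, residue_name: str, atom_name: str) -> bool:
        try:
            self.lookup(residue_name, atom_name)
        except TypingError:
            return False
        return True


def assign_atom_types(s: Structure, table: AtomTypeTable | None = None) -> Structure:
    """Type every surface protein atom; non-surface ones get the sentinel.

    Surface flags must already be set (see :mod:`voxbind.surface`).  Metals
    retained as hetero atoms are typed MET through their table entries.
    """
    if table is None:
        table = AtomTypeTable.default()
    for a in s.atoms:
        if a.molecule_class is not MoleculeClass.PROTEIN:
            continue
        if a.is_surface:
            a.atom_type = table.lookup(a.residue_name, a.name)
        else:
            a.atom_type = NON_SURFACE
    return s


def list_atom_types(table: AtomTypeTable | None = None) -> list[str]:
    """Deterministic channel ordering of the 16 codes used by featurization."""
    return list(ATOM_TYPE_CODES)
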