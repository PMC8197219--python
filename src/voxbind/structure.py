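"""Structure parsing, molecule classification and complex screening.

A protein--DNA complex enters the pipeline as a standard PDB file and is
reduced to a flat, ordered list of heavy atoms.  Each atom carries the
fields later stages fill in: solvent accessibility, the surface flag, and
one of the 16 surface atom-type codes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "MoleculeClass",
    "Atom",
    "Structure",
    "ParseError",
    "parse_pdb",
    "classify_molecules",
    "screen_complex",
    "write_table",
    "read_table",
    "STANDARD_AMINO_ACIDS",
    "DNA_RESIDUES",
]

#: The 20 standard amino acids (three-letter codes).
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Deoxyribonucleotide residue names, including pre-remediation single-letter
#: naming still found in older PDB entries.
DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT", "DI", "A", "C", "G", "T"})

_WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

#: Sentinel atom-type for protein atoms not on the surface.
NON_SURFACE = "NON_SURFACE"
#: Sentinel for atoms whose type has not been assigned yet.
UNASSIGNED = "UNASSIGNED"


class MoleculeClass(enum.Enum):
    PROTEIN = "PROTEIN"
    DNA = "DNA"
    OTHER = "OTHER"


class ParseError(ValueError):
    """Raised for unreadable, empty or coordinate-less structure files."""


@dataclass
class Atom:
    """One heavy atom of the complex.

    ``sasa``, ``is_surface`` and ``atom_type`` start unset and are filled by
    the surface and atom-typing stages; ``atom_type`` only ever holds one of
    the 16 surface codes, :data:`NON_SURFACE`, or :data:`UNASSIGNED`.
    """

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    element: str
    icode: str = ""
    molecule_class: MoleculeClass = MoleculeClass.OTHER
    sasa: float = float("nan")
    is_surface: bool = False
    atom_type: str = UNASSIGNED

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ParseError(
                f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector"
            )


@dataclass
class Structure:
    """An ordered collection of atoms with a PDB-style identifier."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def atoms_of(self, cls: MoleculeClass) -> list[Atom]:
        return [a for a in self.atoms if a.molecule_class is cls]

    def coords_of(self, cls: MoleculeClass) -> np.ndarray:
        """(n, 3) coordinate array of one molecule class (empty -> (0, 3))."""
        sel = self.atoms_of(cls)
        if not sel:
            return np.empty((0, 3))
        return np.array([a.coords for a in sel])


def parse_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only the first MODEL is kept.  Hydrogens and waters are dropped, and
    alternate locations are resolved by keeping altloc ``' '`` or ``'A'``.
    HETATM records other than water are kept only with ``keep_hetero``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi wraps line info in message
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    st.setup_entities()

    atoms: list[Atom] = []
    serial = 0
    model = st[0]  # first MODEL only
    for chain in model:
        for residue in chain:
            rname = residue.name.strip()
            if rname in _WATER_RESIDUES:
                continue
            if residue.het_flag == "H" and not keep_hetero and rname not in DNA_RESIDUES:
                continue
            seen: set[str] = set()
            for at in residue:
                if at.altloc not in ("\0", "", " ", "A"):
                    continue
                if at.name in seen:  # duplicate after altloc filtering
                    continue
                elem = at.element.name.upper()
                if elem in ("H", "D"):
                    continue
                seen.add(at.name)
                serial += 1
                pos = at.pos
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        residue_name=rname,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        coords=np.array([pos.x, pos.y, pos.z]),
                        element=elem,
                    )
                )
    if not atoms:
        raise ParseError(f"{path}: no usable heavy atoms after filtering")
    pdb_id = (st.name or path.stem).strip().lower() or path.stem
    return Structure(id=pdb_id, atoms=atoms)


def classify_molecules(s: Structure) -> Structure:
    """Assign every atom a molecule class by residue name.

    DNA nucleotides (including legacy single-letter names) map to DNA, the 20
    standard amino acids to PROTEIN, and everything else to OTHER.
    """
    for a in s.atoms:
        if a.residue_name in DNA_RESIDUES:
            a.molecule_class = MoleculeClass.DNA
        elif a.residue_name in STANDARD_AMINO_ACIDS:
            a.molecule_class = MoleculeClass.PROTEIN
        else:
            a.molecule_class = MoleculeClass.OTHER
    return s


def screen_complex(s: Structure, table=None) -> bool:
    """Usability screen: at least one DNA atom and a fully typeable protein.

    A complex passes only if every PROTEIN atom has an entry in the typing
    table, so downstream featurization can never meet an unknown atom.
    """
    from .atom_typing import AtomTypeTable  # local import to avoid a cycle

    if table is None:
        table = AtomTypeTable.default()
    has_dna = any(a.molecule_class is MoleculeClass.DNA for a in s.atoms)
    if not has_dna:
        return False
    has_protein = False
    for a in s.atoms:
        if a.molecule_class is MoleculeClass.PROTEIN:
            has_protein = True
            if not table.is_typeable(a.residue_name, a.name):
                return False
    return has_protein


# ---------------------------------------------------------------------------
# Intermediate tab-separated format: one atom per line, ten fields.

_TABLE_HEADER = [
    "serial", "name", "residue_name", "chain", "residue_seq",
    "x", "y", "z", "element", "molecule_class",
]


def write_table(s: Structure, path: str | Path) -> Path:
    """Write the tab-separated intermediate representation of a structure."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#id\t%s\n" % s.id)
        fh.write("\t".join(_TABLE_HEADER) + "\n")
        for a in s.atoms:
            x, y, z = a.coords
            fh.write(
                f"{a.serial}\t{a.name}\t{a.residue_name}\t{a.chain_id}\t"
                f"{a.residue_seq}{a.icode}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t"
                f"{a.element}\t{a.molecule_class.value}\n"
            )
    return path


def read_table(path: str | Path) -> Structure:
    """Inverse of :func:`write_table`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#id\t"):
        raise ParseError(f"{path}: not an intermediate atom table")
    sid = lines[0].split("\t", 1)[1]
    atoms: list[Atom] = []
    for ln in lines[2:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        if len(f) != 10:
            raise ParseError(f"{path}: malformed line: {ln!r}")
        seq = f[4]
        icode = ""
        if seq and not seq.lstrip("-").isdigit():
            seq, icode = seq[:-1], seq[-1]
        atoms.append(
            Atom(
                serial=int(f[0]),
                name=f[1],
                residue_name=f[2],
                chain_id=f[3],
                residue_seq=int(seq),
                icode=icode,
                coords=np.array([float(f[5]), float(f[6]), float(f[7])]),
                element=f[8],
                molecule_class=MoleculeClass(f[9]),
            )
        )
    return Structure(id=sid, atoms=atoms)
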