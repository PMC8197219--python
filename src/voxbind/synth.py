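"""Deterministic synthetic fixtures.

Two generators make every pipeline stage testable without downloading real
structures: toy protein--DNA complexes with standard residue and atom
nomenclature (so parsing, typing and screening all succeed), and planted
voxel-pattern datasets that give the network a learnable toy segmentation
task.  Geometry is idealized, not physical — the fixtures exercise
pipeline mechanics, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .atom_typing import AtomTypeTable
from .featurize import BindingMask, GridSpec, VoxelGrid, N_CHANNELS
from .structure import (
    Atom,
    MoleculeClass,
    Structure,
    STANDARD_AMINO_ACIDS,
)

__all__ = ["SynthSpec", "generate_complex", "generate_planted_task", "write_pdb"]

# Base atoms by nucleotide; sugar/phosphate names are shared.
_SUGAR = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
_BASES = {
    "DA": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "DG": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "DC": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "DT": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
}


@dataclass
class SynthSpec:
    seed: int = 0
    n_residues: int = 12
    dna_length: int = 6
    contact_distance: float = 4.0  # target min protein-DNA separation, Å
    residue_alphabet: tuple[str, ...] = field(
        default_factory=lambda: tuple(sorted(STANDARD_AMINO_ACIDS))
    )

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.dna_length < 2:
            raise ValueError("need at least 2 nucleotides per strand")
        bad = set(self.residue_alphabet) - STANDARD_AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues in alphabet: {sorted(bad)}")


def _sidechain_atoms(table: AtomTypeTable) -> dict[str, list[str]]:
    """Side-chain atom names per residue, read off the shipped typing table."""
    out: dict[str, list[str]] = {r: [] for r in STANDARD_AMINO_ACIDS}
    for (res, atom), _ in table.entries.items():
        if res in out:
            out[res].append(atom)
    return out


def generate_complex(spec: SynthSpec | None = None) -> Structure:
    """A toy helical protein next to a twin-strand DNA ladder.

    The DNA is translated along the contact axis until the minimum
    protein--DNA atom distance is within ±0.5 Å of
    ``spec.contact_distance``.
    """
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    table = AtomTypeTable.default()
    side = _sidechain_atoms(table)

    atoms: list[Atom] = []
    serial = 0

    def add(name, res, chain, seq, xyz, elem, cls):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(serial=serial, name=name, residue_name=res, chain_id=chain,
                 residue_seq=seq, coords=np.asarray(xyz, float), element=elem,
                 molecule_class=cls)
        )

    # protein: alpha-helix-like CA trace along z, residues drawn from alphabet
    for i in range(spec.n_residues):
        res = spec.residue_alphabet[int(rng.integers(len(spec.residue_alphabet)))]
        ang = np.deg2rad(100.0 * i)
        ca = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        tang = np.cross(axis, radial)
        add("N", res, "A", i + 1, ca - 0.8 * tang - np.array([0, 0, 1.0]), "N",
            MoleculeClass.PROTEIN)
        add("CA", res, "A", i + 1, ca, "C", MoleculeClass.PROTEIN)
        add("C", res, "A", i + 1, ca + 0.9 * tang + np.array([0, 0, 0.9]), "C",
            MoleculeClass.PROTEIN)
        add("O", res, "A", i + 1, ca + 1.1 * tang + np.array([0, 0, 1.9]), "O",
            MoleculeClass.PROTEIN)
        # side chain marches outward from CA with mild deterministic jitter
        for k, aname in enumerate(side[res]):
            jitter = 0.25 * rng.standard_normal(3)
            pos = ca + radial * (1.5 * (k + 1)) + jitter
            add(aname, res, "A", i + 1, pos, aname[0], MoleculeClass.PROTEIN)

    # DNA: two antiparallel strands as helical ladders along z
    nts = ["DA", "DT", "DG", "DC"]
    protein_coords = np.array([a.coords for a in atoms])
    dna_local: list[tuple[str, str, int, np.ndarray, str]] = []
    for chain, phase in (("B", 0.0), ("C", np.pi)):
        for j in range(spec.dna_length):
            res = nts[int(rng.integers(4))]
            ang = np.deg2rad(36.0 * j) + phase
            anchor = np.array([9.0 * np.cos(ang), 9.0 * np.sin(ang), 3.4 * j])
            inward = -np.array([np.cos(ang), np.sin(ang), 0.0])
            names = _SUGAR + _BASES[res]
            for k, aname in enumerate(names):
                jitter = 0.2 * rng.standard_normal(3)
                pos = anchor + inward * (0.45 * k) + jitter
                dna_local.append((aname, res, j + 1, pos, chain))

    # shift the whole DNA along +x until the minimum separation hits target
    dna_coords = np.array([p for (_, _, _, p, _) in dna_local])
    tree = cKDTree(protein_coords)

    def min_dist(shift: float) -> float:
        d, _ = tree.query(dna_coords + np.array([shift, 0.0, 0.0]))
        return float(d.min())

    lo, hi = 0.0, 300.0
    if min_dist(lo) > spec.contact_distance:
        lo = -50.0
        if min_dist(lo) > spec.contact_distance:
            raise ValueError("infeasible geometry: cannot reach requested contact distance")
    for _ in range(80):  # bisection on the monotone far side
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < spec.contact_distance:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    if abs(min_dist(shift) - spec.contact_distance) > 0.5:
        raise ValueError("infeasible geometry: contact distance not attainable to ±0.5 Å")

    for aname, res, seq, pos, chain in dna_local:
        elem = "P" if aname == "P" else aname[0]
        add(aname, res, chain, seq, pos + np.array([shift, 0.0, 0.0]), elem,
            MoleculeClass.DNA)

    return Structure(id=f"syn{spec.seed:04d}", atoms=atoms)


def generate_planted_task(
    seed: int,
    grid_shape: tuple[int, int, int] = (12, 12, 12),
    pattern_channel: int = 2,
    n_samples: int = 16,
    background_density: float = 0.04,
    motif_size: int = 2,
    halo: int = 1,
) -> list[tuple[VoxelGrid, BindingMask]]:
    """Planted-motif voxel dataset for training sanity checks.

    Each sample carries a ``motif_size``-cube of one-hot occupancy on
    ``pattern_channel`` at a random location plus sparse background
    occupancy on the other channels; the mask marks the motif dilated by
    ``halo`` voxels.  The mask is a deterministic local function of the
    input, so a small fully-convolutional network can drive BCE far below
    the ln 2 baseline.
    """
    if any(d < 8 for d in grid_shape):
        raise ValueError("each grid dimension must be at least 8")
    if not (0 <= pattern_channel < N_CHANNELS):
        raise ValueError(f"pattern_channel must be in 0..{N_CHANNELS - 1}")
    rng = np.random.default_rng(seed)
    spec = GridSpec(origin=(-0.5, -0.5, -0.5), shape=tuple(grid_shape), padding=0.0)
    samples = []
    other = [c for c in range(N_CHANNELS) if c != pattern_channel]
    for _ in range(n_samples):
        values = np.zeros(tuple(grid_shape) + (N_CHANNELS,), dtype=np.uint8)
        occupied = rng.random(grid_shape) < background_density
        channels = rng.choice(other, size=int(occupied.sum()))
        values[occupied, :] = 0
        values[tuple(np.argwhere(occupied).T) + (channels,)] = 1
        corner = np.array([rng.integers(halo, d - motif_size - halo) for d in grid_shape])
        mask = np.zeros(grid_shape, dtype=np.uint8)
        sl = tuple(slice(c, c + motif_size) for c in corner)
        values[sl] = 0
        values[sl + (pattern_channel,)] = 1
        msl = tuple(slice(c - halo, c + motif_size + halo) for c in corner)
        mask[msl] = 1
        samples.append(
            (VoxelGrid(spec=spec, values=values), BindingMask(spec=spec, values=mask))
        )
    return samples


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Emit the structure as a fixed-column PDB file (synthetic fixture)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"HEADER    SYNTHETIC COMPLEX                       {s.id.upper():>8}\n")
        for a in s.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3}"
            x, y, z = a.coords
            fh.write(
                f"ATOM  {a.serial:>5} {name} {a.residue_name:>3} {a.chain_id}"
                f"{a.residue_seq:>4}{a.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2}\n"
            )
        fh.write("END\n")
    return path
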