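"""Voxelization, ground-truth binding masks, cubic rotations and archives.

The complex is embedded in a 1-Å cubic grid covering the protein bounding
box plus padding.  Each protein atom occupies the voxel nearest its center
and one-hot encodes its atom type over 17 channels (16 surface types plus
one channel for non-surface protein atoms).  DNA atoms are never written to
the input grid — they define only the ground truth.

A grid voxel is a *binding* voxel when some protein atom P and DNA atom D
satisfy the triple rule: dist(voxel, P) <= cutoff, dist(voxel, D) <= cutoff
and dist(P, D) <= cutoff, all distances taken from the voxel center and the
default cutoff being 6 Å.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .atom_typing import ATOM_TYPE_CODES
from .structure import NON_SURFACE, MoleculeClass, Structure

__all__ = [
    "GridSpec",
    "VoxelGrid",
    "BindingMask",
    "voxelize",
    "label_binding_voxels",
    "enumerate_rotations",
    "rotate_grid",
    "save_archive",
    "load_archive",
    "protein_proximal_region",
    "N_CHANNELS",
    "CHANNEL_LEGEND",
]

#: 16 atom-type channels followed by the non-surface channel.
CHANNEL_LEGEND: tuple[str, ...] = ATOM_TYPE_CODES + (NON_SURFACE,)
N_CHANNELS = len(CHANNEL_LEGEND)  # 17

VOXEL_SIZE = 1.0  # Å, fixed by construction


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid anchored in structure coordinates.

    Voxel ``(i, j, k)`` covers the half-open cell
    ``origin + [i, i+1) x [j, j+1) x [k, k+1)`` and has its center at
    ``origin + (i, j, k) + 0.5``.
    """

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    padding: float = 3.0
    n_channels: int = N_CHANNELS

    @classmethod
    def from_structure(cls, s: Structure, padding: float = 3.0) -> "GridSpec":
        """Grid covering the protein bounding box with ``padding`` Å margins.

        The origin is placed so that an atom sitting exactly at the bounding
        box minimum lands at the center of the voxel ``padding`` cells in.
        """
        coords = s.coords_of(MoleculeClass.PROTEIN)
        if coords.shape[0] == 0:
            raise ValueError("cannot build a grid spec for a structure with no protein atoms")
        pad = int(round(padding))
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        origin = lo - pad - 0.5
        shape = tuple(int(np.floor(h - o)) + pad + 1 for h, o in zip(hi, origin))
        return cls(origin=tuple(origin), shape=shape, padding=float(pad))

    def indices_of(self, coords: np.ndarray) -> np.ndarray:
        """World coordinates -> integer voxel indices (floor convention)."""
        return np.floor((np.asarray(coords) - np.asarray(self.origin)) / VOXEL_SIZE).astype(int)

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel center coordinates."""
        ax = [np.asarray(self.origin)[d] + np.arange(self.shape[d]) + 0.5 for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class VoxelGrid:
    spec: GridSpec
    values: np.ndarray  # (x, y, z, channel) uint8, one-hot per voxel

    def __post_init__(self) -> None:
        expected = self.spec.shape + (self.spec.n_channels,)
        if self.values.shape != expected:
            raise ValueError(f"grid values shape {self.values.shape} != spec {expected}")


@dataclass
class BindingMask:
    spec: GridSpec
    values: np.ndarray  # (x, y, z) uint8
    cutoff: float = 6.0

    def __post_init__(self) -> None:
        if self.values.shape != self.spec.shape:
            raise ValueError(f"mask shape {self.values.shape} != spec {self.spec.shape}")


def voxelize(s: Structure, spec: GridSpec | None = None) -> VoxelGrid:
    """One-hot encode protein atoms into their nearest voxels.

    When two atoms fall into the same voxel, the atom whose center is
    nearest the voxel center wins; ties break on the lower serial.
    """
    if spec is None:
        spec = GridSpec.from_structure(s)
    values = np.zeros(spec.shape + (spec.n_channels,), dtype=np.uint8)
    channel_index = {code: i for i, code in enumerate(CHANNEL_LEGEND)}
    # winner-tracking per occupied voxel: (distance to center, serial)
    best: dict[tuple[int, int, int], tuple[float, int, int]] = {}
    origin = np.asarray(spec.origin)
    for a in s.atoms:
        if a.molecule_class is not MoleculeClass.PROTEIN:
            continue
        code = a.atom_type if a.atom_type in channel_index else NON_SURFACE
        idx = tuple(spec.indices_of(a.coords))
        if any(i < 0 or i >= n for i, n in zip(idx, spec.shape)):
            raise ValueError(
                f"atom {a.serial} at {a.coords} falls outside the grid {spec.shape}"
            )
        center = origin + np.array(idx) + 0.5
        d = float(np.sum((a.coords - center) ** 2))
        prev = best.get(idx)
        if prev is None or (d, a.serial) < (prev[0], prev[1]):
            best[idx] = (d, a.serial, channel_index[code])
    for idx, (_, _, ch) in best.items():
        values[idx] = 0
        values[idx + (ch,)] = 1
    return VoxelGrid(spec=spec, values=values)


def label_binding_voxels(s: Structure, spec: GridSpec, cutoff: float = 6.0) -> BindingMask:
    """Ground-truth mask from the triple proximity rule.

    Implemented pairwise: for every protein--DNA contact pair within the
    cutoff, voxels whose centers lie in the intersection of the two cutoff
    balls are marked.  Equivalent to the exhaustive per-voxel scan.
    """
    prot = s.coords_of(MoleculeClass.PROTEIN)
    dna = s.coords_of(MoleculeClass.DNA)
    if dna.shape[0] == 0:
        raise ValueError("structure has no DNA atoms; cannot label binding voxels")
    values = np.zeros(spec.shape, dtype=np.uint8)
    pairs = cKDTree(prot).query_ball_tree(cKDTree(dna), r=cutoff)
    origin = np.asarray(spec.origin)
    shape = np.asarray(spec.shape)
    for ip, dlist in enumerate(pairs):
        if not dlist:
            continue
        p = prot[ip]
        for idn in dlist:
            d = dna[idn]
            # bounding box of the lens formed by the two balls, in indices
            lo = np.maximum(np.floor(np.maximum(p, d) - cutoff - origin - 0.5), 0).astype(int)
            hi = np.minimum(np.ceil(np.minimum(p, d) + cutoff - origin - 0.5) + 1, shape).astype(int)
            if np.any(lo >= hi):
                continue
            ax = [origin[k] + np.arange(lo[k], hi[k]) + 0.5 for k in range(3)]
            gx, gy, gz = np.meshgrid(*ax, indexing="ij")
            centers = np.stack([gx, gy, gz], axis=-1)
            ok = (np.sum((centers - p) ** 2, axis=-1) <= cutoff**2) & (
                np.sum((centers - d) ** 2, axis=-1) <= cutoff**2
            )
            values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ok.astype(np.uint8)
    return BindingMask(spec=spec, values=values, cutoff=cutoff)


def enumerate_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cube as integer matrices.

    Signed permutation matrices with determinant +1, enumerated in a fixed
    (lexicographic) order with the identity first.
    """
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for i, (p, sgn) in enumerate(zip(perm, signs)):
                m[i, p] = sgn
            if round(np.linalg.det(m)) == 1:
                mats.append(m)
    # stable order with the identity first
    mats.sort(key=lambda m: (not np.array_equal(m, np.eye(3, dtype=int)), m.tolist()))
    return mats


def _perm_signs(r: np.ndarray) -> tuple[list[int], list[int]]:
    r = np.asarray(r, dtype=int)
    rots = enumerate_rotations()
    if not any(np.array_equal(r, m) for m in rots):
        raise ValueError("matrix is not one of the 24 cubic rotations")
    perm, signs = [], []
    for i in range(3):
        j = int(np.flatnonzero(r[i])[0])
        perm.append(j)
        signs.append(int(r[i, j]))
    return perm, signs


def rotate_grid(g, r: np.ndarray):
    """Apply a cubic rotation to a :class:`VoxelGrid` or :class:`BindingMask`.

    Pure axis permutation + flips of the spatial dimensions; the channel
    dimension (if present) is untouched.  Composition satisfies
    ``rotate(rotate(a, r1), r2) == rotate(a, r2 @ r1)``.
    """
    perm, signs = _perm_signs(r)
    arr = g.values
    spatial_extra = arr.ndim - 3  # 0 for masks, 1 for grids
    axes = perm + [3] if spatial_extra else perm
    out = np.transpose(arr, axes)
    for i, sgn in enumerate(signs):
        if sgn < 0:
            out = np.flip(out, axis=i)
    out = np.ascontiguousarray(out)
    new_shape = tuple(g.spec.shape[p] for p in perm)
    new_spec = GridSpec(
        origin=g.spec.origin, shape=new_shape,
        padding=g.spec.padding, n_channels=g.spec.n_channels,
    )
    if isinstance(g, VoxelGrid):
        return VoxelGrid(spec=new_spec, values=out)
    return BindingMask(spec=new_spec, values=out, cutoff=g.cutoff)


def save_archive(
    g: VoxelGrid, m: BindingMask, pdb_id: str, rotation_id: int, out_dir: str | Path
) -> Path:
    """Persist an aligned grid/mask pair as ``<pdb_id>_r<rotation_id>.npz``.

    A JSON sidecar records the grid geometry and channel legend.
    """
    if not (0 <= rotation_id <= 23):
        raise ValueError(f"rotation_id must be in 0..23, got {rotation_id}")
    if g.values.shape[:3] != m.values.shape:
        raise ValueError("grid and mask are not aligned")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{pdb_id}_r{rotation_id:02d}.npz"
    np.savez_compressed(path, input=g.values.astype(np.uint8), mask=m.values.astype(np.uint8))
    sidecar = {
        "pdb_id": pdb_id,
        "rotation_id": rotation_id,
        "origin": list(g.spec.origin),
        "shape": list(g.spec.shape),
        "padding": g.spec.padding,
        "cutoff": m.cutoff,
        "channels": list(CHANNEL_LEGEND),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_archive(path: str | Path) -> tuple[VoxelGrid, BindingMask, dict]:
    """Inverse of :func:`save_archive`."""
    path = Path(path)
    with np.load(path) as npz:
        inp = npz["input"]
        mask = npz["mask"]
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = GridSpec(
        origin=tuple(meta["origin"]), shape=tuple(meta["shape"]),
        padding=meta["padding"], n_channels=inp.shape[3],
    )
    return (
        VoxelGrid(spec=spec, values=inp),
        BindingMask(spec=spec, values=mask, cutoff=meta["cutoff"]),
        meta,
    )


def protein_proximal_region(s: Structure, spec: GridSpec, radius: float = 6.0,
                            surface_only: bool = False) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` of a protein atom.

    With ``surface_only`` the reference set shrinks to surface atoms; this is
    the candidate support used by heat-map binarization, while the full-atom
    version is the default evaluation region for per-voxel statistics.
    """
    atoms = s.atoms_of(MoleculeClass.PROTEIN)
    if surface_only:
        atoms = [a for a in atoms if a.is_surface]
    if not atoms:
        return np.zeros(spec.shape, dtype=bool)
    coords = np.array([a.coords for a in atoms])
    centers = spec.voxel_centers().reshape(-1, 3)
    dist, _ = cKDTree(coords).query(centers, k=1)
    return (dist <= radius).reshape(spec.shape)
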