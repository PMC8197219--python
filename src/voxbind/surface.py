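"""Per-atom solvent-accessible surface area and the surface flag.

SASA is computed on the protein *in isolation*: DNA and other molecules are
excluded so that atoms buried under the bound DNA still count as surface —
the binding interface is exactly what the model must see.

The estimator is Shrake–Rupley: each atom's van der Waals sphere is
expanded by the probe radius and sampled with a deterministic golden-spiral
point set; the accessible fraction is the share of points not inside any
neighbouring expanded sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import MoleculeClass, Structure
from .atom_typing import TypingError

__all__ = ["SasaParams", "compute_sasa", "flag_surface", "sphere_points"]

#: Built-in van der Waals radii (Å).  Metals get a single generic radius.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "SE": 1.9,
    "ZN": 2.0, "MG": 2.0, "MN": 2.0, "FE": 2.0, "NA": 2.0,
    "K": 2.0, "CA": 2.0, "NI": 2.0, "CU": 2.0, "CO": 2.0,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4  # water probe, Å
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    surface_threshold: float = 0.0  # Å²; strict > comparison

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be at least 92")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all van der Waals radii must be positive")

    def radius_of(self, element: str) -> float:
        try:
            return self.radii_table[element.upper()]
        except KeyError:
            raise TypingError(f"no van der Waals radius for element {element!r}")


def sphere_points(n: int) -> np.ndarray:
    """(n, 3) unit vectors on a golden-spiral (Fibonacci) lattice."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_sasa(s: Structure, params: SasaParams | None = None) -> Structure:
    """Fill ``atom.sasa`` for every PROTEIN atom (others keep NaN)."""
    if params is None:
        params = SasaParams()
    prot = s.atoms_of(MoleculeClass.PROTEIN)
    if not prot:
        return s
    coords = np.array([a.coords for a in prot])
    radii = np.array([params.radius_of(a.element) for a in prot]) + params.probe_radius
    unit = sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    for i, atom in enumerate(prot):
        ri = radii[i]
        pts = coords[i] + ri * unit
        # Any neighbour whose expanded sphere can reach this atom's surface.
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        atom.sasa = float(frac * 4.0 * np.pi * ri * ri)
    return s


def flag_surface(s: Structure, params: SasaParams | None = None) -> Structure:
    """Set ``is_surface`` from the SASA threshold (protein atoms only)."""
    if params is None:
        params = SasaParams()
    for a in s.atoms:
        if a.molecule_class is MoleculeClass.PROTEIN:
            a.is_surface = bool(np.isfinite(a.sasa) and a.sasa > params.surface_threshold)
        else:
            a.is_surface = False
    return s
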