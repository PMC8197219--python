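"""End-to-end orchestration helpers shared by the CLI and scripts."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .atom_typing import AtomTypeTable, assign_atom_types
from .config import PipelineConfig
from .featurize import (
    BindingMask,
    GridSpec,
    VoxelGrid,
    label_binding_voxels,
    voxelize,
)
from .structure import MoleculeClass, Structure, classify_molecules, parse_pdb, screen_complex
from .surface import compute_sasa, flag_surface

__all__ = ["prepare_structure", "featurize_complex"]


def prepare_structure(
    path: str | Path,
    config: PipelineConfig | None = None,
    table: AtomTypeTable | None = None,
    require_dna: bool = True,
) -> Structure:
    """Parse, classify, screen, compute SASA and assign atom types.

    Raises ``ValueError`` when the complex fails the usability screen.
    """
    config = config or PipelineConfig()
    s = classify_molecules(parse_pdb(path, keep_hetero=config.keep_hetero))
    if require_dna and not screen_complex(s, table):
        raise ValueError(f"{s.id}: complex fails screening (missing DNA or untypeable atoms)")
    compute_sasa(s, config.sasa)
    flag_surface(s, config.sasa)
    assign_atom_types(s, table)
    return s


def featurize_complex(
    s: Structure, config: PipelineConfig | None = None
) -> tuple[VoxelGrid, BindingMask]:
    """Voxel grid plus ground-truth binding mask for a prepared complex."""
    config = config or PipelineConfig()
    spec = GridSpec.from_structure(s, padding=config.grid_padding)
    grid = voxelize(s, spec)
    mask = label_binding_voxels(s, spec, cutoff=config.binding_cutoff)
    return grid, mask
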