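"""Binarization of the continuous heat map by two rounds of k-means.

The heat map assigns every voxel a binding probability; a binary call is
made by clustering candidate voxels as points (x, y, z, score).  All four
dimensions are standardized to zero mean / unit variance, the score axis is
then inflated 5x so clusters separate on score first and location second.
Round one forms ceil(n_atoms / 1000) clusters; round two clusters the
per-cluster mean scores into two groups, and every voxel in the
higher-mean group is called binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .featurize import GridSpec, VoxelGrid, protein_proximal_region
from .structure import MoleculeClass, Structure

__all__ = ["ClusterConfig", "binarize", "cluster_summary"]


@dataclass
class ClusterConfig:
    atoms_per_cluster: int = 1000
    score_weight: float = 5.0
    k_second_round: int = 2
    candidate_radius: float = 6.0  # Å around surface atoms
    n_init: int = 10
    seed: int = 0

    def first_round_k(self, n_atoms: int) -> int:
        if n_atoms <= 0:
            raise ValueError("need at least one protein atom")
        return int(np.ceil(n_atoms / self.atoms_per_cluster))


def binarize(
    heat: np.ndarray,
    s: Structure,
    grid: VoxelGrid,
    config: ClusterConfig | None = None,
    return_labels: bool = False,
):
    """Binary binding-region mask from a heat map.

    Candidate points are the voxels within ``candidate_radius`` of a surface
    protein atom — the support on which the prediction is meaningful.
    Degenerate inputs (no candidates, or zero score variance) yield an
    all-zero mask: no binding region is called.
    """
    config = config or ClusterConfig()
    heat = np.asarray(getattr(heat, "values", heat), dtype=float)
    if heat.shape != grid.spec.shape:
        raise ValueError(f"heat map {heat.shape} does not align with grid {grid.spec.shape}")
    out = np.zeros(grid.spec.shape, dtype=np.uint8)
    support = protein_proximal_region(s, grid.spec, config.candidate_radius, surface_only=True)
    pts = np.argwhere(support)
    if pts.shape[0] == 0:
        warnings.warn("no candidate voxels near the protein surface; empty prediction")
        return (out, None, None) if return_labels else out
    scores = heat[support]
    if np.ptp(scores) == 0.0:
        # uniform heat map carries no signal to cluster on
        return (out, None, None) if return_labels else out

    n_atoms = len(s.atoms_of(MoleculeClass.PROTEIN))
    k1 = config.first_round_k(n_atoms)
    feats = np.column_stack([pts.astype(float), scores])
    std = feats.std(axis=0)
    std[std == 0.0] = 1.0
    feats = (feats - feats.mean(axis=0)) / std
    feats[:, 3] *= config.score_weight

    k1 = min(k1, pts.shape[0])
    km1 = KMeans(n_clusters=k1, n_init=config.n_init, random_state=config.seed)
    labels = km1.fit_predict(feats)
    means = np.array([scores[labels == c].mean() for c in range(k1)])

    if k1 == 1:
        # a single cluster cannot be split in round two; call it binding
        # only if it actually looks like binding on average
        binding_clusters = np.array([0]) if means[0] > 0.5 else np.array([], dtype=int)
    else:
        k2 = min(config.k_second_round, k1)
        km2 = KMeans(n_clusters=k2, n_init=config.n_init, random_state=config.seed)
        lab2 = km2.fit_predict(means.reshape(-1, 1))
        group_means = [means[lab2 == g].mean() for g in range(k2)]
        top = int(np.argmax(group_means))
        binding_clusters = np.flatnonzero(lab2 == top)

    member = np.isin(labels, binding_clusters)
    out[tuple(pts[member].T)] = 1
    if return_labels:
        return out, labels, (pts, scores, binding_clusters)
    return out


def cluster_summary(labels: np.ndarray, scores: np.ndarray,
                    binding_clusters=None) -> pd.DataFrame:
    """Per-cluster table: id, size, mean score and the binding flag."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    ids = np.unique(labels)
    means = np.array([scores[labels == c].mean() for c in ids])
    if binding_clusters is None:
        # single cluster: binding iff its mean clears 0.5; otherwise argmax group
        if len(ids) == 1:
            binding_clusters = ids if means[0] > 0.5 else np.array([], dtype=int)
        else:
            binding_clusters = ids[[int(np.argmax(means))]]
    flag = np.isin(ids, binding_clusters)
    return pd.DataFrame(
        {
            "cluster": ids,
            "size": [int((labels == c).sum()) for c in ids],
            "mean_score": means,
            "binding": flag,
        }
    )
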