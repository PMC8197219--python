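"""Voxelization, the triple 6-Å mask rule, cubic rotations and archives."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import random_structure
from voxbind.featurize import (
    CHANNEL_LEGEND,
    GridSpec,
    N_CHANNELS,
    VoxelGrid,
    enumerate_rotations,
    label_binding_voxels,
    load_archive,
    protein_proximal_region,
    rotate_grid,
    save_archive,
    voxelize,
)
from voxbind.structure import Atom, MoleculeClass, Structure


def _atom(serial, coords, cls=MoleculeClass.PROTEIN, name="CA", res="ALA",
          atom_type=None):
    a = Atom(serial=serial, name=name, residue_name=res, chain_id="A",
             residue_seq=serial, coords=np.asarray(coords, float), element="C",
             molecule_class=cls)
    if atom_type:
        a.atom_type = atom_type
        a.is_surface = True
    return a


class TestGridSpec:
    def test_two_atoms_ten_angstroms_apart_span_17_voxels(self):
        s = Structure(id="t", atoms=[
            _atom(1, [0, 0, 0]), _atom(2, [10, 0, 0])])
        spec = GridSpec.from_structure(s, padding=3.0)
        assert spec.shape[0] == 17  # 10 + 2*3 + 1

    def test_empty_protein_rejected(self):
        s = Structure(id="t", atoms=[_atom(1, [0, 0, 0], cls=MoleculeClass.DNA)])
        with pytest.raises(ValueError):
            GridSpec.from_structure(s)

    def test_atoms_at_bbox_corners_land_at_voxel_centers(self):
        s = Structure(id="t", atoms=[_atom(1, [1.2, 3.4, -2.0])])
        spec = GridSpec.from_structure(s)
        idx = spec.indices_of(np.array([[1.2, 3.4, -2.0]]))[0]
        center = np.asarray(spec.origin) + idx + 0.5
        np.testing.assert_allclose(center, [1.2, 3.4, -2.0])


class TestVoxelize:
    def test_single_typed_atom_sets_one_hot_channel(self):
        s = Structure(id="t", atoms=[_atom(1, [0, 0, 0], atom_type="C3N")])
        g = voxelize(s)
        assert g.values.sum() == 1
        occ = np.argwhere(g.values)[0]
        assert CHANNEL_LEGEND[occ[3]] == "C3N"

    def test_channel_vectors_are_one_hot(self, featurized):
        grid, _ = featurized
        per_voxel = grid.values.sum(axis=3)
        assert per_voxel.max() <= 1

    def test_occupied_voxels_bounded_by_atom_count(self, prepared, featurized):
        grid, _ = featurized
        n_prot = len(prepared.atoms_of(MoleculeClass.PROTEIN))
        assert grid.values.sum() <= n_prot

    def test_collision_resolved_to_nearest_center_then_serial(self):
        # two atoms in one voxel: serial 2 is nearer to its center
        s = Structure(id="t", atoms=[
            _atom(1, [0.4, 0.0, 0.0], atom_type="C3N"),
            _atom(2, [0.05, 0.0, 0.0], atom_type="N3C"),
            _atom(3, [6.0, 6.0, 6.0], atom_type="C3N"),  # spans the grid
        ])
        g = voxelize(s)
        idx = g.spec.indices_of(np.array([[0.1, 0, 0]]))[0]
        ch = np.argwhere(g.values[tuple(idx)])[0][0]
        assert CHANNEL_LEGEND[ch] == "N3C"

    def test_dna_never_written_to_grid(self, prepared, featurized):
        grid, _ = featurized
        n_prot = len(prepared.atoms_of(MoleculeClass.PROTEIN))
        # all occupied channels are protein channels; occupancy from protein only
        assert grid.values.sum() <= n_prot
        assert grid.values.shape[3] == N_CHANNELS


class TestBindingMask:
    def _two_atom_structure(self, p, d):
        return Structure(id="t", atoms=[
            _atom(1, p), _atom(2, d, cls=MoleculeClass.DNA, name="P", res="DA")])

    def test_voxel_between_close_pair_is_binding(self):
        s = self._two_atom_structure([0, 0, 0], [4, 0, 0])
        spec = GridSpec.from_structure(s)
        m = label_binding_voxels(s, spec)
        idx = spec.indices_of(np.array([[2.0, 0, 0]]))[0]
        # center (2,0,0): within 6 of both atoms which are 4 apart
        assert m.values[tuple(idx)] == 1

    def test_distant_pair_fails_third_condition(self):
        s = self._two_atom_structure([0, 0, 0], [11, 0, 0])
        spec = GridSpec.from_structure(s)
        m = label_binding_voxels(s, spec)
        assert m.values.sum() == 0  # dist(P,D)=11 > 6 kills every voxel

    def test_no_dna_is_an_error(self):
        s = Structure(id="t", atoms=[_atom(1, [0, 0, 0])])
        with pytest.raises(ValueError):
            label_binding_voxels(s, GridSpec.from_structure(s))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_triple_rule_oracle(self, seed):
        s = random_structure(seed, n_protein=30, n_dna=20)
        spec = GridSpec.from_structure(s)
        got = label_binding_voxels(s, spec, cutoff=6.0).values
        prot = s.coords_of(MoleculeClass.PROTEIN)
        dna = s.coords_of(MoleculeClass.DNA)
        centers = spec.voxel_centers().reshape(-1, 3)
        pd = cdist(prot, dna) <= 6.0
        expected = np.zeros(len(centers), dtype=np.uint8)
        for v, c in enumerate(centers):
            vp = np.linalg.norm(prot - c, axis=1) <= 6.0
            vd = np.linalg.norm(dna - c, axis=1) <= 6.0
            expected[v] = np.any(vp[:, None] & vd[None, :] & pd)
        np.testing.assert_array_equal(got.ravel(), expected)

    def test_mask_monotone_in_cutoff(self):
        s = random_structure(99, n_protein=25, n_dna=15)
        spec = GridSpec.from_structure(s)
        m5 = label_binding_voxels(s, spec, cutoff=5.0).values
        m6 = label_binding_voxels(s, spec, cutoff=6.0).values
        assert np.all(m6[m5 == 1] == 1)


class TestRotations:
    def test_exactly_24_distinct_proper_rotations(self):
        rots = enumerate_rotations()
        assert len(rots) == 24
        assert len({tuple(r.ravel()) for r in rots}) == 24
        for r in rots:
            assert round(np.linalg.det(r)) == 1

    def test_identity_member_and_group_closure(self):
        rots = enumerate_rotations()
        keys = {tuple(r.ravel()) for r in rots}
        assert tuple(np.eye(3, dtype=int).ravel()) in keys
        for a in rots:
            for b in rots:
                assert tuple((a @ b).ravel()) in keys

    def test_identity_rotation_is_a_noop(self, featurized):
        grid, _ = featurized
        out = rotate_grid(grid, np.eye(3, dtype=int))
        np.testing.assert_array_equal(out.values, grid.values)

    def test_inverse_recovers_original(self, featurized):
        grid, mask = featurized
        for r in enumerate_rotations()[:8]:
            back = rotate_grid(rotate_grid(grid, r), r.T)
            np.testing.assert_array_equal(back.values, grid.values)
            mback = rotate_grid(rotate_grid(mask, r), r.T)
            np.testing.assert_array_equal(mback.values, mask.values)

    def test_composition_matches_matrix_product(self, featurized):
        grid, _ = featurized
        rots = enumerate_rotations()
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rots[rng.integers(24)], rots[rng.integers(24)]
            lhs = rotate_grid(rotate_grid(grid, a), b)
            rhs = rotate_grid(grid, b @ a)
            np.testing.assert_array_equal(lhs.values, rhs.values)

    def test_per_channel_counts_invariant(self, featurized):
        grid, _ = featurized
        base = grid.values.sum(axis=(0, 1, 2))
        for r in enumerate_rotations():
            rot = rotate_grid(grid, r)
            np.testing.assert_array_equal(rot.values.sum(axis=(0, 1, 2)), base)

    def test_non_member_matrix_rejected(self, featurized):
        grid, _ = featurized
        with pytest.raises(ValueError):
            rotate_grid(grid, -np.eye(3, dtype=int))  # det -1 reflection

    def test_rotating_coordinates_equals_rotating_grid(self, prepared):
        """Voxelize-then-rotate agrees with rotate-then-voxelize."""
        from copy import deepcopy

        spec = GridSpec.from_structure(prepared)
        grid = voxelize(prepared, spec)
        r = enumerate_rotations()[7]
        # rotate all coordinates about the grid origin-anchored box center
        lo = np.asarray(spec.origin)
        center = lo + np.asarray(spec.shape) / 2.0
        s2 = deepcopy(prepared)
        for a in s2.atoms:
            a.coords = r @ (a.coords - center) + center
        new_shape = tuple(spec.shape[int(np.flatnonzero(r[i])[0])] for i in range(3))
        new_lo = center - np.asarray(new_shape) / 2.0
        spec2 = GridSpec(origin=tuple(new_lo), shape=new_shape, padding=spec.padding)
        direct = voxelize(s2, spec2)
        via_grid = rotate_grid(grid, r)
        np.testing.assert_array_equal(direct.values, via_grid.values)


class TestArchives:
    def test_save_load_bit_identical(self, tmp_path, featurized):
        grid, mask = featurized
        p = save_archive(grid, mask, "syn1", 0, tmp_path)
        g2, m2, meta = load_archive(p)
        np.testing.assert_array_equal(g2.values, grid.values)
        np.testing.assert_array_equal(m2.values, mask.values)
        assert meta["channels"] == list(CHANNEL_LEGEND)

    def test_24_rotations_make_24_distinct_files(self, tmp_path, featurized):
        grid, mask = featurized
        paths = set()
        for rid, r in enumerate(enumerate_rotations()):
            paths.add(save_archive(rotate_grid(grid, r), rotate_grid(mask, r),
                                   "syn1", rid, tmp_path))
        assert len(paths) == 24

    def test_rotation_id_bounds(self, tmp_path, featurized):
        grid, mask = featurized
        with pytest.raises(ValueError):
            save_archive(grid, mask, "syn1", 24, tmp_path)


class TestEvalRegion:
    def test_region_contains_all_occupied_voxels(self, prepared, featurized):
        grid, _ = featurized
        region = protein_proximal_region(prepared, grid.spec, 6.0)
        occupied = grid.values.sum(axis=3) > 0
        assert np.all(region[occupied])

    def test_surface_only_region_is_a_subset(self, prepared, featurized):
        grid, _ = featurized
        full = protein_proximal_region(prepared, grid.spec, 6.0)
        surf = protein_proximal_region(prepared, grid.spec, 6.0, surface_only=True)
        assert np.all(full[surf])
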