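"""Max-tree structure and hyperconnected openings against oracles."""

import numpy as np
import pytest

import hyperstrip as hs
from hyperstrip.maxtree import _neighbor_offsets
from conftest import random_volume
from oracles import flood_fill_maxima


def leaf_voxel_sets(tree):
    return {
        frozenset(map(tuple, np.argwhere(tree.pixel_node == leaf)))
        for leaf in tree.leaves
    }


class TestBuildMaxtree:
    def test_constant_volume_single_node(self):
        f = hs.make_fixture("flat")
        tree = hs.build_maxtree(f)
        assert tree.n_nodes == 1
        assert tree.node_level[0] == 37
        assert list(tree.leaves) == [0]
        assert tree.node_area[0] == f.size

    def test_two_peak_structure(self):
        img = hs.make_fixture("two_peak_2d")
        tree = hs.build_maxtree(img)
        assert tree.n_nodes == 3
        assert sorted(tree.node_level[tree.leaves]) == [10, 20]
        assert tree.node_level[0] == 0  # root is the background
        assert len(tree.leaves) == 2

    def test_parent_levels_strictly_increase(self, rng):
        f = random_volume(rng, (8, 8, 4), high=12)
        tree = hs.build_maxtree(f)
        nonroot = np.arange(tree.n_nodes) != tree.parent
        assert np.all(tree.node_level[nonroot]
                      > tree.node_level[tree.parent[nonroot]])
        assert tree.node_area[0] == f.size

    @pytest.mark.parametrize("seed", range(5))
    def test_random_volume_identities(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 10, size=(12, 12, 4)).astype(np.uint8)
        tree = hs.build_maxtree(f)
        # reconstruction identity
        assert np.array_equal(tree.reconstruct(), f)
        # leaves are exactly the flood-fill regional maxima
        offs = [tuple(o) for o in _neighbor_offsets(None, None)]
        assert leaf_voxel_sets(tree) == flood_fill_maxima(f, offs)

    def test_cross_check_against_skimage(self, rng):
        # independent implementation: per-voxel (level, peak-component area)
        from skimage.morphology import max_tree as sk_max_tree

        f = random_volume(rng, (9, 9, 5), high=15)
        tree = hs.build_maxtree(f, connectivity=26)
        parent_px, traverser = sk_max_tree(f, connectivity=3)
        flat = f.ravel().astype(np.int64)
        area_px = np.ones(flat.size, np.int64)
        canonical = (flat[parent_px.ravel()] != flat) \
            | (np.arange(flat.size) == parent_px.ravel())
        for p in traverser[::-1]:
            q = parent_px.ravel()[p]
            if p != q:
                area_px[q] += area_px[p]
        # area of each voxel's node = area at its canonical voxel
        canon = np.where(canonical, np.arange(flat.size), parent_px.ravel())
        sk_levels = flat[canon]
        sk_areas = area_px[canon]
        my_levels = tree.node_level[tree.pixel_node].ravel()
        my_areas = tree.node_area[tree.pixel_node].ravel()
        assert np.array_equal(my_levels, sk_levels)
        assert np.array_equal(my_areas, sk_areas)


class TestHyperconnectedFunctions:
    def test_single_maximum_image_reconstructs_itself(self):
        f = hs.make_fixture("cone_3d")
        tree = hs.build_maxtree(f)
        assert len(tree.leaves) == 1
        g = hs.reconstruct_from_maximum(tree, f, int(tree.leaves[0]))
        assert np.array_equal(g, f)

    def test_two_peak_reconstruction(self):
        img = hs.make_fixture("two_peak_2d")
        tree = hs.build_maxtree(img)
        leaf_a = tree.leaves[tree.node_level[tree.leaves] == 20][0]
        g = hs.reconstruct_from_maximum(tree, img, int(leaf_a))
        expect = np.where(img == 20, 20, 0).astype(np.uint8)
        assert np.array_equal(g, expect)

    def test_non_leaf_id_rejected(self):
        img = hs.make_fixture("two_peak_2d")
        tree = hs.build_maxtree(img)
        with pytest.raises(ValueError):
            hs.reconstruct_from_maximum(tree, img, 0)  # root

    @pytest.mark.parametrize("seed", range(3))
    def test_gmi_matches_geodesic_reconstruction(self, seed, se11):
        rng = np.random.default_rng(seed + 10)
        f = rng.integers(0, 8, size=(10, 10, 4)).astype(np.uint8)
        tree = hs.build_maxtree(f)
        sup = np.zeros_like(f)
        for leaf in tree.leaves:
            g = hs.reconstruct_from_maximum(tree, f, int(leaf))
            marker = np.where(tree.pixel_node == leaf, f, 0).astype(np.uint8)
            ref = hs.reconstruct_by_dilation(marker, f, connectivity=None,
                                             se=se11)
            assert np.array_equal(g, ref)
            # class-W property: exactly one regional maximum
            offs = [tuple(o) for o in _neighbor_offsets(None, None)]
            assert len(flood_fill_maxima(g, offs)) == 1
            sup = np.maximum(sup, g)
        # the family W(f) covers f
        assert np.array_equal(sup, f)

    def test_volumes_match_summed_reconstructions(self, rng):
        f = random_volume(rng, (10, 10, 4), high=9)
        tree = hs.build_maxtree(f)
        records = hs.maxima_volumes(tree, f)
        assert len(records) == len(tree.leaves)
        total = f.size
        for rec in records:
            g = hs.reconstruct_from_maximum(tree, f, rec.leaf_id)
            assert rec.volume == int(g.sum(dtype=np.int64))
            assert rec.volume >= rec.level * rec.area
            assert rec.volume <= rec.level * total

    def test_two_peak_volumes(self):
        img = hs.make_fixture("two_peak_2d")
        tree = hs.build_maxtree(img)
        vols = {r.level: r.volume for r in hs.maxima_volumes(tree, img)}
        assert vols == {20: 80, 10: 40}


class TestHyperconnectedOpening:
    def test_mu_zero_is_identity(self, rng):
        f = random_volume(rng, (9, 9, 4))
        assert np.array_equal(hs.hyperconnected_opening(f, 0), f)

    def test_unreachable_criterion_gives_zero(self):
        img = hs.make_fixture("two_peak_2d")
        out = hs.hyperconnected_opening(img, 10_000)
        assert not out.any()

    def test_negative_mu_v_rejected(self):
        with pytest.raises(ValueError):
            hs.hyperconnected_opening(hs.make_fixture("flat"), -1)

    def test_two_peak_threshold_keeps_larger_volume(self):
        img = hs.make_fixture("two_peak_2d")
        out = hs.hyperconnected_opening(img, 50)  # Vol(A)=80, Vol(B)=40
        assert np.array_equal(out, np.where(img == 20, 20, 0))

    def test_anti_monotone_in_criterion(self, rng):
        f = random_volume(rng, (9, 9, 4), high=30)
        prev = hs.hyperconnected_opening(f, 0)
        for mu in (50, 200, 800, 3000):
            cur = hs.hyperconnected_opening(f, mu)
            assert np.all(cur <= prev)
            prev = cur

    def test_increasing_in_f(self, rng):
        f = random_volume(rng, (8, 8, 4), high=100)
        g = np.minimum(255, f.astype(np.int16)
                       + rng.integers(0, 40, f.shape)).astype(np.uint8)
        assert np.all(hs.hyperconnected_opening(f, 300)
                      <= hs.hyperconnected_opening(g, 300))


class TestExtremeHyperconnected:
    def test_single_maximum_returns_f(self):
        f = hs.make_fixture("cone_3d")
        assert np.array_equal(hs.extreme_hyperconnected(f), f)

    def test_two_peak_selects_larger(self):
        img = hs.make_fixture("two_peak_2d")
        out = hs.extreme_hyperconnected(img)
        assert np.array_equal(out, np.where(img == 20, 20, 0))

    def test_tied_volumes_keep_all_argmax(self):
        img = np.zeros((10, 10), np.uint8)
        img[2:4, 2:4] = 20
        img[6:8, 6:8] = 20  # mirror peak, equal volume
        out = hs.extreme_hyperconnected(img)
        assert np.array_equal(out, img)  # supremum of both reconstructions
        assert np.array_equal(out, out[::-1, ::-1])


class TestViscousOpening:
    def test_lam_zero_single_max_degenerates(self):
        f = hs.make_fixture("cone_3d")
        out = hs.viscous_hyperconnected_opening(f, 0, "extreme")
        assert np.array_equal(out, f)

    def test_bounded_by_morphological_opening(self, rng):
        f = random_volume(rng, (12, 12, 6))
        out = hs.viscous_hyperconnected_opening(f, 1, "extreme")
        assert np.all(out <= hs.open_(f, lam=1))

    def test_matches_literal_composition(self, rng):
        f = random_volume(rng, (12, 12, 6), high=20)
        got = hs.viscous_hyperconnected_opening(f, 1, "extreme")
        ero = hs.erode(f, lam=1)
        tree = hs.build_maxtree(ero)
        records = hs.maxima_volumes(tree, ero)
        best = max(r.volume for r in records)
        sel = np.zeros_like(ero)
        for r in records:
            if r.volume == best:
                sel = np.maximum(sel,
                                 hs.reconstruct_from_maximum(tree, ero,
                                                             r.leaf_id))
        assert np.array_equal(got, hs.dilate(sel, lam=1))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            hs.viscous_hyperconnected_opening(hs.make_fixture("flat"), 1,
                                              "nope")
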