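"""Morphological refinement operators: case removal, erosion/dilation,
hole-filling, 2D/3D feature filters, component labeling."""

import numpy as np
import pytest

from oracles import flood_fill_components
from specimenseg.grid import LabelMask
from specimenseg.morphology import (
    CaseGeometry,
    StructuringElement,
    dilate,
    erode,
    fill_holes,
    filter_small_2d,
    filter_small_3d,
    label_components,
    remove_case,
)


def _mask(arr, spacing=1.0, origin=None):
    arr = np.asarray(arr)
    if origin is None:
        origin = tuple(-(n - 1) / 2 for n in arr.shape)  # centered grid
    return LabelMask(arr.astype(np.int32), spacing, origin)


class TestRemoveCase:
    def test_interior_mask_unchanged(self):
        arr = np.zeros((21, 21, 5), dtype=int)
        arr[10, 10, :] = 1  # on the axis
        mask = _mask(arr)
        out = remove_case(mask, CaseGeometry(axis=2, center=(0, 0), radius=8, margin=2))
        assert np.array_equal(out.labels, mask.labels)

    def test_survivors_match_brute_force_radial_scan(self):
        mask = _mask(np.ones((21, 21, 5), dtype=int))
        geom = CaseGeometry(axis=2, center=(0.0, 0.0), radius=8.0, margin=2.5)
        out = remove_case(mask, geom)
        survivors = 0
        for i in range(21):
            for j in range(21):
                x, y = i - 10.0, j - 10.0
                if np.hypot(x, y) < geom.radius - geom.margin:
                    survivors += 5
        assert out.foreground_count() == survivors

    def test_phantom_case_shell_fully_removed(self, default_phantom):
        ct, _, _, meta = default_phantom
        # the shell is the only structure at radial distance >= lumen radius
        shell_geom = CaseGeometry(
            axis=2, center=(0, 0), radius=meta["case"]["radius"], margin=meta["case"]["wall"]
        )
        shell = ct.values >= 150.0  # wall voxels sit near +200, far above node
        mask = LabelMask(shell.astype(np.int32), ct.spacing, ct.origin)
        assert remove_case(mask, shell_geom).foreground_count() == 0

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="radius > margin"):
            CaseGeometry(axis=2, center=(0, 0), radius=1.0, margin=2.0)


class TestErodeDilate:
    def test_erode_empty_is_empty(self):
        assert erode(np.zeros((5, 5, 5), bool)).sum() == 0

    def test_erode_cube_ball1_leaves_center(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[1:4, 1:4, 1:4] = True
        out = erode(arr, StructuringElement("ball", 1))
        assert out.sum() == 1 and out[2, 2, 2]

    def test_erosion_detaches_bridged_blocks(self):
        arr = np.zeros((15, 7, 7), bool)
        arr[1:6, 1:6, 1:6] = True
        arr[8:13, 1:6, 1:6] = True
        arr[6:8, 3, 3] = True  # 1-voxel bridge
        assert label_components(arr, 26).max() == 1
        eroded = erode(arr, StructuringElement("ball", 1))
        assert label_components(eroded, 26).max() == 2

    def test_dilate_empty_is_empty(self):
        assert dilate(np.zeros((4, 4, 4), bool)).sum() == 0

    def test_dilate_voxel_cube1_gives_27(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 2, 2] = True
        assert dilate(arr, StructuringElement("cube", 1)).sum() == 27

    def test_dilation_rejoins_fragments(self):
        arr = np.zeros((9, 3, 3), bool)
        arr[1, 1, 1] = True
        arr[4, 1, 1] = True  # 2 empty voxels between fragments
        assert label_components(arr, 26).max() == 2
        joined = dilate(arr, StructuringElement("ball", 1))
        assert label_components(joined, 26).max() == 1

    def test_anti_extensive_and_extensive(self, rng):
        arr = rng.random((12, 12, 12)) < 0.4
        er, di = erode(arr), dilate(arr)
        assert not np.any(er & ~arr)  # erosion result subset of input
        assert not np.any(arr & ~di)  # input subset of dilation result

    @pytest.mark.parametrize("elem", [StructuringElement("ball", 1), StructuringElement("cube", 1), StructuringElement("ball", 2)])
    def test_erosion_dilation_duality(self, rng, elem):
        """erode(m) == complement(dilate(complement(m))) with background padding."""
        r = elem.radius
        arr = np.pad(rng.random((10, 10, 10)) < 0.5, r)  # declared-background border
        inner = tuple([slice(r, -r)] * 3)
        lhs = erode(arr, elem)[inner]
        rhs = ~dilate(~arr, elem)
        assert np.array_equal(lhs, rhs[inner])


class TestFillHoles:
    def test_solid_block_unchanged(self):
        arr = np.zeros((7, 7, 7), bool)
        arr[2:5, 2:5, 2:5] = True
        assert np.array_equal(fill_holes(arr), arr)

    def test_hollow_shell_becomes_solid(self):
        arr = np.zeros((9, 9, 9), bool)
        arr[2:7, 2:7, 2:7] = True
        arr[3:6, 3:6, 3:6] = False
        assert fill_holes(arr).sum() == 125

    def test_filling_is_extensive(self, rng):
        arr = rng.random((10, 10, 10)) < 0.5
        assert not np.any(arr & ~fill_holes(arr))

    def test_hilum_cavity_included_after_filling(self):
        """A low-density hilum excluded by clustering is recovered by filling."""
        from specimenseg.clustering import ClusterModel, assign_clusters, extract_node_mask
        from specimenseg.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(shape=(96, 96, 96), n_nodes=1, hilum_enabled=True, seed=3, ct_noise_sd=5.0)
        ct, _, truth, _ = generate_phantom(spec)
        model = ClusterModel(np.array([spec.air, spec.fat, spec.node]), 0.0)
        node_mask = extract_node_mask(assign_clusters(ct, model), model)
        hilum = truth.as_bool() & ~node_mask.as_bool()  # truth includes the hilum
        assert hilum.sum() > 0  # clustering really excluded a cavity
        filled = fill_holes(node_mask.as_bool())
        assert np.all(filled[hilum])


class TestSizeFilters:
    def test_min_pixels_one_is_identity(self, rng):
        arr = rng.random((6, 6, 6)) < 0.5
        assert np.array_equal(filter_small_2d(arr, 1), arr)

    def test_2d_filter_keeps_only_large_components(self):
        sl = np.zeros((20, 20), bool)
        sl[1:11, 1:6] = True  # 50 pixels
        sl[15:18, 15] = True  # 3 pixels
        arr = sl[:, :, None]
        out = filter_small_2d(arr, 10, slice_axis=2)
        assert out.sum() == 50

    def test_2d_postcondition_no_small_survivors(self, rng):
        from scipy import ndimage

        arr = rng.random((15, 15, 4)) < 0.35
        out = filter_small_2d(arr, 5, slice_axis=2)
        for k in range(4):
            lab, n = ndimage.label(out[:, :, k], structure=np.ones((3, 3)))
            sizes = np.bincount(lab.ravel())[1:]
            assert np.all(sizes[sizes > 0] >= 5)

    def test_3d_filter_keeps_only_large_components(self):
        arr = np.zeros((20, 20, 20), bool)
        arr[1:11, 1:11, 1:6] = True  # 500 voxels
        arr[15, 15, 10:15] = True  # 5 voxels
        out = filter_small_3d(arr, 100)
        assert out.sum() == 500

    def test_filters_idempotent(self, rng):
        arr = rng.random((12, 12, 12)) < 0.4
        once2d = filter_small_2d(arr, 4)
        assert np.array_equal(filter_small_2d(once2d, 4), once2d)
        once3d = filter_small_3d(arr, 6)
        assert np.array_equal(filter_small_3d(once3d, 6), once3d)

    def test_empty_input_empty_output(self):
        empty = np.zeros((4, 4, 4), bool)
        assert filter_small_3d(empty, 2).sum() == 0


class TestLabelComponents:
    def test_single_block_single_label(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[1:4, 1:4, 1:4] = True
        out = label_components(arr)
        assert set(np.unique(out)) == {0, 1}

    def test_diagonal_voxels_connectivity(self):
        arr = np.zeros((3, 3, 3), bool)
        arr[0, 0, 0] = arr[1, 1, 1] = True
        assert label_components(arr, 26).max() == 1
        assert label_components(arr, 6).max() == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill(self, rng, connectivity):
        arr = rng.random((20, 20, 20)) < 0.35
        assert np.array_equal(label_components(arr, connectivity), flood_fill_components(arr, connectivity))

    def test_labels_are_raster_ordered(self):
        arr = np.zeros((6, 6, 6), bool)
        arr[4, 4, 4] = True  # later in raster order
        arr[0, 0, 0] = True
        out = label_components(arr, 6)
        assert out[0, 0, 0] == 1 and out[4, 4, 4] == 2
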