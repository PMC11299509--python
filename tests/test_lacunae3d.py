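"""3D pipeline unit tests: ROI arithmetic, segmentation sweep, pore
extraction semantics, volume-band classification, sphericity and the
summary metrics, plus the partition/conservation/monotonicity
invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import spheroid_surface_area
from conftest import digitized_cube, digitized_ellipsoid, digitized_sphere
from osteolcn.core import RoiSlab, VoxelVolume
from osteolcn.lacunae3d import (
    analyze_volume,
    classify_pores,
    extract_pores,
    lacunar_metrics,
    pore_sphericity,
    remove_trabeculae,
    segment_cortex,
    select_roi_slab,
)
from osteolcn.synthetic import Volume3DSpec, generate_volume

SMALL_VOLUME = Volume3DSpec(
    shape_voxels=(60, 140, 140),
    outer_radius_um=42.0,
    wall_thickness_um=20.0,
    canal_count=1,
    canal_radius_um=4.5,
    noise_speck_count=5,
    seed=7,
)


class TestRoiSlab:
    @pytest.mark.parametrize(
        "voxel_um,extent_um,expected_slices",
        [(0.65, 500.0, 769), (1.0, 500.0, 500), (0.65, 100.0, 153)],
    )
    def test_extent_floor(self, voxel_um, extent_um, expected_slices):
        nz = 1200
        vol = VoxelVolume(np.zeros((nz, 4, 4), dtype=np.uint8), voxel_um)
        slab = select_roi_slab(vol, RoiSlab(0, offset_um=0.0, extent_um=extent_um))
        assert slab.shape[0] == expected_slices

    def test_offset_rounds_to_nearest_slice(self):
        vol = VoxelVolume(np.arange(1000)[:, None, None] * np.ones((1, 2, 2)), 0.65)
        slab = select_roi_slab(vol, RoiSlab(0, offset_um=100.0, extent_um=100.0))
        assert slab.data[0, 0, 0] == round(100.0 / 0.65)  # 154

    def test_out_of_bounds_names_missing_extent(self):
        vol = VoxelVolume(np.zeros((100, 4, 4)), 0.65)
        with pytest.raises(ValueError, match="um"):
            select_roi_slab(vol, RoiSlab(0, offset_um=0.0, extent_um=500.0))


class TestSegmentCortex:
    def test_all_background_raises(self):
        vol = VoxelVolume(np.zeros((10, 10, 10), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="foreground"):
            segment_cortex(vol, threshold=50)

    def test_sweep_keeps_only_largest_component(self):
        data = np.zeros((30, 30, 30), dtype=np.uint8)
        data[5:25, 5:25, 5:25] = 200  # cortex block
        data[1:3, 1:3, 1:3] = 200  # debris island
        mask = segment_cortex(VoxelVolume(data, 1.0), threshold=100)
        assert mask[10, 10, 10]
        assert not mask[1, 1, 1]
        assert mask.sum() == 20**3

    def test_noiseless_annulus_mask_matches_generator(self):
        spec = Volume3DSpec(
            shape_voxels=(40, 120, 120),
            outer_radius_um=35.0,
            wall_thickness_um=15.0,
            lacuna_density_per_mm3=0.0,
            canal_count=0,
            noise_speck_count=0,
            noise_sd=0.0,
            blur_sigma_um=0.0,
        )
        vol, truth = generate_volume(spec)
        mask = segment_cortex(vol, threshold="auto")
        assert mask.sum() == truth.attrs["wall_voxels"]


class TestRemoveTrabeculae:
    def test_empty_trabecular_mask_is_identity(self):
        mask = digitized_cube(10)
        out = remove_trabeculae(mask, np.zeros_like(mask))
        assert np.array_equal(out, mask)

    def test_explicit_mask_subtracts(self):
        mask = digitized_cube(10)
        trab = np.zeros_like(mask)
        trab[4:6] = True
        out = remove_trabeculae(mask, trab)
        assert not out[5, 8, 8]
        assert out.sum() == mask.sum() - (mask & trab).sum()

    def test_subtraction_emptying_mask_raises(self):
        mask = digitized_cube(6)
        with pytest.raises(ValueError, match="emptied"):
            remove_trabeculae(mask, np.ones_like(mask))

    def test_auto_mode_drops_free_rods(self):
        # annulus wall plus free-floating interior rods (no wall contact)
        n = 60
        y, x = np.mgrid[:n, :n]
        rr = np.hypot(y - n / 2, x - n / 2)
        wall2d = (rr <= 25) & (rr >= 18)
        mask = np.broadcast_to(wall2d, (20, n, n)).copy()
        mask[5:15, 28:32, 28:32] = True  # rod in the marrow space
        out = remove_trabeculae(mask, "auto")
        assert not out[10, 30, 30]
        assert out.sum() == 20 * wall2d.sum()


class TestExtractPores:
    def test_solid_cube_has_no_pores(self):
        labels, n = extract_pores(digitized_cube(12))
        assert n == 0 and labels.max() == 0

    def test_single_enclosed_cavity(self):
        mask = digitized_cube(12, pad=2)
        mask[7:9, 7:9, 7:9] = False  # one hole fully inside, 8 voxels
        labels, n = extract_pores(mask)
        assert n == 1
        assert (labels > 0).sum() == 8

    def test_tunnel_open_to_side_face_is_not_a_pore(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        mask[8, 8, 0:9] = False  # tunnel reaching an x-face
        labels, n = extract_pores(mask, cap_faces=True)
        assert n == 0

    def test_pore_bisected_by_cut_face_is_kept_when_capped(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        mask[0:4, 8:10, 8:10] = False  # half-pore cut by the z=0 face
        labels_cap, n_cap = extract_pores(mask, cap_faces=True)
        labels_open, n_open = extract_pores(mask, cap_faces=False)
        assert n_cap == 1 and (labels_cap > 0).sum() == 16
        assert n_open == 0

    def test_open_region_guard_removes_marrow_like_space(self):
        mask = np.ones((16, 20, 20), dtype=bool)
        mask[:, 5:15, 5:15] = False  # big cavity open at both cut faces
        mask[8, 2, 2] = False  # one tiny enclosed pore
        labels, n = extract_pores(mask, cap_faces=True, open_region_max_voxels=100)
        assert n == 1
        assert (labels > 0).sum() == 1


class TestSphericity:
    def test_digitized_sphere_is_near_one(self):
        psi = pore_sphericity(digitized_sphere(20))
        assert psi == pytest.approx(1.0, abs=0.02)

    def test_digitized_cube_matches_analytic_wadell_index(self):
        psi = pore_sphericity(digitized_cube(20))
        assert psi == pytest.approx((math.pi / 6) ** (1 / 3), rel=0.03)

    def test_prolate_spheroid_matches_closed_form(self):
        a, b = 40.0, 20.0
        psi = pore_sphericity(digitized_ellipsoid((a, b, b)))
        v = 4.0 / 3.0 * math.pi * a * b * b
        expected = math.pi ** (1 / 3) * (6 * v) ** (2 / 3) / spheroid_surface_area(a, b)
        assert psi == pytest.approx(expected, rel=0.02)

    def test_degenerate_pore_returns_nan(self):
        flat = np.zeros((5, 5, 5), dtype=bool)
        flat[2, 1:4, 1:4] = True  # single-slice sheet
        assert math.isnan(pore_sphericity(flat))
        assert math.isnan(pore_sphericity(np.zeros((3, 3, 3), dtype=bool)))

    def test_voxel_size_invariance(self):
        m = digitized_sphere(8)
        assert pore_sphericity(m, 0.65) == pytest.approx(pore_sphericity(m, 1.0))


class TestClassifyPores:
    def test_volume_bands(self):
        # three pores with volumes 10 / 500 / 5000 um^3 at 1 um voxels
        from scipy import ndimage

        mask = np.zeros((40, 48, 48), dtype=bool)
        mask[2:4, 2:7, 2:3] = True  # 2x5x1 = 10 voxels
        mask[10:15, 10:20, 10:20] = True  # 5x10x10 = 500 voxels
        mask[25:30, 5:30, 5:45] = True  # 5x25x40 = 5000 voxels
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 3
        table = classify_pores(labels, voxel_size_um=1.0, compute_sphericity=False)
        classes = dict(zip(table.voxel_count, table.cls))
        assert classes[10] == "noise"
        assert classes[500] == "lacuna"
        assert classes[5000] == "canal"

    @pytest.mark.parametrize(
        "volume_um3,expected",
        [(24.999, "noise"), (25.0, "lacuna"), (1999.9, "lacuna"), (2000.0, "canal")],
    )
    def test_band_boundary_ties_go_up(self, volume_um3, expected):
        from osteolcn.core import classify_volume_um3

        assert classify_volume_um3(volume_um3) == expected


class TestLacunarMetrics:
    def _table(self, volumes_um3, vox=1.0):
        from osteolcn.core import classify_volume_um3

        return pd.DataFrame(
            {
                "label": range(1, len(volumes_um3) + 1),
                "voxel_count": [int(v / vox**3) for v in volumes_um3],
                "volume_um3": volumes_um3,
                "surface_area_um2": np.nan,
                "sphericity": np.nan,
                "centroid_z_um": 0.0,
                "centroid_y_um": 0.0,
                "centroid_x_um": 0.0,
                "cls": [classify_volume_um3(v) for v in volumes_um3],
            }
        )

    def test_density_arithmetic(self):
        # 100 lacunae of 100 um^3 in 0.002 mm^3 of filled cortex
        table = self._table([100.0] * 100)
        cortex_voxels = int(2e6 - 100 * 100)  # filled = cortex + pores
        mask = np.zeros(cortex_voxels, dtype=bool).reshape(-1, 1, 1) | True
        m = lacunar_metrics(table, mask, voxel_size_um=1.0)
        assert m.density_per_mm3 == pytest.approx(50_000.0)
        assert m.proportion_pct == pytest.approx(100 * 100 * 100 / 2e6)

    def test_no_lacunae_gives_zero_density_and_nan_means(self):
        table = self._table([])
        m = lacunar_metrics(table, np.ones((10, 10, 10), bool), 1.0)
        assert m.density_per_mm3 == 0.0
        assert m.proportion_pct == 0.0
        assert math.isnan(m.mean_volume_um3)

    def test_zero_cortex_raises(self):
        with pytest.raises(ValueError, match="cortical volume"):
            lacunar_metrics(self._table([]), np.zeros((4, 4, 4), bool), 1.0)


class TestInvariants:
    def test_partition_and_conservation_on_generated_volume(self):
        vol, _ = generate_volume(SMALL_VOLUME)
        res = analyze_volume(vol, compute_sphericity=False)
        table = res.pore_table
        # partition: every pore in exactly one class
        assert table.cls.isin(["noise", "lacuna", "canal"]).all()
        assert table.cls.value_counts().sum() == len(table)
        # conservation: filled cortex = cortex + all pore voxels, exactly
        from scipy import ndimage

        filled = res.cortex_mask | (res.pore_labels > 0)
        assert filled.sum() == res.cortex_mask.sum() + table.voxel_count.sum()

    def test_adding_one_lacuna_increments_count(self):
        vol, _ = generate_volume(SMALL_VOLUME)
        res = analyze_volume(vol, compute_sphericity=False)
        data = vol.data.copy()
        # carve an extra ellipsoidal pore in a clear wall location
        mask = res.cortex_mask
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, np.ones((9, 9, 9)))
        interior[(res.pore_labels > 0)] = False
        interior = ndimage.binary_erosion(interior, np.ones((3, 3, 3)))
        zc, yc, xc = [int(v[len(v) // 2]) for v in np.nonzero(interior)]
        z, y, x = np.ogrid[: data.shape[0], : data.shape[1], : data.shape[2]]
        pore = ((z - zc) / 5) ** 2 + ((y - yc) / 4) ** 2 + ((x - xc) / 3) ** 2 <= 1
        data[pore] = 40
        res2 = analyze_volume(VoxelVolume(data, vol.voxel_size_um), compute_sphericity=False)
        assert res2.metrics.n_lacunae == res.metrics.n_lacunae + 1
        assert res2.metrics.density_per_mm3 > res.metrics.density_per_mm3
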