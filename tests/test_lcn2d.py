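"""2D LCN quantification: binarization, area fraction, skeleton tracing
geometry, and the orientation-alignment statistic."""

import math

import numpy as np
import pytest
from skimage.draw import line as draw_line

from osteolcn.core import Field2D, wrap_angle_deg
from osteolcn.lcn2d import (
    LcnSegmentation,
    analyze_field,
    binarize_lcn,
    lcn_area_fraction,
    orientation_analysis,
    trace_canaliculi,
)
from osteolcn.synthetic import Field2DSpec, generate_field2d


def _segmentation_from_masks(network, bodies=None, pixel_size_um=0.5):
    h, w = network.shape
    bodies = bodies if bodies is not None else np.zeros((h, w), dtype=bool)
    from scipy import ndimage
    from skimage.morphology import disk

    grown = ndimage.binary_dilation(bodies, structure=disk(2))
    return LcnSegmentation(
        network=network & ~grown,
        bodies=bodies,
        bodies_grown=grown,
        roi=np.ones((h, w), dtype=bool),
        threshold=128.0,
        pixel_size_um=pixel_size_um,
    )


class TestBinarize:
    def test_uniform_bright_bone_gives_empty_mask(self):
        img = np.full((64, 64), 220, dtype=np.uint8)
        seg = binarize_lcn(Field2D(img, 0.5), threshold=100)
        assert seg.network.sum() == 0

    def test_empty_roi_raises(self):
        img = np.full((32, 32), 220, dtype=np.uint8)
        with pytest.raises(ValueError):
            Field2D(img, 0.5, bone_roi=np.zeros((32, 32), bool))

    def test_large_body_excluded_from_network(self):
        img = np.full((96, 96), 220, dtype=np.uint8)
        yy, xx = np.mgrid[:96, :96]
        body = ((yy - 48) / 10) ** 2 + ((xx - 48) / 20) ** 2 <= 1
        img[body] = 30
        img[10, 10:40] = 30  # a thin canaliculus-like line
        seg = binarize_lcn(Field2D(img, 0.5), threshold=128)
        assert not (seg.network & body).any()
        assert seg.network[10, 20]

    def test_network_count_close_to_generator_truth(self):
        fld, truth = generate_field2d(Field2DSpec(seed=21))
        seg = binarize_lcn(fld)
        assert seg.network.sum() == pytest.approx(truth.attrs["network_px"], rel=0.05)


class TestAreaFraction:
    def test_empty_network_is_zero(self):
        seg = _segmentation_from_masks(np.zeros((40, 40), bool))
        assert lcn_area_fraction(seg) == 0.0

    def test_half_filled_roi_is_fifty_percent(self):
        network = np.zeros((40, 40), dtype=bool)
        network[:20] = True
        seg = _segmentation_from_masks(network)
        assert lcn_area_fraction(seg) == pytest.approx(50.0)

    def test_generator_truth_recovered(self):
        fld, truth = generate_field2d(Field2DSpec(seed=22))
        seg = binarize_lcn(fld)
        measured = lcn_area_fraction(seg)
        assert measured == pytest.approx(
            100.0 * truth.attrs["true_area_fraction"], rel=0.05
        )


class TestTracing:
    def _field_with_one_canaliculus(self, rr_cc, pixel_size_um=0.5):
        img = np.full((120, 120), 220, dtype=np.uint8)
        yy, xx = np.mgrid[:120, :120]
        body = ((yy - 60) / 6) ** 2 + ((xx - 30) / 12) ** 2 <= 1
        img[body] = 30
        img[rr_cc] = 30
        return Field2D(img, pixel_size_um)

    def test_horizontal_segment_length(self):
        # 30 px straight line at 0.5 um/px -> 15 um, measured from the body
        rr, cc = draw_line(60, 43, 60, 72)
        fld = self._field_with_one_canaliculus((rr, cc))
        seg = binarize_lcn(fld, threshold=128, body_opening_radius_px=3)
        traces = trace_canaliculi(seg, n_lacunae=1)
        assert len(traces) == 1
        assert traces.length_um.iloc[0] == pytest.approx(15.0, abs=1.2)

    def test_diagonal_path_uses_sqrt2_steps(self):
        rr, cc = draw_line(57, 41, 27, 71)  # 30 diagonal steps from the body edge
        fld = self._field_with_one_canaliculus((rr, cc))
        seg = binarize_lcn(fld, threshold=128)
        traces = trace_canaliculi(seg, n_lacunae=1)
        assert len(traces) == 1
        expected = 30 * math.sqrt(2.0) * 0.5
        assert traces.length_um.iloc[0] == pytest.approx(expected, abs=1.5)

    def test_length_scale_equivariance(self):
        rr, cc = draw_line(60, 43, 60, 72)
        f1 = self._field_with_one_canaliculus((rr, cc), pixel_size_um=0.5)
        f2 = self._field_with_one_canaliculus((rr, cc), pixel_size_um=1.0)
        t1 = trace_canaliculi(binarize_lcn(f1, threshold=128), n_lacunae=1)
        t2 = trace_canaliculi(binarize_lcn(f2, threshold=128), n_lacunae=1)
        assert t2.length_um.iloc[0] == pytest.approx(2 * t1.length_um.iloc[0])

    def test_generator_mean_length_recovered(self):
        lens = []
        for seed in (31, 32, 33):
            fld, _ = generate_field2d(
                Field2DSpec(seed=seed, canaliculus_length_sd_um=2.0)
            )
            fa = analyze_field(fld)
            lens.extend(fa.traces.length_um.tolist())
        assert np.mean(lens) == pytest.approx(15.0, rel=0.10)


class TestOrientation:
    def _network_with_lines(self, angles_deg, n=200, length=40):
        network = np.zeros((n, n), dtype=bool)
        rng = np.random.default_rng(0)
        for ang in angles_deg:
            t = math.radians(ang)
            r0 = rng.integers(length + 2, n - length - 2)
            c0 = rng.integers(length + 2, n - length - 2)
            r1 = int(round(r0 - length * math.cos(t)))
            c1 = int(round(c0 + length * math.sin(t)))
            rr, cc = draw_line(r0, c0, r1, c1)
            network[rr, cc] = True
        return _segmentation_from_masks(network)

    def test_all_vertical_gives_one(self):
        seg = self._network_with_lines([0.0] * 12)
        frac, _ = orientation_analysis(seg)
        assert frac == 1.0

    def test_all_forty_five_gives_zero(self):
        seg = self._network_with_lines([45.0] * 12)
        frac, table = orientation_analysis(seg)
        assert frac == 0.0
        assert np.allclose(np.abs(table.angle_deg), 45.0, atol=2.0)

    def test_uniform_angles_approach_window_measure(self):
        # E[aligned] = 40/180 for angles uniform on (-90, 90]
        fracs = []
        for seed in (41, 42, 43, 44):
            fld, _ = generate_field2d(
                Field2DSpec(
                    seed=seed,
                    canaliculus_angle_sd_deg=None,
                    target_lcn_area_fraction=None,
                )
            )
            fa = analyze_field(fld)
            fracs.append(fa.aligned_fraction)
        assert np.mean(fracs) == pytest.approx(40.0 / 180.0, abs=0.05)

    def test_invariant_under_180_degree_rotation(self):
        fld, _ = generate_field2d(Field2DSpec(seed=51, target_lcn_area_fraction=None))
        fa = analyze_field(fld)
        rotated = Field2D(np.rot90(fld.image, 2).copy(), fld.pixel_size_um)
        fa_rot = analyze_field(rotated)
        assert fa_rot.aligned_fraction == pytest.approx(fa.aligned_fraction, abs=1e-12)

    def test_lower_concentration_does_not_increase_alignment(self):
        # monotone trend: wider angular spread -> lower aligned fraction
        def mean_aligned(sd):
            vals = []
            for seed in (61, 62, 63):
                fld, _ = generate_field2d(
                    Field2DSpec(
                        seed=seed,
                        canaliculus_angle_sd_deg=sd,
                        target_lcn_area_fraction=None,
                    )
                )
                vals.append(analyze_field(fld).aligned_fraction)
            return np.mean(vals)

        a15, a30, a60 = mean_aligned(15.0), mean_aligned(30.0), mean_aligned(60.0)
        assert a15 > a30 > a60

    def test_no_components_gives_nan(self):
        seg = _segmentation_from_masks(np.zeros((50, 50), bool))
        frac, _ = orientation_analysis(seg)
        assert math.isnan(frac)


class TestWrapAngle:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.0, 0.0), (90.0, 90.0), (-90.0, 90.0), (135.0, -45.0), (-135.0, 45.0), (180.0, 0.0)],
    )
    def test_axial_wrapping(self, raw, expected):
        assert wrap_angle_deg(raw) == pytest.approx(expected)
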