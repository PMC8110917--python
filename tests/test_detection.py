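from types import SimpleNamespace

import numpy as np
import pytest

import vesselkit as vk
from vesselkit.errors import BackendContractError, ValidationError


class TestBoxesFromPolyline:
    def test_straight_line_stride_divides_evenly(self):
        p = vk.Polyline(((0, 0), (10, 0)))
        ds = vk.boxes_from_polyline(p, box_size=8, stride=5)
        centers = [(b.cx, b.cy) for b in ds.boxes]
        assert centers == [(0, 0), (5, 0), (10, 0)]

    def test_short_polyline_keeps_both_endpoints(self):
        p = vk.Polyline(((0, 0), (3, 0)))
        ds = vk.boxes_from_polyline(p, box_size=8, stride=5)
        assert [(b.cx, b.cy) for b in ds.boxes] == [(0, 0), (3, 0)]

    def test_box_count_formula(self):
        # arc length 13, stride 5 -> interior samples 0,5,10 plus endpoint = 5
        p = vk.Polyline(((0, 0), (13, 0)))
        ds = vk.boxes_from_polyline(p, box_size=8, stride=5)
        assert len(ds.boxes) == int(13 // 5) + 2

    def test_non_overlapping_stride_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            vk.boxes_from_polyline(vk.Polyline(((0, 0), (10, 0))), box_size=8, stride=8)

    def test_union_of_boxes_covers_polyline(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = tuple(map(tuple, rng.uniform(50, 450, (6, 2))))
            p = vk.Polyline(pts)
            ds = vk.boxes_from_polyline(p, box_size=32, stride=16)
            L = vk.polyline_length(p)
            half = 16.0
            for s in np.arange(0, L, 0.1):
                x, y = vk.point_at_arc(p, float(s))
                assert any(
                    abs(x - b.cx) <= half and abs(y - b.cy) <= half for b in ds.boxes
                ), f"arc position {s} uncovered"

    def test_consecutive_centers_within_stride(self):
        rng = np.random.default_rng(6)
        pts = tuple(map(tuple, rng.uniform(0, 300, (5, 2))))
        ds = vk.boxes_from_polyline(vk.Polyline(pts), box_size=32, stride=16)
        c = np.array([(b.cx, b.cy) for b in ds.boxes])
        gaps = np.hypot(*np.diff(c, axis=0).T)
        assert np.all(gaps <= 16 + 1e-9)

    def test_boxes_inherit_label(self):
        p = vk.Polyline(((0, 0), (40, 0)), "debris")
        ds = vk.boxes_from_polyline(p, 32, 16)
        assert {b.label for b in ds.boxes} == {"debris"}


class TestOracleDetect:
    def _truth(self):
        return vk.AnnotationSet("t", [vk.Polyline(((0.0, 0.0), (200.0, 0.0)))])

    def test_noise_free_identity(self):
        truth = self._truth()
        ds = vk.oracle_detect(truth, 32, 16, jitter_sd=0, miss_rate=0, seed=4)
        ref = vk.boxes_for_annotations(truth, 32, 16)
        assert [(b.cx, b.cy, b.label) for b in ds.boxes] == [
            (b.cx, b.cy, b.label) for b in ref.boxes
        ]

    def test_deterministic_given_seed(self):
        truth = self._truth()
        a = vk.oracle_detect(truth, 32, 16, jitter_sd=1.5, miss_rate=0.3, seed=9)
        b = vk.oracle_detect(truth, 32, 16, jitter_sd=1.5, miss_rate=0.3, seed=9)
        assert [(x.cx, x.cy) for x in a.boxes] == [(x.cx, x.cy) for x in b.boxes]
        c = vk.oracle_detect(truth, 32, 16, jitter_sd=1.5, miss_rate=0.3, seed=10)
        assert [(x.cx, x.cy) for x in a.boxes] != [(x.cx, x.cy) for x in c.boxes]

    def test_retained_fraction_matches_binomial(self):
        # one long straight vessel -> 501 boxes at stride 16
        truth = vk.AnnotationSet("t", [vk.Polyline(((0.0, 0.0), (8000.0, 0.0)))])
        n_boxes = len(vk.boxes_for_annotations(truth, 32, 16).boxes)
        fracs = [
            len(vk.oracle_detect(truth, 32, 16, miss_rate=0.2, seed=s).boxes) / n_boxes
            for s in range(50)
        ]
        sd_mean = np.sqrt(0.2 * 0.8 / (n_boxes * 50))
        assert abs(np.mean(fracs) - 0.8) < 3 * sd_mean

    def test_false_positives_are_vessel_labelled_and_bounded(self):
        truth = self._truth()
        ds = vk.oracle_detect(
            truth, 32, 16, miss_rate=0, false_positive_count=20, seed=1, field_px=(300, 120)
        )
        extras = ds.boxes[len(vk.boxes_for_annotations(truth, 32, 16).boxes):]
        assert len(extras) == 20
        assert all(b.label == "vessel" for b in extras)
        assert all(0 <= b.cx <= 300 and 0 <= b.cy <= 120 for b in extras)


class TestClassicalDetect:
    def _bar_image(self):
        img = np.zeros((120, 200))
        img[58:63, 40:140] = 1.0
        return vk.Image2D(img, 1.0, "fluorescent", "bar")

    def test_blank_image_empty_set(self):
        ds = vk.classical_detect(vk.Image2D(np.zeros((50, 50)) + 1.0, 1.0), 0.9, 20, 5000)
        assert ds.boxes == []

    def test_box_centers_lie_on_the_bar(self):
        ds = vk.classical_detect(self._bar_image(), 0.9, 20, 50000, box_size=32, stride=16)
        assert len(ds.boxes) >= 3
        for b in ds.boxes:
            assert 38 <= b.cx <= 141 and 56 <= b.cy <= 64
            assert 0.0 <= b.confidence <= 1.0

    def test_small_component_filtered_out(self):
        img = self._bar_image().pixels.copy()
        img[10:12, 10:12] = 1.0  # 4-px speck below min_component_px
        ds = vk.classical_detect(vk.Image2D(img, 1.0), 0.9, 20, 50000)
        assert all(b.cy > 40 for b in ds.boxes)


class TestPixelBasedLength:
    def test_blank_image_zero(self):
        assert vk.pixel_based_length(vk.Image2D(np.zeros((64, 64)) + 0.5, 1.0)) == 0.0

    def test_horizontal_bar_length_recovered(self):
        img = np.zeros((160, 160))
        img[78:83, 30:130] = 1.0  # 100 px axis length, 5 px wide
        L = vk.pixel_based_length(vk.Image2D(img, 1.0), 0.9, 50, 50000)
        assert L == pytest.approx(100, abs=5)

    def test_small_speck_does_not_change_length(self):
        img = np.zeros((160, 160))
        img[78:83, 30:130] = 1.0
        base = vk.pixel_based_length(vk.Image2D(img, 1.0), 0.9, 10, 50000)
        img2 = img.copy()
        img2[10:12, 10:12] = 1.0  # 4 px speck < min_object_px=10
        with_speck = vk.pixel_based_length(vk.Image2D(img2, 1.0), 0.9, 10, 50000)
        assert with_speck == pytest.approx(base, abs=1e-9)

    def test_diagonal_bar_uses_sqrt2_steps(self):
        img = np.zeros((160, 160))
        for i in range(100):
            img[20 + i, 20 + i] = 1.0
            img[21 + i, 20 + i] = 1.0
            img[20 + i, 21 + i] = 1.0
        L = vk.pixel_based_length(vk.Image2D(img, 1.0), 0.9, 50, 50000)
        assert L == pytest.approx(99 * np.sqrt(2), rel=0.08)


class TestDetectDispatch:
    def test_dispatch_matches_direct_call(self):
        img = np.zeros((120, 200))
        img[58:63, 40:140] = 1.0
        image = vk.Image2D(img, 1.0, "fluorescent", "bar")
        direct = vk.classical_detect(image, 0.9, 20, 50000, 32, 16.0)
        via = vk.detect(
            image, "classical", threshold_quantile=0.9, min_component_px=20,
            max_component_px=50000, box_size=32, stride=16.0,
        )
        assert [(b.cx, b.cy) for b in via.boxes] == [(b.cx, b.cy) for b in direct.boxes]

    def test_contract_violation_names_the_box(self):
        bad = SimpleNamespace(cx=1.0, cy=1.0, w=0.0, h=5.0, confidence=0.5, label="vessel")

        def backend(image):
            return vk.DetectionSet(image.id, [bad])

        with pytest.raises(BackendContractError, match="box 0"):
            vk.detect(vk.Image2D(np.ones((8, 8)), 1.0), backend)

    def test_detections_json_round_trip(self, tmp_path):
        ds = vk.DetectionSet(
            "img-7", [vk.DetectionBox(1.5, 2.5, 32, 32, 0.75, "vessel")]
        )
        path = tmp_path / "det.json"
        vk.write_detections(ds, path)
        back = vk.read_detections(path)
        assert back.image_id == "img-7"
        assert back.boxes[0] == ds.boxes[0]
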