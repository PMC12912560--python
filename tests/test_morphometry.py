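"""Airspace measurement, gate classification and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import draw

from lungmorph import (
    AirspaceMeasurement,
    CalibrationSettings,
    ClassificationParams,
    classify_airspace,
    label_airspaces,
    measure_airspaces,
    summarize_animal,
    summarize_image,
)


def measurement(area, circ=0.8, label=1):
    return AirspaceMeasurement(
        label=label, area_um2=area, perimeter_um=1.0, circularity=circ,
        centroid_xy=(0.0, 0.0), touches_edge=False,
    )


class TestMeasurement:
    def test_large_disk_circularity_near_one(self, calibration):
        mask = np.ones((220, 220), dtype=bool)
        rr, cc = draw.disk((110, 110), 80)
        mask[rr, cc] = False
        (m,) = measure_airspaces(label_airspaces(mask, calibration), calibration)
        assert 0.95 <= m.circularity <= 1.0
        # Crofton perimeter within 2% of the analytic circumference
        assert m.perimeter_um == pytest.approx(2 * np.pi * 80, rel=0.02)

    def test_single_pixel_object(self):
        cal = CalibrationSettings(scale_um_per_px=2.0, threshold=150)
        mask = np.ones((5, 5), dtype=bool)
        mask[2, 2] = False
        (m,) = measure_airspaces(label_airspaces(mask, cal), cal)
        assert m.area_um2 == pytest.approx(4.0)  # scale^2
        assert m.circularity == 1.0  # capped

    def test_square_area_and_scale(self):
        cal = CalibrationSettings(scale_um_per_px=0.5, threshold=150)
        mask = np.ones((70, 70), dtype=bool)
        mask[10:60, 10:60] = False
        (m,) = measure_airspaces(label_airspaces(mask, cal), cal)
        assert m.area_um2 == pytest.approx(50 * 50 * 0.25)

    def test_edge_touch_flag(self, calibration):
        mask = np.ones((20, 20), dtype=bool)
        mask[0:4, 5:9] = False
        mask[10:14, 10:14] = False
        ms = measure_airspaces(label_airspaces(mask, calibration), calibration)
        assert sorted(m.touches_edge for m in ms) == [False, True]


class TestClassification:
    @pytest.mark.parametrize(
        "area, circ, expected",
        [
            (4500, 0.30, "duct"),  # optimal duct gate: >=4000 um^2, circ 0-0.5
            (200, 0.80, "alveolus"),  # optimal alveolus gate: 150 um^2, circ 0.01-1
            (4500, 0.70, "unclassified"),  # fails the duct circularity gate
            (40, 0.90, "unclassified"),  # below the alveolus minimum
            (2000, 0.20, "intermediate"),  # buffer band carries no circ gate
            (4000, 0.50, "duct"),  # inclusive bounds
            (150, 0.01, "alveolus"),
            (200, 0.005, "unclassified"),  # below the alveolus circ floor
        ],
    )
    def test_gate_assignment(self, area, circ, expected):
        assert classify_airspace(measurement(area, circ), ClassificationParams()) == expected

    def test_invalid_band_ordering_rejected(self):
        with pytest.raises(ValueError):
            ClassificationParams(alv_min_area_um2=2000, alv_max_area_um2=1500)
        with pytest.raises(ValueError):
            ClassificationParams(duct_circ=(0.0, 1.5))

    @given(
        area=st.floats(min_value=1e-3, max_value=1e6),
        circ=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_every_airspace_gets_exactly_one_class(self, area, circ):
        cls = classify_airspace(measurement(area, circ), ClassificationParams())
        assert cls in {"duct", "intermediate", "alveolus", "unclassified"}
        # area bands are disjoint by construction
        if 1500 <= area < 4000:
            assert cls == "intermediate"

    @given(
        areas=st.lists(st.floats(min_value=10, max_value=20000), min_size=1, max_size=30),
        lo=st.floats(min_value=1500, max_value=6000),
        hi=st.floats(min_value=1500, max_value=6000),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_duct_minimum_never_increases_duct_count(self, areas, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        ms = [measurement(a, 0.3) for a in areas]

        def duct_count(min_area):
            p = ClassificationParams(duct_min_area_um2=min_area, alv_max_area_um2=1499)
            return sum(classify_airspace(m, p) == "duct" for m in ms)

        assert duct_count(hi) <= duct_count(lo)


class TestImageSummary:
    def test_two_duct_arithmetic(self):
        ms = [measurement(4000, 0.3), measurement(6000, 0.3)]
        for m in ms:
            m.assigned_class = "duct"
        s = summarize_image(ms, tissue_area_um2=1e4, image_id="f1")
        assert s.count["duct"] == 2
        assert s.mean_area_um2["duct"] == pytest.approx(5000)
        assert s.total_area_um2["duct"] == pytest.approx(10000)
        assert s.percent_area["duct"] == pytest.approx(100)

    def test_mixed_classes_percent(self):
        duct, alv = measurement(5000, 0.3), measurement(500, 0.9, label=2)
        duct.assigned_class, alv.assigned_class = "duct", "alveolus"
        s = summarize_image([duct, alv], tissue_area_um2=1e4)
        assert s.percent_area["duct"] == pytest.approx(100 * 5000 / 5500)
        assert sum(s.percent_area[c] for c in ("duct", "intermediate", "alveolus")
                   if s.percent_area[c] is not None) == pytest.approx(100)

    def test_empty_image_reports_missing_not_zero(self):
        s = summarize_image([], tissue_area_um2=100.0)
        assert all(v == 0 for v in s.count.values())
        assert all(v is None for v in s.mean_area_um2.values())
        assert all(v is None for v in s.percent_area.values())


class TestAnimalSummary:
    @staticmethod
    def field(counts=(3,), animal="m1"):
        ms = []
        for i, _ in enumerate(range(counts[0])):
            m = measurement(5000, 0.3, label=i + 1)
            m.assigned_class = "duct"
            ms.append(m)
        return summarize_image(ms, tissue_area_um2=1e4, image_id="f", animal_id=animal)

    def test_identical_fields_mean_identity(self):
        fields = [self.field() for _ in range(6)]
        a = summarize_animal(fields)
        assert a.count["duct"] == pytest.approx(3)
        assert a.mean_area_um2["duct"] == pytest.approx(5000)
        assert a.n_fields == 6

    def test_count_mean_over_two_fields(self):
        with pytest.warns(UserWarning, match="2 fields"):
            a = summarize_animal([self.field((3,)), self.field((5,))])
        assert a.count["duct"] == pytest.approx(4.0)

    def test_unexpected_field_count_warns(self):
        with pytest.warns(UserWarning, match="5 fields"):
            summarize_animal([self.field() for _ in range(5)])

    def test_mixed_animals_rejected(self):
        with pytest.raises(ValueError, match="mixed animal ids"):
            summarize_animal([self.field(animal="m1"), self.field(animal="m2")])
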