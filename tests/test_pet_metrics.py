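import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsig.pet_metrics import (
    caliper_volume,
    classify_preclinical_response,
    lean_body_mass_g,
    metabolic_tumor_volume,
    normalize_suv,
    percent_change,
    sul_peak,
    suv_summary,
)

from conftest import make_scan


class TestNormalizeSuv:
    def test_formula_arithmetic(self):
        # 1000 Bq/mL, 25 g animal, 7.4 MBq dose
        suv = normalize_suv(np.array([[[1000.0]]]), 25.0, 7.4e6)
        assert suv[0, 0, 0] == pytest.approx(0.003378, abs=1e-6)

    def test_activity_equal_dose_over_weight_gives_unity(self):
        act = np.full((2, 2, 2), 7.4e6 / 25.0)
        assert np.allclose(normalize_suv(act, 25.0, 7.4e6), 1.0)

    def test_linearity_in_weight(self):
        act = np.random.default_rng(0).uniform(10, 100, (3, 3, 3))
        assert np.allclose(
            normalize_suv(act, 50.0, 7.4e6), 2 * normalize_suv(act, 25.0, 7.4e6)
        )

    @pytest.mark.parametrize("dose,weight", [(0, 25), (-1, 25), (7e6, 0), (7e6, -2)])
    def test_nonpositive_dose_or_weight_rejected(self, dose, weight):
        with pytest.raises(ValueError):
            normalize_suv(np.ones((1, 1, 1)), weight, dose)


class TestSuvSummary:
    def test_uniform_tumor(self):
        s = suv_summary(make_scan(np.full((6, 6, 6), 3.0)))
        assert s.suv_mean == s.suv_max == s.suv_median == 3.0
        assert s.suv_sd == 0.0

    def test_tumor_volume_from_voxel_count(self):
        vals = np.ones((10, 10, 10))
        assert suv_summary(make_scan(vals)).tumor_volume_ml == pytest.approx(1.0)

    def test_hot_voxel_order_statistics(self):
        vals = np.ones((5, 5, 5))
        vals[2, 2, 2] = 10.0
        s = suv_summary(make_scan(vals))
        assert s.suv_max == 10.0
        assert s.suv_median == 1.0
        assert s.suv_min <= s.suv_median <= s.suv_max
        assert s.sul_peak <= s.suv_max

    def test_mean_within_min_max(self, sample_scan):
        s = suv_summary(sample_scan)
        assert s.suv_min <= s.suv_mean <= s.suv_max
        assert s.suv_peak <= s.suv_max


class TestSulPeak:
    def test_uniform_preclinical_sul_equals_suv(self):
        # preclinical SUL == SUV (no rodent LBM); uniform tumor -> peak = SUV
        scan = make_scan(np.full((14, 14, 14), 2.0))
        peak, _ = sul_peak(scan)
        assert peak == pytest.approx(2.0)

    def test_sphere_averaging_dilutes_a_spike(self):
        vals = np.ones((14, 14, 14))
        vals[7, 7, 7] = 50.0
        peak, fell_back = sul_peak(make_scan(vals))
        assert not fell_back
        assert peak < 50.0

    def test_small_voi_falls_back_to_mean(self):
        vals = np.full((4, 4, 4), 2.0)  # 0.064 mL < 1 mL sphere
        peak, fell_back = sul_peak(make_scan(vals))
        assert fell_back
        assert peak == pytest.approx(2.0)

    def test_clinical_lbm_scales_peak(self):
        scan = make_scan(
            np.full((10, 10, 10), 4.0), spacing=(2.0, 2.0, 2.0),
            arm="clinical", weight=70000.0, sex="F", height_cm=165.0,
        )
        peak, _ = sul_peak(scan)
        lbm = lean_body_mass_g("F", 70000.0, 165.0)
        assert peak == pytest.approx(4.0 * lbm / 70000.0)
        assert 0 < lbm < 70000.0


class TestCaliperVolume:
    @pytest.mark.parametrize(
        "l,w,expected", [(6, 3, 9.0), (10, 5, 41.666667), (0, 0, 0.0)]
    )
    def test_printed_formula(self, l, w, expected):
        assert caliper_volume(l, w) == pytest.approx(expected, rel=1e-6)

    def test_ellipsoid_variant(self):
        assert caliper_volume(6, 3, ellipsoid=True) == pytest.approx(9 * np.pi)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            caliper_volume(-1, 1)


class TestMetabolicTumorVolume:
    def test_uniform_tumor_mtv_equals_volume(self):
        scan = make_scan(np.full((10, 10, 10), 2.0))
        assert metabolic_tumor_volume(scan) == pytest.approx(scan.tumor_volume_ml)

    def test_two_level_phantom_halves(self):
        vals = np.ones((10, 10, 10))
        vals[:5] = 10.0  # half the voxels above 40% of max
        scan = make_scan(vals)
        assert metabolic_tumor_volume(scan) == pytest.approx(
            scan.tumor_volume_ml / 2
        )

    def test_zero_fraction_recovers_full_volume(self):
        vals = np.random.default_rng(1).uniform(1, 5, (8, 8, 8))
        scan = make_scan(vals)
        assert metabolic_tumor_volume(scan, 0.0) == pytest.approx(
            scan.tumor_volume_ml
        )


class TestPercentChange:
    def test_halving_is_minus_fifty(self):
        assert percent_change(10, 5) == -50.0

    def test_no_change_is_zero(self):
        assert percent_change(3.3, 3.3) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0, 1)


class TestResponseTrichotomy:
    @pytest.mark.parametrize(
        "pct,label",
        [(-25, "response"), (0, "partial"), (-20, "partial"), (20, "partial"),
         (25, "no_response"), (-20.0001, "response"), (20.0001, "no_response")],
    )
    def test_thresholds(self, pct, label):
        assert classify_preclinical_response(pct) == label

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_partitions_the_real_line(self, pct):
        assert classify_preclinical_response(pct) in {
            "response", "partial", "no_response"
        }
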