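"""Closed-form (Sen, Spe, Pre) metrics vs the derived-matrix oracle, and sweeps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prevcal import (
    DegenerateLimitWarning,
    PerformanceProfile,
    PrevcalError,
    UndefinedLimitError,
    accuracy,
    accuracy_at,
    balanced_mcc,
    calibrate_matrix,
    calibrated_metric,
    from_profile,
    mcc,
    mcc_at,
    sweep,
)
from prevcal.calibration import SweepCurve

from conftest import interior_floats, profiles, unit_floats


class TestClosedForms:
    @pytest.mark.parametrize(
        "sen, spe, pre, expected",
        [
            (0.71, 0.89, 0.5, 0.800),
            (0.71, 0.89, 0.0, 0.890),  # intercept = Spe
            (0.71, 0.89, 1.0, 0.710),  # limit = Sen
            (0.68, 0.85, 0.6, 0.748),
        ],
    )
    def test_accuracy_at(self, sen, spe, pre, expected):
        assert accuracy_at(sen, spe, pre) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "sen, spe, pre, expected",
        [
            (0.680, 0.850, 0.600, 0.520),
            (0.710, 0.890, 0.900, 0.377),
            (0.5, 0.5, 0.25, 0.0),
        ],
    )
    def test_mcc_at(self, sen, spe, pre, expected):
        assert round(mcc_at(sen, spe, pre), 3) == expected

    @pytest.mark.parametrize(
        "sen, spe, expected",
        [
            (0.680, 0.850, 0.538),
            (0.710, 0.890, 0.610),
            (0.9, 0.9, 0.8),  # sen = spe: balanced MCC = Sen + Spe - 1
        ],
    )
    def test_balanced_mcc(self, sen, spe, expected):
        assert round(balanced_mcc(sen, spe), 3) == expected

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(PrevcalError):
            accuracy_at(1.2, 0.5, 0.5)
        with pytest.raises(PrevcalError):
            mcc_at(0.5, 0.5, -0.1)


class TestEndpointPolicy:
    def test_interior_senspe_anchors_to_zero_with_warning(self):
        with pytest.warns(DegenerateLimitWarning):
            assert mcc_at(0.7, 0.8, 0.0) == 0.0
        with pytest.warns(DegenerateLimitWarning):
            assert mcc_at(0.7, 0.8, 1.0) == 0.0

    @pytest.mark.parametrize("sen, spe", [(1.0, 0.7), (0.7, 0.0), (1.0, 1.0)])
    def test_exempt_corner_cases_raise(self, sen, spe):
        with pytest.raises(UndefinedLimitError):
            mcc_at(sen, spe, 0.0)

    def test_balanced_mcc_degenerate(self):
        with pytest.warns(DegenerateLimitWarning):
            assert balanced_mcc(1.0, 0.0) == 0.0


class TestCalibratedMetric:
    def test_examples(self):
        assert calibrated_metric("accuracy", 0.71, 0.89, 0.5) == pytest.approx(0.800, abs=1e-12)
        assert round(calibrated_metric("mcc", 0.71, 0.89, 0.5), 3) == 0.610
        assert round(calibrated_metric("ppv", 0.71, 0.89, 0.5), 4) == 0.8659

    def test_unknown_metric(self):
        with pytest.raises(PrevcalError, match="unknown metric"):
            calibrated_metric("auroc", 0.7, 0.8, 0.5)

    def test_one_class_target_rejected(self):
        with pytest.raises(UndefinedLimitError):
            calibrated_metric("ppv", 0.7, 0.8, 0.0)

    @given(profile=profiles(), n=st.integers(1, 10**6))
    def test_result_is_n_independent(self, profile, n):
        a = calibrated_metric("mcc", float(profile.sen), float(profile.spe), profile.pre)
        cm = from_profile(PerformanceProfile(profile.sen, profile.spe, profile.pre, n))
        assert float(mcc(cm)) == pytest.approx(a, abs=1e-12)


class TestOracleEquivalence:
    """Closed forms against brute force through the derived confusion matrix."""

    @given(sen=unit_floats, spe=unit_floats, pre=interior_floats)
    def test_accuracy_closed_form(self, sen, spe, pre):
        cm = from_profile(PerformanceProfile(sen, spe, pre, 1000))
        assert accuracy_at(sen, spe, pre) == pytest.approx(float(accuracy(cm)), abs=1e-12)

    @given(sen=unit_floats, spe=unit_floats, pre=interior_floats)
    def test_mcc_closed_form(self, sen, spe, pre):
        cm = from_profile(PerformanceProfile(sen, spe, pre, 1000))
        assert mcc_at(sen, spe, pre) == pytest.approx(float(mcc(cm)), abs=1e-12)

    @given(sen=unit_floats, spe=unit_floats)
    def test_balanced_mcc_is_mcc_at_half(self, sen, spe):
        if abs(sen - spe) == 1.0:
            return
        assert balanced_mcc(sen, spe) == pytest.approx(mcc_at(sen, spe, 0.5), abs=1e-12)

    @given(profile=profiles(interior_senspe=True), other_pre=interior_floats)
    def test_balanced_metrics_invariant_to_source_prevalence(self, profile, other_pre):
        """Two matrices sharing (sen, spe) give identical balanced values."""
        shifted = calibrate_matrix(profile, other_pre, profile.n)
        for metric in ("accuracy", "mcc", "kappa", "f1"):
            a = calibrated_metric(metric, float(profile.sen), float(profile.spe), 0.5)
            p2 = shifted.to_profile()
            b = calibrated_metric(metric, float(p2.sen), float(p2.spe), 0.5)
            assert a == pytest.approx(b, abs=1e-9)

    @given(sen=unit_floats, spe=unit_floats)
    def test_balanced_kappa_equals_informedness(self, sen, spe):
        assert calibrated_metric("kappa", sen, spe, 0.5) == pytest.approx(
            sen + spe - 1.0, abs=1e-12
        )

    @given(sen=interior_floats, spe=interior_floats)
    def test_balanced_ppv_npv_closed_forms(self, sen, spe):
        assert calibrated_metric("ppv", sen, spe, 0.5) == pytest.approx(
            sen / (sen + 1.0 - spe), abs=1e-12
        )
        assert calibrated_metric("npv", sen, spe, 0.5) == pytest.approx(
            spe / (spe + 1.0 - sen), abs=1e-12
        )


class TestSweep:
    def test_accuracy_sweep_is_affine(self):
        curve = sweep("accuracy", 0.71, 0.89, 3, 0.01)
        grid, values = curve.to_arrays()
        slopes = np.diff(values) / np.diff(grid)
        assert slopes == pytest.approx([-0.18, -0.18], abs=1e-12)
        # intercept extrapolates to Spe at pre -> 0
        assert values[0] - slopes[0] * grid[0] == pytest.approx(0.89, abs=1e-12)

    def test_mcc_sweep_hits_balanced_value_at_half(self):
        curve = sweep("mcc", 0.71, 0.89, 199, 0.005)
        grid, values = curve.to_arrays()
        mid = np.argmin(np.abs(grid - 0.5))
        assert grid[mid] == pytest.approx(0.5, abs=1e-12)
        assert round(values[mid], 3) == 0.610

    def test_chance_level_sweep_is_flat_zero(self):
        curve = sweep("mcc", 0.5, 0.5, 21, 0.01)
        assert np.allclose(curve.values, 0.0, atol=1e-12)

    def test_mcc_vanishes_toward_endpoints(self):
        for pre in (1e-9, 1.0 - 1e-9):
            assert abs(mcc_at(0.71, 0.89, pre)) < 1e-3

    @given(sen=interior_floats)
    def test_symmetric_umbrella_when_sen_equals_spe(self, sen):
        curve = sweep("mcc", sen, sen, 21, 0.01)
        grid, values = curve.to_arrays()
        assert values == pytest.approx(values[::-1], abs=1e-12)
        if np.max(np.abs(values)) > 1e-9:  # sen = spe = 0.5 gives a flat zero curve
            extremum = np.argmax(np.abs(values))
            assert grid[extremum] == pytest.approx(0.5, abs=1e-12)

    def test_validation(self):
        with pytest.raises(PrevcalError):
            sweep("accuracy", 0.7, 0.8, 2, 0.01)
        with pytest.raises(PrevcalError):
            sweep("accuracy", 0.7, 0.8, 5, 0.7)
        with pytest.raises(PrevcalError):
            SweepCurve("mcc", 0.7, 0.8, (0.3, 0.2), (0.0, 0.0))
        with pytest.raises(PrevcalError):
            SweepCurve("mcc", 0.7, 0.8, (0.0, 0.5), (0.0, 0.0))
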