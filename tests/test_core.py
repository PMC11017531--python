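"""Confusion-matrix model, profile round-trip and prevalence calibration."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from prevcal import (
    UNDEFINED,
    ConfusionMatrix,
    PerformanceProfile,
    PrevcalError,
    UndefinedMetricError,
    calibrate_matrix,
    from_labels,
    from_profile,
    is_undefined,
    prevalence,
    sensitivity,
    specificity,
    to_profile,
)

from conftest import profiles


class TestConstruction:
    @pytest.mark.parametrize("bad", [(-1, 0, 0, 1), (0, 0, 0, 0), (1, float("nan"), 0, 0)])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(PrevcalError):
            ConfusionMatrix(*bad)

    def test_fractional_counts_allowed_unless_strict(self):
        cm = ConfusionMatrix(0.5, 0.5, 0.25, 0.75)
        assert cm.n == pytest.approx(2.0)
        with pytest.raises(PrevcalError, match="fractional"):
            ConfusionMatrix(0.5, 0.5, 0.25, 0.75, strict_integer=True)

    def test_profile_rejects_out_of_range(self):
        with pytest.raises(PrevcalError):
            PerformanceProfile(1.2, 0.5, 0.5, 10)
        with pytest.raises(PrevcalError):
            PerformanceProfile(0.5, 0.5, 0.5, 0)
        # UNDEFINED sensitivity is only legal on an all-negative set
        with pytest.raises(PrevcalError):
            PerformanceProfile(UNDEFINED, 0.5, 0.3, 10)
        PerformanceProfile(UNDEFINED, 0.5, 0.0, 10)


class TestFromLabels:
    @pytest.mark.parametrize(
        "actual, predicted, expected",
        [
            (["+", "+", "-", "-"], ["+", "-", "+", "-"], (1, 1, 1, 1)),
            (["+", "+", "+"], ["+", "+", "+"], (3, 0, 0, 0)),
        ],
    )
    def test_tabulation(self, actual, predicted, expected):
        cm = from_labels(actual, predicted, positive_label="+")
        assert cm.counts() == expected
        assert cm.n == len(actual)

    def test_errors(self):
        with pytest.raises(PrevcalError, match="equal length"):
            from_labels([1, 0], [1], positive_label=1)
        with pytest.raises(PrevcalError, match="two distinct"):
            from_labels([1, 0, 2], [1, 0, 2], positive_label=1)
        with pytest.raises(PrevcalError, match="positive label"):
            from_labels([0, 0], [0, 0], positive_label=1)


class TestDefiningStatistics:
    @pytest.mark.parametrize(
        "cells, pre, sen, spe",
        [
            ((816, 384, 120, 680), 0.600, 0.680, 0.850),
            ((639, 261, 11, 89), 0.900, 0.710, 0.890),
            ((5, 0, 3, 2), 0.5, 1.0, 0.4),
        ],
    )
    def test_values(self, cells, pre, sen, spe):
        cm = ConfusionMatrix(*cells)
        assert prevalence(cm) == pytest.approx(pre, abs=1e-12)
        assert sensitivity(cm) == pytest.approx(sen, abs=1e-12)
        assert specificity(cm) == pytest.approx(spe, abs=1e-12)

    def test_degenerate_statistics_are_marked_not_zero(self):
        no_positives = ConfusionMatrix(0, 0, 10, 10)
        assert prevalence(no_positives) == 0.0
        assert is_undefined(sensitivity(no_positives))
        no_negatives = ConfusionMatrix(3, 1, 0, 0)
        assert is_undefined(specificity(no_negatives))
        # consuming the marker raises a typed error, it is never coerced
        with pytest.raises(UndefinedMetricError):
            calibrate_matrix(to_profile(no_positives), 0.5)


class TestProfileRoundTrip:
    @pytest.mark.parametrize(
        "cells, profile",
        [
            ((816, 384, 120, 680), (0.680, 0.850, 0.600, 2000)),
            ((639, 261, 11, 89), (0.710, 0.890, 0.900, 1000)),
            ((1, 0, 0, 1), (1.0, 1.0, 0.5, 2)),
        ],
    )
    def test_to_profile(self, cells, profile):
        got = to_profile(ConfusionMatrix(*cells))
        assert (got.sen, got.spe, got.pre, got.n) == pytest.approx(profile, abs=1e-12)

    @pytest.mark.parametrize(
        "profile, cells",
        [
            ((0.680, 0.850, 0.600, 2000), (816, 384, 120, 680)),
            ((0.710, 0.890, 0.900, 1000), (639, 261, 11, 89)),
            ((0.5, 0.5, 0.5, 4), (1, 1, 1, 1)),
        ],
    )
    def test_from_profile(self, profile, cells):
        got = from_profile(PerformanceProfile(*profile))
        assert got.counts() == pytest.approx(cells, abs=1e-9)

    @given(integer_cells=st.tuples(*[st.integers(1, 10**6)] * 4))
    def test_round_trip_counts(self, integer_cells):
        cm = ConfusionMatrix(*integer_cells)
        back = from_profile(to_profile(cm))
        for a, b in zip(back.counts(), cm.counts()):
            assert a == pytest.approx(b, rel=1e-9)

    @given(profile=profiles())
    def test_class_totals_conserved(self, profile):
        """tp+fn = Pre·N and fp+tn = (1−Pre)·N, to machine precision."""
        cm = from_profile(profile)
        assert cm.tp + cm.fn == pytest.approx(profile.pre * profile.n, rel=1e-15)
        assert cm.fp + cm.tn == pytest.approx((1.0 - profile.pre) * profile.n, rel=1e-15)


class TestCalibration:
    def test_examples(self):
        cm = calibrate_matrix(PerformanceProfile(0.710, 0.890, 0.900, 1000), 0.5, 1000)
        assert cm.counts() == pytest.approx((355, 145, 55, 445), abs=1e-9)
        identity = calibrate_matrix(PerformanceProfile(0.680, 0.850, 0.600, 2000), 0.600, 2000)
        assert identity.counts() == pytest.approx((816, 384, 120, 680), abs=1e-9)
        perfect = calibrate_matrix(PerformanceProfile(1.0, 1.0, 0.9, 100), 0.5, 100)
        assert perfect.counts() == pytest.approx((50, 0, 0, 50), abs=1e-12)

    def test_one_class_target_refused_without_opt_in(self):
        profile = PerformanceProfile(0.7, 0.8, 0.5, 100)
        with pytest.raises(UndefinedMetricError):
            calibrate_matrix(profile, 0.0)
        degenerate = calibrate_matrix(profile, 1.0, allow_degenerate=True)
        assert degenerate.counts() == pytest.approx((70, 30, 0, 0), abs=1e-12)

    @given(profile=profiles())
    def test_fixed_point(self, profile):
        assert calibrate_matrix(profile, profile.pre, profile.n) == from_profile(profile)

    @given(profile=profiles(), target=st.floats(0.01, 0.99))
    def test_senspe_preserved_and_idempotent(self, profile, target):
        once = calibrate_matrix(profile, target, profile.n)
        assert prevalence(once) == pytest.approx(target, abs=1e-12)
        assert float(sensitivity(once)) == pytest.approx(float(profile.sen), abs=1e-12)
        assert float(specificity(once)) == pytest.approx(float(profile.spe), abs=1e-12)
        twice = calibrate_matrix(to_profile(once), target, profile.n)
        for a, b in zip(twice.counts(), once.counts()):
            assert a == pytest.approx(b, rel=1e-12, abs=1e-12)
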