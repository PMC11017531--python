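"""Confusion-matrix data model and the derived confusion matrix.

A binary-classification validation run is summarised by the four
prediction-type counts TP, FN, FP and TN.  Three statistics computed from
them — positive prevalence, sensitivity and specificity — together with the
total count N fully characterise the matrix.  The *derived confusion matrix*
re-expresses the four cells as

    TP = Sen · Pre · N          FN = (1 − Sen) · Pre · N
    TN = Spe · (1 − Pre) · N    FP = (1 − Spe) · (1 − Pre) · N

Prevalence and N describe the test set; sensitivity and specificity describe
the model and do not depend on prevalence.  Substituting an arbitrary target
prevalence into the derived matrix therefore reconstructs the confusion
matrix the same model would have produced on a test set of that composition
— the calibration mechanism on which every balanced metric in this package
is built.

Counts are carried as non-negative reals: calibrated matrices are in general
fractional, and keeping the algebra continuous avoids rounding drift in the
metric identities.  Raw validation data can opt into integer checking via
``ConfusionMatrix(..., strict_integer=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence, Union

from .exceptions import PrevcalError, UndefinedMetricError

__all__ = [
    "UNDEFINED",
    "Stat",
    "is_undefined",
    "ConfusionMatrix",
    "PerformanceProfile",
    "from_labels",
    "prevalence",
    "sensitivity",
    "specificity",
    "to_profile",
    "from_profile",
    "calibrate_matrix",
]


class _UndefinedType:
    """Singleton marker for a 0/0 statistic (e.g. sensitivity with no positives)."""

    _instance = None

    def __new__(cls) -> "_UndefinedType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __reduce__(self):
        return (_UndefinedType, ())


#: Explicit marker for an undefined statistic; never silently 0 or 1.
UNDEFINED = _UndefinedType()

#: A statistic that may be undefined.
Stat = Union[float, _UndefinedType]


def is_undefined(value: object) -> bool:
    """Return True if *value* is the :data:`UNDEFINED` marker."""
    return isinstance(value, _UndefinedType)


def _require_defined(value: Stat, what: str) -> float:
    if is_undefined(value):
        raise UndefinedMetricError(f"{what} is undefined for this input (0/0 ratio)")
    return float(value)  # type: ignore[arg-type]


def _check_unit_interval(value: float, name: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise PrevcalError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise PrevcalError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ConfusionMatrix:
    """The four prediction-type counts of a binary validation run.

    Parameters
    ----------
    tp, fn, fp, tn
        True-positive, false-negative, false-positive and true-negative
        counts.  Non-negative; may be fractional (calibrated matrices).
    strict_integer
        If True, reject fractional counts — use for raw validation data.
    """

    tp: float
    fn: float
    fp: float
    tn: float
    strict_integer: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise PrevcalError(f"count {name} must be a number, got {value!r}") from exc
            if not math.isfinite(value):
                raise PrevcalError(f"count {name} must be finite, got {value!r}")
            if value < 0:
                raise PrevcalError(f"count {name} must be non-negative, got {value!r}")
            if self.strict_integer and value != int(value):
                raise PrevcalError(
                    f"count {name}={value!r} is fractional; raw validation matrices "
                    "must hold integer counts (drop strict_integer for calibrated data)"
                )
            object.__setattr__(self, name, value)
        if self.n <= 0:
            raise PrevcalError("confusion matrix must contain at least one instance (N > 0)")

    @property
    def n(self) -> float:
        """Total number of instances N = TP + FN + FP + TN."""
        return self.tp + self.fn + self.fp + self.tn

    def counts(self) -> tuple[float, float, float, float]:
        """The cells in (tp, fn, fp, tn) order."""
        return (self.tp, self.fn, self.fp, self.tn)

    # convenience accessors mirroring the module-level functions
    @property
    def prevalence(self) -> float:
        return prevalence(self)

    @property
    def sensitivity(self) -> Stat:
        return sensitivity(self)

    @property
    def specificity(self) -> Stat:
        return specificity(self)

    def to_profile(self) -> "PerformanceProfile":
        return to_profile(self)


@dataclass(frozen=True)
class PerformanceProfile:
    """The (Sen, Spe, Pre, N) re-parameterisation of a confusion matrix.

    Sensitivity is :data:`UNDEFINED` when ``pre == 0`` (no positives) and
    specificity is :data:`UNDEFINED` when ``pre == 1`` (no negatives); in all
    other positions both must be real numbers in [0, 1].
    """

    sen: Stat
    spe: Stat
    pre: float
    n: float

    def __post_init__(self) -> None:
        pre = _check_unit_interval(self.pre, "prevalence")
        object.__setattr__(self, "pre", pre)
        try:
            n = float(self.n)
        except (TypeError, ValueError) as exc:
            raise PrevcalError(f"n must be a number, got {self.n!r}") from exc
        if not math.isfinite(n) or n <= 0:
            raise PrevcalError(f"n must be a positive count, got {self.n!r}")
        object.__setattr__(self, "n", n)
        if is_undefined(self.sen):
            if pre != 0.0:
                raise PrevcalError(
                    "sensitivity may be UNDEFINED only when prevalence is 0 (no positives)"
                )
        else:
            object.__setattr__(self, "sen", _check_unit_interval(self.sen, "sensitivity"))
        if is_undefined(self.spe):
            if pre != 1.0:
                raise PrevcalError(
                    "specificity may be UNDEFINED only when prevalence is 1 (no negatives)"
                )
        else:
            object.__setattr__(self, "spe", _check_unit_interval(self.spe, "specificity"))


def from_labels(
    actual: Sequence[Hashable],
    predicted: Sequence[Hashable],
    positive_label: Hashable,
) -> ConfusionMatrix:
    """Tabulate paired (actual, predicted) hard-class labels into counts.

    The positive class must be named explicitly: prevalence — and every
    prevalence-dependent metric — is defined with respect to it, and relying
    on an implicit label ordering is a classic source of silently transposed
    matrices.

    Raises
    ------
    PrevcalError
        On length mismatch, more than two distinct labels, or a
        ``positive_label`` absent from the observed label alphabet.
    """
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise PrevcalError(
            f"actual and predicted must have equal length, got {len(actual)} and {len(predicted)}"
        )
    if not actual:
        raise PrevcalError("label sequences must be non-empty")
    alphabet = set(actual) | set(predicted)
    if len(alphabet) > 2:
        raise PrevcalError(
            "binary classification requires at most two distinct labels, got "
            + ", ".join(sorted(repr(lab) for lab in alphabet))
        )
    if positive_label not in alphabet:
        raise PrevcalError(
            f"positive label {positive_label!r} does not occur among the observed "
            "labels " + ", ".join(sorted(repr(lab) for lab in alphabet))
        )
    tp = fn = fp = tn = 0
    for a, p in zip(actual, predicted):
        if a == positive_label:
            if p == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fn, fp, tn, strict_integer=True)


def prevalence(cm: ConfusionMatrix) -> float:
    """Positive prevalence Pre = (TP + FN) / N."""
    return (cm.tp + cm.fn) / cm.n


def sensitivity(cm: ConfusionMatrix) -> Stat:
    """Sensitivity Sen = TP / (TP + FN); :data:`UNDEFINED` with no positives."""
    positives = cm.tp + cm.fn
    if positives == 0:
        return UNDEFINED
    return cm.tp / positives


def specificity(cm: ConfusionMatrix) -> Stat:
    """Specificity Spe = TN / (FP + TN); :data:`UNDEFINED` with no negatives."""
    negatives = cm.fp + cm.tn
    if negatives == 0:
        return UNDEFINED
    return cm.tn / negatives


def to_profile(cm: ConfusionMatrix) -> PerformanceProfile:
    """Re-parameterise a confusion matrix as (Sen, Spe, Pre, N)."""
    return PerformanceProfile(sensitivity(cm), specificity(cm), prevalence(cm), cm.n)


def from_profile(profile: PerformanceProfile) -> ConfusionMatrix:
    """Reconstruct the confusion matrix from its (Sen, Spe, Pre, N) profile.

    Each cell is computed by its own product — TP = Sen·Pre·N,
    FN = (1−Sen)·Pre·N, TN = Spe·(1−Pre)·N, FP = (1−Spe)·(1−Pre)·N — so every
    cell carries full relative precision even when Sen or Spe sits next to 0
    or 1 (a complement-subtraction formulation would cancel catastrophically
    there).  Counts are real-valued; no rounding is applied.
    """
    pre, n = profile.pre, profile.n
    sen = 0.0 if is_undefined(profile.sen) else float(profile.sen)  # pre == 0: row is zero
    spe = 0.0 if is_undefined(profile.spe) else float(profile.spe)  # pre == 1: row is zero
    positives = pre * n
    negatives = (1.0 - pre) * n
    return ConfusionMatrix(
        sen * positives,
        (1.0 - sen) * positives,
        (1.0 - spe) * negatives,
        spe * negatives,
    )


def calibrate_matrix(
    profile: PerformanceProfile,
    target_prevalence: float,
    target_n: float | None = None,
    *,
    allow_degenerate: bool = False,
) -> ConfusionMatrix:
    """Reconstruct the matrix the same model would show at another prevalence.

    Holds the model's intrinsic performance (Sen, Spe) fixed and substitutes
    ``target_prevalence`` (and optionally ``target_n``, defaulting to the
    profile's N) into the derived confusion matrix.  The result has exactly
    the requested prevalence and the profile's sensitivity and specificity.

    Calibrating to prevalence 0 or 1 collapses the matrix to a single class
    and destroys one of (Sen, Spe); it is refused unless
    ``allow_degenerate=True``.
    """
    target_prevalence = _check_unit_interval(target_prevalence, "target prevalence")
    n = profile.n if target_n is None else float(target_n)
    if not math.isfinite(n) or n <= 0:
        raise PrevcalError(f"target n must be a positive count, got {target_n!r}")
    if target_prevalence in (0.0, 1.0):
        if not allow_degenerate:
            raise UndefinedMetricError(
                "calibrating to a one-class test set (prevalence "
                f"{target_prevalence:g}) loses sensitivity or specificity; pass "
                "allow_degenerate=True to build the degenerate matrix anyway"
            )
        if target_prevalence == 0.0:
            spe = _require_defined(profile.spe, "specificity")
            tn = spe * n
            return ConfusionMatrix(0.0, 0.0, n - tn, tn)
        sen = _require_defined(profile.sen, "sensitivity")
        tp = sen * n
        return ConfusionMatrix(tp, n - tp, 0.0, 0.0)
    sen = _require_defined(profile.sen, "sensitivity")
    spe = _require_defined(profile.spe, "specificity")
    return from_profile(PerformanceProfile(sen, spe, target_prevalence, n))
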