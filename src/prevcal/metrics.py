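"""Count-based validation metrics computed directly from a confusion matrix.

Every metric here is a function of the four prediction-type counts alone.
Because the derived confusion matrix expresses those counts through
(Sen, Spe, Pre, N), each metric implicitly depends on the test-set
prevalence unless the algebra cancels it — which is exactly the point this
package exists to expose.  The catalogue is keyed by stable string
identifiers (``METRICS``) so the calibration layer can evaluate any of them
on a reconstructed matrix.

Conventions
-----------
* MCC is defined as 0 whenever one of its four marginal sums vanishes,
  consistent with its anchor behaviour at extreme prevalence.  This is a
  documented convention, not a limit claim.
* Metrics whose denominator vanishes (PPV with no positive predictions,
  NPV, F1, kappa, balanced accuracy on a one-class set) carry the explicit
  :data:`~prevcal.core.UNDEFINED` marker instead of a silent 0.
* Values are carried at full double precision; rounding to the customary
  3 decimal places happens only in the reporting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict

from .core import (
    UNDEFINED,
    ConfusionMatrix,
    Stat,
    is_undefined,
    prevalence,
    sensitivity,
    specificity,
)
from .exceptions import DegenerateLimitWarning, PrevcalError, UndefinedMetricError

__all__ = [
    "MetricValue",
    "METRICS",
    "METRIC_RANGES",
    "accuracy",
    "balanced_accuracy",
    "mcc",
    "balanced_mcc_of",
    "ppv",
    "npv",
    "cohens_kappa",
    "f1",
    "informedness",
    "markedness",
    "rescale_unit_to_signed",
]

#: Declared bounds of each catalogue metric.
METRIC_RANGES: Dict[str, tuple[float, float]] = {
    "accuracy": (0.0, 1.0),
    "balanced_accuracy": (0.0, 1.0),
    "mcc": (-1.0, 1.0),
    "balanced_mcc": (-1.0, 1.0),
    "ppv": (0.0, 1.0),
    "npv": (0.0, 1.0),
    "kappa": (-1.0, 1.0),
    "f1": (0.0, 1.0),
    "informedness": (-1.0, 1.0),
    "markedness": (-1.0, 1.0),
}

_RANGE_SLACK = 1e-9  # tolerated floating overshoot before clamping


@dataclass(frozen=True)
class MetricValue:
    """A named metric score with the prevalence it was evaluated at.

    ``value`` is either a float within the declared ``range`` (tiny floating
    overshoot is clamped) or the :data:`~prevcal.core.UNDEFINED` marker.
    """

    name: str
    value: Stat
    range: tuple[float, float]
    at_prevalence: float

    def __post_init__(self) -> None:
        if self.name not in METRIC_RANGES:
            raise PrevcalError(f"unknown metric identifier {self.name!r}")
        if not is_undefined(self.value):
            lo, hi = self.range
            value = float(self.value)  # type: ignore[arg-type]
            if value < lo - _RANGE_SLACK or value > hi + _RANGE_SLACK:
                raise PrevcalError(
                    f"{self.name} value {value!r} outside declared range [{lo}, {hi}]"
                )
            object.__setattr__(self, "value", min(max(value, lo), hi))

    @property
    def defined(self) -> bool:
        return not is_undefined(self.value)

    def __float__(self) -> float:
        if not self.defined:
            raise UndefinedMetricError(f"metric {self.name!r} is undefined for this matrix")
        return float(self.value)  # type: ignore[arg-type]

    def to_record(self) -> dict:
        """JSON-ready record: {metric, value, at_prevalence, range}."""
        return {
            "metric": self.name,
            "value": None if not self.defined else float(self.value),  # type: ignore[arg-type]
            "at_prevalence": self.at_prevalence,
            "range": list(self.range),
        }


def _make(name: str, value: Stat, cm: ConfusionMatrix) -> MetricValue:
    return MetricValue(name, value, METRIC_RANGES[name], prevalence(cm))


def accuracy(cm: ConfusionMatrix) -> MetricValue:
    """Accuracy Acc = (TP + TN) / N, the raw fraction of correct predictions."""
    return _make("accuracy", (cm.tp + cm.tn) / cm.n, cm)


def balanced_accuracy(cm: ConfusionMatrix) -> MetricValue:
    """Balanced accuracy (Sen + Spe) / 2 — accuracy calibrated to prevalence 0.5."""
    sen, spe = sensitivity(cm), specificity(cm)
    if is_undefined(sen) or is_undefined(spe):
        return _make("balanced_accuracy", sen if is_undefined(sen) else spe, cm)
    return _make("balanced_accuracy", (float(sen) + float(spe)) / 2.0, cm)


def mcc(cm: ConfusionMatrix) -> MetricValue:
    """Matthews' correlation coefficient between actual and predicted classes.

    (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); 0 by convention when
    any marginal sum vanishes.
    """
    tp, fn, fp, tn = cm.counts()
    marginals = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if marginals == 0:
        return _make("mcc", 0.0, cm)
    return _make("mcc", (tp * tn - fp * fn) / math.sqrt(marginals), cm)


def _balanced_mcc_value(sen: float, spe: float) -> float:
    """Balanced MCC (Sen + Spe − 1) / √(1 − (Sen − Spe)²).

    At |Sen − Spe| = 1 both numerator and denominator vanish; 0 is returned
    by convention with a :class:`DegenerateLimitWarning`.
    """
    denom_sq = 1.0 - (sen - spe) ** 2
    if denom_sq <= 0.0:
        warnings.warn(
            "balanced MCC is 0/0 at |sen - spe| = 1; returning 0 by convention",
            DegenerateLimitWarning,
            stacklevel=3,
        )
        return 0.0
    return (sen + spe - 1.0) / math.sqrt(denom_sq)


def balanced_mcc_of(cm: ConfusionMatrix) -> MetricValue:
    """Balanced MCC of a matrix — MCC calibrated to prevalence 0.5.

    Depends only on the matrix's sensitivity and specificity, hence is
    invariant to the prevalence of the set it was measured on.
    """
    sen, spe = sensitivity(cm), specificity(cm)
    if is_undefined(sen) or is_undefined(spe):
        return _make("balanced_mcc", sen if is_undefined(sen) else spe, cm)
    return _make("balanced_mcc", _balanced_mcc_value(float(sen), float(spe)), cm)


def ppv(cm: ConfusionMatrix) -> MetricValue:
    """Positive predictivity TP / (TP + FP); undefined with no positive predictions."""
    denom = cm.tp + cm.fp
    return _make("ppv", UNDEFINED if denom == 0 else cm.tp / denom, cm)


def npv(cm: ConfusionMatrix) -> MetricValue:
    """Negative predictivity TN / (TN + FN); undefined with no negative predictions."""
    denom = cm.tn + cm.fn
    return _make("npv", UNDEFINED if denom == 0 else cm.tn / denom, cm)


def cohens_kappa(cm: ConfusionMatrix) -> MetricValue:
    """Cohen's kappa: agreement between actual and predicted beyond chance.

    Computed from counts as 2(TP·TN − FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)),
    algebraically equal to the observed-vs-expected-agreement form
    (p_o − p_e)/(1 − p_e).
    """
    tp, fn, fp, tn = cm.counts()
    denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if denom == 0:
        return _make("kappa", UNDEFINED, cm)
    return _make("kappa", 2.0 * (tp * tn - fn * fp) / denom, cm)


def f1(cm: ConfusionMatrix) -> MetricValue:
    """F1 score of the positive class, 2TP / (2TP + FP + FN); no macro-averaging."""
    tp, fn, fp, _ = cm.counts()
    denom = 2.0 * tp + fp + fn
    return _make("f1", UNDEFINED if denom == 0 else 2.0 * tp / denom, cm)


def informedness(cm: ConfusionMatrix) -> MetricValue:
    """Informedness (Youden's index) Sen + Spe − 1.

    Identical to balanced accuracy rescaled from [0, 1] to [−1, 1], and the
    numerator of MCC in its (Sen, Spe, Pre) form.
    """
    sen, spe = sensitivity(cm), specificity(cm)
    if is_undefined(sen) or is_undefined(spe):
        return _make("informedness", sen if is_undefined(sen) else spe, cm)
    return _make("informedness", float(sen) + float(spe) - 1.0, cm)


def markedness(cm: ConfusionMatrix) -> MetricValue:
    """Markedness PPV + NPV − 1, the predictivity analogue of informedness."""
    p, q = ppv(cm), npv(cm)
    if not p.defined or not q.defined:
        return _make("markedness", UNDEFINED, cm)
    return _make("markedness", float(p) + float(q) - 1.0, cm)


def rescale_unit_to_signed(value_01: float) -> float:
    """Rescale a [0, 1] score to [−1, 1] via 2·x − 1 (maps chance level 0.5 to 0)."""
    value = float(value_01)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise PrevcalError(f"value must lie in [0, 1], got {value_01!r}")
    return 2.0 * value - 1.0


#: Metric catalogue keyed by stable string identifiers.
METRICS: Dict[str, Callable[[ConfusionMatrix], MetricValue]] = {
    "accuracy": accuracy,
    "balanced_accuracy": balanced_accuracy,
    "mcc": mcc,
    "balanced_mcc": balanced_mcc_of,
    "ppv": ppv,
    "npv": npv,
    "kappa": cohens_kappa,
    "f1": f1,
    "informedness": informedness,
    "markedness": markedness,
}
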