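"""Metrics as closed-form functions of (Sen, Spe, Pre) and prevalence sweeps.

Because the derived confusion matrix writes every cell as a product of
sensitivity, specificity, prevalence and N, any count-based metric can be
re-expressed as a function of (Sen, Spe, Pre) with N cancelling.  Two such
closed forms are first-class here:

    Acc(Pre)  = Sen·Pre + Spe·(1 − Pre)            (affine in Pre)
    MCC(Pre)  = (Sen + Spe − 1) /
                √[(Sen + (1−Spe)(1−Pre)/Pre) · (Spe + (1−Sen)Pre/(1−Pre))]

Setting Pre = 0.5 gives the *balanced* versions: balanced accuracy
(Sen + Spe)/2 and balanced MCC (Sen + Spe − 1)/√(1 − (Sen − Spe)²).

:func:`calibrated_metric` is the generic mechanism: reconstruct the matrix
at the target prevalence and evaluate any catalogue metric on it.  The
closed forms and the generic path agree to machine precision, and the test
suite holds them against each other.  :func:`sweep` evaluates a metric over
a prevalence grid, producing the familiar straight line (accuracy) or
umbrella curve (MCC) with anchors at the prevalence endpoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np

from .core import PerformanceProfile, _check_unit_interval, from_profile
from .exceptions import DegenerateLimitWarning, PrevcalError, UndefinedLimitError
from .metrics import METRICS, _balanced_mcc_value

__all__ = [
    "accuracy_at",
    "mcc_at",
    "balanced_mcc",
    "calibrated_metric",
    "sweep",
    "SweepCurve",
    "DEFAULT_GRID_SIZE",
    "DEFAULT_EPSILON",
]

#: Sweep grid defaults: 199 points on [0.005, 0.995] render the MCC umbrella
#: smoothly while staying clear of the endpoint singularities.
DEFAULT_GRID_SIZE = 199
DEFAULT_EPSILON = 0.005


def accuracy_at(sen: float, spe: float, pre: float) -> float:
    """Accuracy at an arbitrary prevalence: Sen·Pre + Spe·(1 − Pre).

    Affine in prevalence with slope Sen − Spe and intercept Spe, so accuracy
    is prevalence-independent exactly when Sen = Spe.
    """
    sen = _check_unit_interval(sen, "sensitivity")
    spe = _check_unit_interval(spe, "specificity")
    pre = _check_unit_interval(pre, "prevalence")
    return sen * pre + spe * (1.0 - pre)


def mcc_at(sen: float, spe: float, pre: float) -> float:
    """MCC at an arbitrary prevalence, in its (Sen, Spe, Pre) closed form.

    At the prevalence endpoints 0 and 1 the curve is anchored at 0 for
    interior sensitivity and specificity; the anchor value is returned with
    a :class:`DegenerateLimitWarning`.  When sensitivity or specificity sits
    exactly at 0 or 1 the endpoint limit does not exist and
    :class:`UndefinedLimitError` is raised.
    """
    sen = _check_unit_interval(sen, "sensitivity")
    spe = _check_unit_interval(spe, "specificity")
    pre = _check_unit_interval(pre, "prevalence")
    if pre in (0.0, 1.0):
        if 0.0 < sen < 1.0 and 0.0 < spe < 1.0:
            warnings.warn(
                f"MCC at prevalence {pre:g} is reported as its anchor value 0",
                DegenerateLimitWarning,
                stacklevel=2,
            )
            return 0.0
        raise UndefinedLimitError(
            "MCC has no defined limit at prevalence "
            f"{pre:g} when sensitivity or specificity equals 0 or 1 "
            f"(sen={sen:g}, spe={spe:g})"
        )
    term_pos = sen + (1.0 - spe) * (1.0 - pre) / pre
    term_neg = spe + (1.0 - sen) * pre / (1.0 - pre)
    denom_sq = term_pos * term_neg
    if denom_sq == 0.0:
        # only reachable at (sen, spe) in {(0,1), (1,0)} where the numerator
        # also vanishes; keep the marginal-zero convention of the count form
        warnings.warn(
            "MCC is 0/0 for a one-column prediction matrix; returning 0 by convention",
            DegenerateLimitWarning,
            stacklevel=2,
        )
        return 0.0
    return (sen + spe - 1.0) / math.sqrt(denom_sq)


def balanced_mcc(sen: float, spe: float) -> float:
    """Balanced MCC: (Sen + Spe − 1) / √(1 − (Sen − Spe)²), i.e. MCC at Pre = 0.5.

    Equals the rescaled balanced accuracy Sen + Spe − 1 whenever Sen = Spe.
    At |Sen − Spe| = 1 the expression is 0/0 and 0 is returned by convention
    with a :class:`DegenerateLimitWarning`.
    """
    sen = _check_unit_interval(sen, "sensitivity")
    spe = _check_unit_interval(spe, "specificity")
    return _balanced_mcc_value(sen, spe)


def calibrated_metric(
    metric: str,
    sen: float,
    spe: float,
    target_prevalence: float = 0.5,
) -> float:
    """Evaluate any catalogue metric at an arbitrary target prevalence.

    Reconstructs the derived confusion matrix for (sen, spe) at
    ``target_prevalence`` and evaluates the count-based metric on it.  N
    cancels out of every catalogue metric, so the result is N-independent;
    a unit N is used internally.  The default target 0.5 yields the
    *balanced* version of the metric.

    Raises
    ------
    PrevcalError
        Unknown metric identifier.
    UndefinedLimitError
        ``target_prevalence`` at 0 or 1 (one-class matrix).
    UndefinedMetricError
        The metric is undefined on the calibrated matrix.
    """
    if metric not in METRICS:
        raise PrevcalError(
            f"unknown metric {metric!r}; catalogue: {', '.join(sorted(METRICS))}"
        )
    sen = _check_unit_interval(sen, "sensitivity")
    spe = _check_unit_interval(spe, "specificity")
    target_prevalence = _check_unit_interval(target_prevalence, "target prevalence")
    if target_prevalence in (0.0, 1.0):
        raise UndefinedLimitError(
            f"cannot calibrate {metric!r} to the one-class prevalence "
            f"{target_prevalence:g}; use an interior target"
        )
    cm = from_profile(PerformanceProfile(sen, spe, target_prevalence, 1.0))
    return float(METRICS[metric](cm))


@dataclass(frozen=True)
class SweepCurve:
    """A metric evaluated over a prevalence grid at fixed (Sen, Spe).

    ``grid`` is strictly increasing and confined to the open interval (0, 1):
    the exact endpoints are anchor/limit points, not evaluation points.
    """

    metric: str
    sen: float
    spe: float
    grid: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        grid = tuple(float(g) for g in self.grid)
        values = tuple(float(v) for v in self.values)
        if len(grid) != len(values):
            raise PrevcalError(
                f"grid ({len(grid)}) and values ({len(values)}) must align"
            )
        if len(grid) < 2:
            raise PrevcalError("a sweep curve needs at least two grid points")
        if not all(0.0 < g < 1.0 for g in grid):
            raise PrevcalError("sweep grid points must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise PrevcalError("sweep grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.grid), np.asarray(self.values)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "sen": self.sen,
            "spe": self.spe,
            "grid": list(self.grid),
            "values": list(self.values),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SweepCurve":
        return cls(doc["metric"], doc["sen"], doc["spe"], doc["grid"], doc["values"])


def sweep(
    metric: str,
    sen: float,
    spe: float,
    grid_size: int = DEFAULT_GRID_SIZE,
    endpoints_epsilon: float = DEFAULT_EPSILON,
) -> SweepCurve:
    """Evaluate a catalogue metric on a uniform prevalence grid.

    The grid spans [epsilon, 1 − epsilon] with ``grid_size`` points; an odd
    ``grid_size`` places a point exactly at the balanced prevalence 0.5.
    """
    if not isinstance(grid_size, int) or grid_size < 3:
        raise PrevcalError(f"grid_size must be an integer >= 3, got {grid_size!r}")
    eps = float(endpoints_epsilon)
    if not 0.0 < eps < 0.5:
        raise PrevcalError(f"endpoints_epsilon must lie in (0, 0.5), got {endpoints_epsilon!r}")
    grid = np.linspace(eps, 1.0 - eps, grid_size)
    values = [calibrated_metric(metric, sen, spe, p) for p in grid]
    return SweepCurve(metric, float(sen), float(spe), tuple(grid), tuple(values))
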