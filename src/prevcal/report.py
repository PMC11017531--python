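"""Comparison of validation runs with prevalence-shift aware verdicts.

The variation of sensitivity and specificity between two runs is the
ground truth about relative model performance: both up means the model got
better, both down means worse, opposite directions is a use-case-specific
trade-off.  Every other metric is then checked against that verdict.  When
the two test sets differ in prevalence, prevalence-dependent raw metrics
(accuracy, MCC, PPV, kappa, ...) can move *against* the verdict; the report
flags both the prevalence shift and any such raw-metric contradiction, and
places the balanced (prevalence-0.5-calibrated) value of every catalogue
metric alongside the raw one so the comparison can be read correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calibration import calibrated_metric
from .core import (
    UNDEFINED,
    ConfusionMatrix,
    Stat,
    is_undefined,
    prevalence,
    sensitivity,
    specificity,
)
from .exceptions import PrevcalError
from .metrics import METRICS
from .scenarios import Scenario

__all__ = [
    "ValidationRun",
    "MetricComparison",
    "ComparisonReport",
    "compare",
    "compare_many",
    "runs_from_scenario",
    "coverage",
    "FLAG_PREVALENCE_SHIFT",
    "FLAG_RAW_CONTRADICTION",
]

FLAG_PREVALENCE_SHIFT = "prevalence_shift"
FLAG_RAW_CONTRADICTION = "raw_metric_contradiction"

#: |delta| below this counts as "constant" — floating noise must not create verdicts.
DEFAULT_VARIATION_TOLERANCE = 1e-9
#: |delta prevalence| above this raises the prevalence_shift flag.
DEFAULT_SHIFT_THRESHOLD = 0.02

_ARROWS = {"increase": "↑", "decrease": "↓", "constant": "=", "undefined": "?"}


@dataclass(frozen=True)
class ValidationRun:
    """A labelled confusion matrix with optional provenance."""

    label: str
    matrix: ConfusionMatrix
    source: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise PrevcalError("validation run label must be non-empty")


@dataclass(frozen=True)
class MetricComparison:
    """One metric row of a report: values per run plus the variation direction."""

    metric: str
    kind: str  # "statistic" | "raw" | "balanced"
    values: tuple[Stat, ...]
    variation: str  # "increase" | "decrease" | "constant" | "undefined"


@dataclass(frozen=True)
class ComparisonReport:
    """Raw and balanced metric values for two runs, with verdict and flags.

    ``verdict`` is ``better``/``worse`` when both sensitivity and
    specificity move in that direction, ``trade_off`` otherwise, and None
    when either statistic is undefined in either run.
    """

    runs: tuple[ValidationRun, ...]
    metrics: tuple[MetricComparison, ...]
    verdict: str | None
    flags: tuple[str, ...]
    reference_prevalence: float = 0.5
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD
    variation_tolerance: float = DEFAULT_VARIATION_TOLERANCE

    def row(self, metric: str, kind: str) -> MetricComparison:
        for entry in self.metrics:
            if entry.metric == metric and entry.kind == kind:
                return entry
        raise PrevcalError(f"no {kind} row for metric {metric!r} in report")

    def to_dict(self) -> dict:
        return {
            "runs": [
                {
                    "label": run.label,
                    "source": run.source,
                    "matrix": {
                        "tp": run.matrix.tp,
                        "fn": run.matrix.fn,
                        "fp": run.matrix.fp,
                        "tn": run.matrix.tn,
                    },
                }
                for run in self.runs
            ],
            "metrics": [
                {
                    "metric": entry.metric,
                    "kind": entry.kind,
                    "values": [
                        None if is_undefined(v) else float(v) for v in entry.values
                    ],
                    "variation": entry.variation,
                }
                for entry in self.metrics
            ],
            "verdict": self.verdict,
            "flags": list(self.flags),
            "config": {
                "reference_prevalence": self.reference_prevalence,
                "shift_threshold": self.shift_threshold,
                "variation_tolerance": self.variation_tolerance,
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ComparisonReport":
        runs = tuple(
            ValidationRun(
                entry["label"],
                ConfusionMatrix(**entry["matrix"]),
                entry.get("source", ""),
            )
            for entry in doc["runs"]
        )
        metrics = tuple(
            MetricComparison(
                entry["metric"],
                entry["kind"],
                tuple(UNDEFINED if v is None else float(v) for v in entry["values"]),
                entry["variation"],
            )
            for entry in doc["metrics"]
        )
        config = doc.get("config", {})
        return cls(
            runs,
            metrics,
            doc["verdict"],
            tuple(doc["flags"]),
            reference_prevalence=config.get("reference_prevalence", 0.5),
            shift_threshold=config.get("shift_threshold", DEFAULT_SHIFT_THRESHOLD),
            variation_tolerance=config.get(
                "variation_tolerance", DEFAULT_VARIATION_TOLERANCE
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per (metric, kind), one column per run."""
        records = []
        for entry in self.metrics:
            record = {"metric": entry.metric, "kind": entry.kind}
            for run, value in zip(self.runs, entry.values):
                record[run.label] = None if is_undefined(value) else float(value)
            record["variation"] = entry.variation
            records.append(record)
        return pd.DataFrame.from_records(records)

    def format_table(self, precision: int = 3) -> str:
        """Human-readable table with variation arrows, values rounded for display."""
        frame = self.to_frame()
        run_labels = [run.label for run in self.runs]
        lines = []
        header = f"{'metric':<20}{'kind':<11}" + "".join(
            f"{label:>12}" for label in run_labels
        ) + f"{'var':>6}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, row in frame.iterrows():
            cells = "".join(
                f"{'undef' if row[label] is None else format(row[label], f'.{precision}f'):>12}"
                for label in run_labels
            )
            lines.append(
                f"{row['metric']:<20}{row['kind']:<11}{cells}"
                f"{_ARROWS[row['variation']]:>6}"
            )
        verdict = self.verdict if self.verdict is not None else "undefined"
        lines.append(f"verdict: {verdict}")
        lines.append(f"flags: {', '.join(self.flags) if self.flags else '(none)'}")
        return "\n".join(lines)


def _classify(delta: float, tolerance: float) -> str:
    if abs(delta) < tolerance:
        return "constant"
    return "increase" if delta > 0 else "decrease"


def _variation(values: Sequence[Stat], tolerance: float) -> str:
    if any(is_undefined(v) for v in values):
        return "undefined"
    return _classify(float(values[-1]) - float(values[0]), tolerance)


def compare(
    run_a: ValidationRun,
    run_b: ValidationRun,
    *,
    reference_prevalence: float = 0.5,
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
    variation_tolerance: float = DEFAULT_VARIATION_TOLERANCE,
) -> ComparisonReport:
    """Compare two validation runs (second relative to first).

    The report lists sensitivity/specificity/prevalence, the raw value of
    every catalogue metric, and its value calibrated to
    ``reference_prevalence`` (0.5 = balanced).  Flags: ``prevalence_shift``
    when |ΔPre| exceeds ``shift_threshold``; ``raw_metric_contradiction``
    when a raw metric's direction opposes the sensitivity/specificity
    verdict.
    """
    if run_a.label == run_b.label:
        raise PrevcalError(f"run labels must be unique, both are {run_a.label!r}")
    runs = (run_a, run_b)
    matrices = [run.matrix for run in runs]
    sens = [sensitivity(cm) for cm in matrices]
    spes = [specificity(cm) for cm in matrices]
    pres = [prevalence(cm) for cm in matrices]

    entries: list[MetricComparison] = []
    for name, values in (
        ("sensitivity", sens),
        ("specificity", spes),
        ("prevalence", pres),
    ):
        entries.append(
            MetricComparison(
                name, "statistic", tuple(values), _variation(values, variation_tolerance)
            )
        )

    for name, fn in METRICS.items():
        raw = [fn(cm).value for cm in matrices]
        entries.append(
            MetricComparison(name, "raw", tuple(raw), _variation(raw, variation_tolerance))
        )
    for name in METRICS:
        balanced: list[Stat] = []
        for sen, spe in zip(sens, spes):
            if is_undefined(sen) or is_undefined(spe):
                balanced.append(UNDEFINED)
            else:
                balanced.append(
                    calibrated_metric(name, float(sen), float(spe), reference_prevalence)
                )
        entries.append(
            MetricComparison(
                name, "balanced", tuple(balanced), _variation(balanced, variation_tolerance)
            )
        )

    sen_var = _variation(sens, variation_tolerance)
    spe_var = _variation(spes, variation_tolerance)
    verdict: str | None
    if "undefined" in (sen_var, spe_var):
        verdict = None
    elif sen_var == "increase" and spe_var == "increase":
        verdict = "better"
    elif sen_var == "decrease" and spe_var == "decrease":
        verdict = "worse"
    else:
        verdict = "trade_off"

    flags: list[str] = []
    if abs(pres[1] - pres[0]) > shift_threshold:
        flags.append(FLAG_PREVALENCE_SHIFT)
    if verdict in ("better", "worse"):
        opposite = "decrease" if verdict == "better" else "increase"
        if any(
            entry.variation == opposite
            for entry in entries
            if entry.kind == "raw"
        ):
            flags.append(FLAG_RAW_CONTRADICTION)

    return ComparisonReport(
        runs,
        tuple(entries),
        verdict,
        tuple(flags),
        reference_prevalence=reference_prevalence,
        shift_threshold=shift_threshold,
        variation_tolerance=variation_tolerance,
    )


def compare_many(runs: Sequence[ValidationRun], **config) -> list[ComparisonReport]:
    """Compare three or more runs pairwise against the first."""
    if len(runs) < 2:
        raise PrevcalError("need at least two runs to compare")
    labels = [run.label for run in runs]
    if len(set(labels)) != len(labels):
        raise PrevcalError(f"run labels must be unique, got {labels}")
    return [compare(runs[0], other, **config) for other in runs[1:]]


def runs_from_scenario(scenario: Scenario) -> list[ValidationRun]:
    """Materialise a scenario's profiles into exact (fractional-free) runs."""
    from .core import from_profile

    return [
        ValidationRun(label, from_profile(profile), source=f"scenario:{scenario.name}")
        for label, profile in scenario.runs
    ]


def coverage(full_n: float, in_domain_n: float) -> float:
    """Fraction of the full test set the model predicts after AD filtering."""
    if full_n <= 0:
        raise PrevcalError(f"full_n must be positive, got {full_n!r}")
    if not 0 <= in_domain_n <= full_n:
        raise PrevcalError(
            f"in_domain_n must lie in [0, full_n={full_n!r}], got {in_domain_n!r}"
        )
    return in_domain_n / full_n
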