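"""Synthetic validation scenarios and random-profile generation.

Four packaged scenarios reproduce the classic ways a prevalence shift
sneaks into QSAR model validation:

``same_prevalence``
    Internal vs external validation at identical prevalence 0.900
    (N = 2000 vs 1000).  Every metric moves with sensitivity/specificity;
    the baseline, no-surprise case.
``shifted_prevalence``
    The same internal run, but the external set's prevalence drops from
    0.900 to 0.600.  Sensitivity and specificity both fall, yet raw MCC,
    accuracy, PPV and kappa all *rise* — the misleading comparison that
    balanced metrics correct.
``ad_split``
    Applicability-domain filtering: full test set (N = 2000, Pre = 0.600,
    Sen = 0.680, Spe = 0.850) vs the in-domain half (N = 1000, Pre = 0.900,
    Sen = 0.710, Spe = 0.890).  Coverage drops to 50 %, sen/spe improve,
    raw MCC paradoxically falls 0.520 → 0.377 while balanced MCC rises
    0.538 → 0.610.
``stream_drift``
    A non-stationary data stream: ten windows of 500 instances with
    prevalence drifting linearly 0.3 → 0.9 at fixed Sen = 0.75,
    Spe = 0.85.  Raw accuracy drifts monotonically; balanced accuracy is
    flat.  (Illustrative parameterisation; see the methods note.)

The first three use profiles whose derived-matrix cells are exact
integers; the drift windows are integer-realised by largest-remainder
rounding.  :func:`realise_labels` turns any profile into shuffled
(actual, predicted) label arrays that tabulate back to the same matrix,
and :func:`random_profile` supports property-based testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PerformanceProfile, from_profile
from .exceptions import PrevcalError

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "paper_scenario",
    "realise_labels",
    "random_profile",
    "largest_remainder_round",
]

SCENARIO_NAMES = ("same_prevalence", "shifted_prevalence", "ad_split", "stream_drift")

# flags (mirroring prevcal.report) a scenario's comparison must raise
FLAG_PREVALENCE_SHIFT = "prevalence_shift"
FLAG_RAW_CONTRADICTION = "raw_metric_contradiction"


@dataclass(frozen=True)
class Scenario:
    """A named list of validation runs plus the report flags it must trigger."""

    name: str
    runs: tuple[tuple[str, PerformanceProfile], ...]
    expected_flags: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.runs:
            raise PrevcalError("a scenario needs at least one run")
        labels = [label for label, _ in self.runs]
        if len(set(labels)) != len(labels):
            raise PrevcalError(f"scenario run labels must be unique, got {labels}")


def _profile(sen: float, spe: float, pre: float, n: int) -> PerformanceProfile:
    return PerformanceProfile(sen, spe, pre, n)


def paper_scenario(name: str) -> Scenario:
    """Return one of the four packaged synthetic scenarios by name."""
    if name == "same_prevalence":
        return Scenario(
            name,
            (
                ("internal", _profile(0.710, 0.890, 0.900, 2000)),
                ("external", _profile(0.680, 0.850, 0.900, 1000)),
            ),
            expected_flags=(),
            description=(
                "Internal vs external validation at identical prevalence: every "
                "metric varies in the same direction as sensitivity/specificity."
            ),
        )
    if name == "shifted_prevalence":
        return Scenario(
            name,
            (
                ("internal", _profile(0.710, 0.890, 0.900, 2000)),
                ("external", _profile(0.680, 0.850, 0.600, 1000)),
            ),
            expected_flags=(FLAG_PREVALENCE_SHIFT, FLAG_RAW_CONTRADICTION),
            description=(
                "External prevalence drops 0.900 -> 0.600: sensitivity and "
                "specificity both fall yet raw MCC/accuracy/PPV/kappa rise."
            ),
        )
    if name == "ad_split":
        return Scenario(
            name,
            (
                ("full", _profile(0.680, 0.850, 0.600, 2000)),
                ("in_domain", _profile(0.710, 0.890, 0.900, 1000)),
            ),
            expected_flags=(FLAG_PREVALENCE_SHIFT, FLAG_RAW_CONTRADICTION),
            description=(
                "Applicability-domain filtering halves coverage and shifts "
                "prevalence 0.600 -> 0.900: raw MCC falls 0.520 -> 0.377 while "
                "balanced MCC rises 0.538 -> 0.610."
            ),
        )
    if name == "stream_drift":
        prevalences = np.linspace(0.3, 0.9, 10)
        runs = tuple(
            (f"window_{i + 1:02d}", _profile(0.75, 0.85, float(p), 500))
            for i, p in enumerate(prevalences)
        )
        return Scenario(
            name,
            runs,
            expected_flags=(FLAG_PREVALENCE_SHIFT,),
            description=(
                "Ten stream windows with prevalence drifting 0.3 -> 0.9 at fixed "
                "sen/spe: raw accuracy drifts monotonically, balanced accuracy is "
                "constant. Windows are integer-realised by largest-remainder "
                "rounding."
            ),
        )
    raise PrevcalError(f"unknown scenario {name!r}; choose one of {', '.join(SCENARIO_NAMES)}")


def largest_remainder_round(cells: Sequence[float], total: int) -> tuple[int, ...]:
    """Round non-negative cells to integers summing exactly to ``total``.

    Each cell is floored and the remaining units are given to the largest
    fractional parts (ties broken by cell order) — the standard
    largest-remainder apportionment.
    """
    cells = [float(c) for c in cells]
    if any(c < 0 for c in cells):
        raise PrevcalError("cells must be non-negative")
    floors = [math.floor(c) for c in cells]
    missing = total - sum(floors)
    if missing < 0 or missing > len(cells):
        raise PrevcalError(
            f"cells sum {sum(cells)!r} is inconsistent with requested total {total}"
        )
    order = sorted(range(len(cells)), key=lambda i: (floors[i] - cells[i], i))
    for i in order[:missing]:
        floors[i] += 1
    return tuple(floors)


def realise_labels(
    profile: PerformanceProfile, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Materialise a profile as shuffled (actual, predicted) 0/1 label arrays.

    The derived-matrix cells are integer-realised by largest-remainder
    rounding (exact for integer-consistent profiles), expanded into label
    pairs and deterministically shuffled with ``seed``.  Tabulating the
    output with :func:`~prevcal.core.from_labels` (positive label 1)
    reproduces the rounded matrix exactly.
    """
    total = int(round(profile.n))
    if total <= 0:
        raise PrevcalError("profile n must round to a positive integer")
    cm = from_profile(PerformanceProfile(profile.sen, profile.spe, profile.pre, total))
    tp, fn, fp, tn = largest_remainder_round(cm.counts(), total)
    actual = np.concatenate(
        [np.ones(tp + fn, dtype=np.int64), np.zeros(fp + tn, dtype=np.int64)]
    )
    predicted = np.concatenate(
        [
            np.ones(tp, dtype=np.int64),
            np.zeros(fn, dtype=np.int64),
            np.ones(fp, dtype=np.int64),
            np.zeros(tn, dtype=np.int64),
        ]
    )
    perm = np.random.default_rng(seed).permutation(total)
    return actual[perm], predicted[perm]


def random_profile(
    rng_seed: int | np.random.Generator,
    *,
    sen_bounds: tuple[float, float] = (0.0, 1.0),
    spe_bounds: tuple[float, float] = (0.0, 1.0),
    pre_bounds: tuple[float, float] = (0.0, 1.0),
    n_bounds: tuple[int, int] = (10, 10**6),
) -> PerformanceProfile:
    """Draw a uniformly random valid profile, reproducibly from ``rng_seed``.

    Bounds must be non-empty sub-intervals of [0, 1] (and positive integers
    for ``n_bounds``).  Passing a :class:`numpy.random.Generator` lets
    callers draw streams of profiles.
    """
    for name, (lo, hi) in (
        ("sen_bounds", sen_bounds),
        ("spe_bounds", spe_bounds),
        ("pre_bounds", pre_bounds),
    ):
        if not (0.0 <= lo <= hi <= 1.0):
            raise PrevcalError(f"{name} must be a non-empty sub-interval of [0, 1], got {(lo, hi)}")
    n_lo, n_hi = n_bounds
    if not (0 < n_lo <= n_hi):
        raise PrevcalError(f"n_bounds must be a non-empty positive interval, got {n_bounds}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sen = float(rng.uniform(*sen_bounds))
    spe = float(rng.uniform(*spe_bounds))
    pre = float(rng.uniform(*pre_bounds))
    n = int(rng.integers(n_lo, n_hi + 1))
    return PerformanceProfile(sen, spe, pre, n)
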