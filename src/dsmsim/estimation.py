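"""Parameter estimation from annotated process observations.

Rework probabilities are built from two observable frequencies per
dependency: *volatility* P_i = N_oc / N_o, the chance that the provider
activity deviates from its protocol-standard execution, and *sensitivity*
P_r = N_ir / N_ic, the chance that such a deviation forces rework of the
consumer.  Their product P_ir = P_i * P_r is the per-dependency rework
probability used in the DSM.  Activity durations observed in annotated
video are condensed into a triangular three-point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .model import TriangularDuration

__all__ = [
    "ObservationCounts",
    "DurationSample",
    "UndefinedEstimateError",
    "estimate_volatility",
    "estimate_sensitivity",
    "rework_probability",
    "combine_rework_probabilities",
    "fit_triangular",
    "aggregate_rework_impact",
]


class UndefinedEstimateError(ValueError):
    """An estimator was asked for a ratio with a zero denominator."""


@dataclass(frozen=True)
class ObservationCounts:
    """Annotation tallies for one dependency (optionally one deviation class).

    ``n_o``  — observations of the provider activity;
    ``n_oc`` — of those, executions deviating from protocol;
    ``n_ic`` — deviant executions considered for the downstream effect;
    ``n_ir`` — of those, executions that caused rework of the consumer.

    ``n_ic`` and ``n_oc`` tally the same deviation class when a single
    class is recorded; they are accepted as independent tallies (a deviant
    execution can be considered against several consumers) and checked for
    consistency only where explicitly linked.
    """

    n_o: int
    n_oc: int
    n_ic: int
    n_ir: int

    def __post_init__(self) -> None:
        if min(self.n_o, self.n_oc, self.n_ic, self.n_ir) < 0:
            raise ValueError("observation counts must be non-negative")
        if self.n_oc > self.n_o:
            raise ValueError(
                f"n_oc ({self.n_oc}) cannot exceed n_o ({self.n_o})"
            )
        if self.n_ir > self.n_ic:
            raise ValueError(
                f"n_ir ({self.n_ir}) cannot exceed n_ic ({self.n_ic})"
            )


@dataclass(frozen=True)
class DurationSample:
    """Observed execution durations (minutes) for one activity."""

    activity_id: str
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.durations) == 0:
            raise ValueError(f"activity {self.activity_id!r}: empty duration sample")
        if any(d < 0 for d in self.durations):
            raise ValueError(
                f"activity {self.activity_id!r}: negative duration observed"
            )
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))


def estimate_volatility(counts: ObservationCounts) -> float:
    """Volatility P_i = N_oc / N_o: how often the provider deviates."""
    if counts.n_o == 0:
        raise UndefinedEstimateError("volatility undefined: no observations (n_o = 0)")
    return counts.n_oc / counts.n_o


def estimate_sensitivity(counts: ObservationCounts) -> float:
    """Sensitivity P_r = N_ir / N_ic: how often a deviation causes rework."""
    if counts.n_ic == 0:
        raise UndefinedEstimateError(
            "sensitivity undefined: no deviant executions considered (n_ic = 0)"
        )
    return counts.n_ir / counts.n_ic


def rework_probability(p_i: float, p_r: float) -> float:
    """Per-dependency rework probability P_ir = P_i * P_r."""
    for name, p in (("volatility", p_i), ("sensitivity", p_r)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} {p} outside [0, 1]")
    return p_i * p_r


def combine_rework_probabilities(per_class: Iterable[float]) -> float:
    """Combine per-deviation-class rework probabilities.

    Distinct deviation classes can have different sensitivities; the
    dependency triggers rework if *at least one* class does, so the
    combined probability is 1 - prod(1 - P_ir,class).  A single class
    passes through unchanged.
    """
    ps = list(per_class)
    if not ps:
        raise ValueError("no per-class probabilities to combine")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"rework probability {p} outside [0, 1]")
    if len(ps) == 1:
        return ps[0]
    return 1.0 - float(np.prod([1.0 - p for p in ps]))


def _half_sample_mode(sorted_x: np.ndarray) -> float:
    # Robertson-Cryer half-sample mode: recursively keep the half-width
    # window containing the most points (smallest range over ceil(n/2)
    # consecutive order statistics) until <= 2 points remain.
    x = sorted_x
    while x.size > 2:
        h = (x.size + 1) // 2
        widths = x[h - 1 :] - x[: x.size - h + 1]
        k = int(np.argmin(widths))  # argmin = leftmost on ties
        x = x[k : k + h]
    return float(x.mean())


def fit_triangular(
    sample: DurationSample,
    mode_estimator: Literal["auto", "median", "half-sample"] = "auto",
) -> TriangularDuration:
    """Condense observed durations into a triangular three-point estimate.

    ``bcv`` and ``wcv`` are the sample minimum and maximum.  The mode
    (``mlv``) is never directly observable from a handful of annotated
    executions; by default the sample median is used for n <= 5 and a
    half-sample mode estimator for larger samples — both robust choices
    for the small-sample, high-variation regime of annotated surgical
    video.  The estimate is clamped to [min, max].
    """
    x = np.sort(np.asarray(sample.durations, dtype=float))
    bcv, wcv = float(x[0]), float(x[-1])
    if mode_estimator == "auto":
        mode_estimator = "median" if x.size <= 5 else "half-sample"
    if mode_estimator == "median":
        mlv = float(np.median(x))
    elif mode_estimator == "half-sample":
        mlv = _half_sample_mode(x)
    else:
        raise ValueError(f"unknown mode estimator {mode_estimator!r}")
    mlv = min(max(mlv, bcv), wcv)
    return TriangularDuration(bcv, mlv, wcv)


def aggregate_rework_impact(values: Sequence[float]) -> float:
    """Average a range of expert rework-impact assessments into a single RI."""
    if len(values) == 0:
        raise ValueError("no rework-impact assessments given")
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rework impact {v} outside [0, 1]")
    return float(np.mean(values))
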