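"""Latency-based response coding, squared-error scoring, and classification metrics.

The network's answer is read from the timing of the output neuron's spikes:
dt1 is the time from stimulus onset to the first spike and dt2 the interval
between the first and second spikes.  Classification compares a response's
latency pair against the reference code (the mode over positive training
responses) with a squared error

    SE = (dt1 - dt1_mode)^2 + (dt2 - dt2_mode)^2      [ms^2]

and accepts a pattern as positive iff SE <= threshold.  A pattern that evokes
fewer spikes than the code requires yields NO_RESPONSE and is classified
negative: a genuine fusion event must drive the network.

The latency code also bounds the usable sampling rate of the amperometric
signal: the classifier must finish reading one window before the next sample
arrives, so f_max = 1 / (max dt1 + max dt2) over positive responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .neuron import SpikeTrain

__all__ = [
    "ResponseCode",
    "NO_RESPONSE",
    "NoResponse",
    "ScoredResponse",
    "ConfusionCounts",
    "extract_latencies",
    "squared_error",
    "mse",
    "classify",
    "accuracy",
    "max_sampling_frequency",
    "first_spike_classify",
]


class NoResponse:
    """Sentinel: the spike train held too few spikes to form the code."""

    _instance: "NoResponse | None" = None

    def __new__(cls) -> "NoResponse":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_RESPONSE"


NO_RESPONSE = NoResponse()


@dataclass(frozen=True)
class ResponseCode:
    """The latency pair (dt1, dt2) in ms."""

    dt1: float
    dt2: float

    def __post_init__(self) -> None:
        if self.dt1 <= 0 or self.dt2 <= 0:
            raise ValueError(
                f"latencies must be positive, got ({self.dt1}, {self.dt2})"
            )


@dataclass(frozen=True)
class ScoredResponse:
    """One evaluated pattern: its code, SE vs the trained mode, and prediction."""

    code: ResponseCode | NoResponse
    se: float | NoResponse
    predicted: bool


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _round_to_bin(value: float, bin_ms: float) -> float:
    # round-half-up in units of the bin, so 3.5 ms -> 4 ms at bin = 1;
    # sub-bin latencies read as one bin (the code's granularity floor)
    return max(math.floor(value / bin_ms + 0.5), 1) * bin_ms


def extract_latencies(
    train: SpikeTrain, k: int = 2, bin_ms: float = 1.0
) -> tuple[float, ...] | NoResponse:
    """First-k latency code from a spike train, quantized to ``bin_ms``.

    The first latency is onset-to-first-spike; subsequent latencies are the
    interspike intervals.  Fewer than k spikes is a NO_RESPONSE outcome, not
    an error.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if bin_ms <= 0:
        raise ValueError(f"bin_ms must be positive, got {bin_ms}")
    times = train.times
    if times.size < k:
        return NO_RESPONSE
    raw = [times[0]] + [times[j] - times[j - 1] for j in range(1, k)]
    return tuple(_round_to_bin(t, bin_ms) for t in raw)


def squared_error(code: ResponseCode, mode: ResponseCode) -> float:
    """Squared latency-space distance between a response and the mode (ms^2)."""
    return (mode.dt1 - code.dt1) ** 2 + (mode.dt2 - code.dt2) ** 2


def mse(codes: Sequence[ResponseCode], mode: ResponseCode) -> float:
    """Mean squared error of a set of responses against the mode."""
    if len(codes) == 0:
        raise ValueError("mse requires at least one response code")
    return float(np.mean([squared_error(c, mode) for c in codes]))


def classify(se: float | NoResponse, threshold: float) -> bool:
    """Positive iff SE <= threshold; NO_RESPONSE is always negative.

    The comparison is inclusive so that training positives sitting exactly at
    the maximal positive SE are accepted.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    if isinstance(se, NoResponse):
        return False
    return se <= threshold


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + FN + FP + TN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined for an empty evaluation")
    return (c.tp + c.tn) / c.total


def max_sampling_frequency(positive_codes: Sequence[ResponseCode]) -> float:
    """Reciprocal of the summed maximal positive latencies, in Hz."""
    if len(positive_codes) == 0:
        raise ValueError("max_sampling_frequency requires at least one code")
    max_dt1 = max(c.dt1 for c in positive_codes)
    max_dt2 = max(c.dt2 for c in positive_codes)
    return 1000.0 / (max_dt1 + max_dt2)


def first_spike_classify(
    trains: Iterable[SpikeTrain],
    mode_dt1: float,
    threshold: float,
    bin_ms: float = 1.0,
) -> list[bool]:
    """Baseline time-to-first-spike rule: one-component SE on dt1 only."""
    labels = []
    for train in trains:
        code = extract_latencies(train, k=1, bin_ms=bin_ms)
        if isinstance(code, NoResponse):
            labels.append(False)
        else:
            labels.append((code[0] - mode_dt1) ** 2 <= threshold)
    return labels
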