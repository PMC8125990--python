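"""One-pass analytic training: weight mapping, neuron routing, response coding.

There is no gradient descent, no STDP and no epochs.  The whole fit is:

1. Average the positive training patterns sample-wise into AVG (length N).
2. Map input weights analytically:  w1 = delta * (kappa - AVG).
3. Route neurons by weight sign: negative -> inhibition-induced, otherwise
   tonic spiking (a zero weight silences its input and maps to tonic).
4. Assign the shared constants w2 and Cref to the output layer.
5. Run the network once over the training patterns, read each two-latency
   response, and store the per-component mode over positive responses
   (quantized to the latency bin, ties broken toward the earlier latency)
   as the reference code.
6. Set the decision bound to the largest squared error any positive training
   pattern produced against that mode; at evaluation time a pattern is
   positive iff its SE does not exceed the bound.

Each pattern is touched a constant number of times, so training cost is
linear in the data and the only data-dependent parameters are the N input
weights.

delta and kappa are the two learning parameters of the weight rule.  kappa
is an offset on the pA scale of the averaged samples (samples below kappa
get positive weights, samples above get negative ones) and grows with N;
delta is an overall scale and shrinks as 1/N.  ``suggest_delta_kappa``
anchors both at the reference 20-input configuration (delta=1.4, kappa=26)
and clips to the calibrated ranges delta in [0.95, 1.4], kappa in [26, 32].

``input_gain`` — the single coupling factor between the weighted pA-scale
samples and the neurons' dynamic range — is the one quantity with no
analytic rule.  ``calibrate_input_gain`` fixes it with a self-check that
uses positive patterns only: every positive must evoke at least two output
spikes, the positive mode must differ clearly from the network's background
response (the code an all-zero pattern evokes through the inhibition-induced
neurons' intrinsic firing), must sit well off the one-bin saturation floor,
and the positive class should cluster as tightly as possible around its
mode.  Negatives never influence the fitted weights or the calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import Counter
from typing import Sequence

import numpy as np

from .coding import (
    NO_RESPONSE,
    ConfusionCounts,
    NoResponse,
    ResponseCode,
    ScoredResponse,
    classify,
    extract_latencies,
    max_sampling_frequency,
    squared_error,
)
from .neuron import DEFAULT_DT_MS, NeuronKind, NumericalBlowupError
from .network import (
    DEFAULT_DURATION_MS,
    DEFAULT_W2,
    NetworkModel,
    forward_batch,
)
from .synapse import DEFAULT_C_REF

__all__ = [
    "TrainingConfig",
    "PatternSet",
    "CalibrationError",
    "Evaluation",
    "average_pattern",
    "compute_input_weights",
    "map_neurons",
    "suggest_delta_kappa",
    "calibrate_input_gain",
    "fit",
    "evaluate",
]

#: reference configuration the delta/kappa heuristic is anchored to
_ANCHOR_N = 20
_ANCHOR_DELTA = 1.4
_ANCHOR_KAPPA = 26.0
_DELTA_RANGE = (0.95, 1.4)
_KAPPA_RANGE = (26.0, 32.0)
_CALIBRATED_N = (10, 40)


@dataclass(frozen=True)
class TrainingConfig:
    """Learning parameters of the analytic weight rule."""

    delta: float
    kappa: float
    latency_bin: float = 1.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.latency_bin <= 0:
            raise ValueError(f"latency_bin must be positive, got {self.latency_bin}")


@dataclass(frozen=True)
class PatternSet:
    """Labeled current patterns: rows are patterns, columns the N samples (pA).

    Labels mark fusion events (positive) vs everything else; they are used
    only for threshold setting and evaluation, never by the weight mapping.
    """

    patterns: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "patterns", patterns)
        object.__setattr__(self, "labels", labels)
        if patterns.ndim != 2:
            raise ValueError("patterns must form a 2-D matrix")
        if labels.shape != (patterns.shape[0],):
            raise ValueError(
                f"{labels.size} labels for {patterns.shape[0]} patterns"
            )
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0 = negative, 1 = positive)")
        if not np.all(np.isfinite(patterns)):
            raise ValueError("patterns contain non-finite samples")

    @property
    def n_patterns(self) -> int:
        return int(self.patterns.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.patterns.shape[1])

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels == 1

    def positives(self) -> np.ndarray:
        return self.patterns[self.positive_mask]

    def negatives(self) -> np.ndarray:
        return self.patterns[~self.positive_mask]

    def standardized(self) -> "PatternSet":
        """Clip samples at zero (input currents must be non-negative)."""
        return PatternSet(np.maximum(self.patterns, 0.0), self.labels)


class CalibrationError(RuntimeError):
    """Positive training patterns failed to drive the output neuron."""


def average_pattern(ts: PatternSet, subset: np.ndarray | None = None) -> np.ndarray:
    """Sample-wise arithmetic mean over the selected rows."""
    rows = ts.patterns if subset is None else ts.patterns[subset]
    if rows.shape[0] == 0:
        raise ValueError("cannot average an empty pattern subset")
    return rows.mean(axis=0)


def compute_input_weights(avg: np.ndarray, cfg: TrainingConfig) -> np.ndarray:
    """Analytic weight rule: w1(i) = delta * (kappa - avg(i))."""
    avg = np.asarray(avg, dtype=float)
    if not np.all(np.isfinite(avg)):
        raise ValueError("avg contains non-finite values")
    return cfg.delta * (cfg.kappa - avg)


def map_neurons(w1: np.ndarray) -> tuple[NeuronKind, ...]:
    """Strictly negative weight -> inhibition-induced; otherwise tonic spiking."""
    return tuple(
        NeuronKind.INHIBITION_INDUCED if w < 0 else NeuronKind.TONIC_SPIKING
        for w in np.asarray(w1, dtype=float)
    )


def suggest_delta_kappa(n_inputs: int, latency_bin: float = 1.0) -> TrainingConfig:
    """Heuristic delta, kappa for a given network size.

    delta ~ 1/N and kappa ~ N, anchored so N=20 gives (1.4, 26), clipped to
    the calibrated ranges.  Sizes outside 10..40 extrapolate with a warning.
    """
    if n_inputs < 1:
        raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
    if not (_CALIBRATED_N[0] <= n_inputs <= _CALIBRATED_N[1]):
        warnings.warn(
            f"N={n_inputs} is outside the calibrated size range "
            f"{_CALIBRATED_N[0]}..{_CALIBRATED_N[1]}; extrapolating",
            stacklevel=2,
        )
    delta = _ANCHOR_DELTA * _ANCHOR_N / n_inputs
    kappa = _ANCHOR_KAPPA * n_inputs / _ANCHOR_N
    delta = float(np.clip(delta, *_DELTA_RANGE))
    kappa = float(np.clip(kappa, *_KAPPA_RANGE))
    return TrainingConfig(delta=delta, kappa=kappa, latency_bin=latency_bin)


def _component_mode(values: Sequence[float]) -> float:
    """Most frequent value; ties break toward the smaller (earlier) latency."""
    counts = Counter(values)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def _codes_for(
    model: NetworkModel, patterns: np.ndarray, bin_ms: float
) -> list[tuple[float, float] | NoResponse]:
    trains = forward_batch(model, patterns)
    return [extract_latencies(t, k=2, bin_ms=bin_ms) for t in trains]


def _untrained_model(ts, cfg, w2, c_ref, gain, dt, duration, settle,
                     use_all_patterns):
    subset = None if use_all_patterns else ts.positive_mask
    avg = average_pattern(ts, subset)
    w1 = compute_input_weights(avg, cfg)
    return NetworkModel(
        w1=w1, neuron_map=map_neurons(w1), w2=w2, c_ref=c_ref,
        input_gain=float(gain), dt=dt, duration=duration, settle=settle,
    )


def calibrate_input_gain(
    ts: PatternSet,
    cfg: TrainingConfig,
    *,
    w2: float = DEFAULT_W2,
    c_ref: float = DEFAULT_C_REF,
    dt: float = DEFAULT_DT_MS,
    duration: float = DEFAULT_DURATION_MS,
    settle: float = 0.0,
    gain_bounds: tuple[float, float] = (0.004, 64.0),
    gain_step: float = 1.25,
    use_all_patterns: bool = False,
) -> float:
    """Fix the input coupling factor by a positive-pattern self-check.

    A gain is admissible when every positive training pattern elicits at
    least two output spikes within the response window.  Among admissible
    gains on a geometric grid the calibration prefers, in order:

    1. operating points whose positive mode is stimulus-driven — distinct
       from the network's background response (the code evoked by an
       all-zero pattern) and at least five bins off the one-bin saturation
       floor;
    2. the smallest squared-error spread of the positive class around its
       own mode (the quantity the decision threshold is built from);
    3. the largest fraction of positives sitting exactly on the mode;
    4. the larger separation from the background code, then the smallest
       gain.

    Every quantity involved is computed from positive patterns (plus the
    zero pattern); negatives never influence the calibration.
    """
    ts = ts.standardized()
    positives = ts.positives()
    if positives.shape[0] == 0:
        raise ValueError("calibration requires at least one positive pattern")
    bin_ms = cfg.latency_bin

    def probe(gain: float):
        model = _untrained_model(
            ts, cfg, w2, c_ref, gain, dt, duration, settle, use_all_patterns
        )
        try:
            codes = _codes_for(model, positives, bin_ms)
            background = _codes_for(model, np.zeros((1, ts.n_samples)), bin_ms)[0]
        except NumericalBlowupError:
            return None
        if any(isinstance(c, NoResponse) for c in codes):
            return None
        mode = (
            _component_mode([c[0] for c in codes]),
            _component_mode([c[1] for c in codes]),
        )
        spread = max(
            (c[0] - mode[0]) ** 2 + (c[1] - mode[1]) ** 2 for c in codes
        )
        agree = sum(1 for c in codes if c == mode) / len(codes)
        bg_dist = (
            float("inf")
            if isinstance(background, NoResponse)
            else abs(mode[0] - background[0])
        )
        stimulus_driven = bg_dist >= bin_ms and mode[0] >= 5 * bin_ms
        # a mode two or more bins clear of the background outranks a tighter
        # spread at one bin (background-like negatives collide with the mode
        # when only one bin separates them) — but only while the positive
        # class stays coherent; a blown-up spread means part of the class
        # switched response channel and the operating point is unusable
        coherent = spread <= 8.0 * bin_ms * bin_ms
        return (
            not stimulus_driven,
            not coherent,
            -min(bg_dist, 2 * bin_ms) if coherent else 0.0,
            spread,
            -agree,
            gain,
        )

    best: tuple | None = None
    best_gain: float | None = None
    gain = gain_bounds[0]
    while gain <= gain_bounds[1]:
        key = probe(gain)
        if key is not None and (best is None or key < best):
            best = key
            best_gain = gain
        gain *= gain_step
    if best_gain is None:
        raise CalibrationError(
            "no input_gain in "
            f"[{gain_bounds[0]:g}, {gain_bounds[1]:g}] made every positive "
            "training pattern fire >= 2 output spikes; adjust delta/kappa "
            "or the gain bounds"
        )
    return float(best_gain)


def fit(
    ts: PatternSet,
    cfg: TrainingConfig | None = None,
    *,
    w2: float = DEFAULT_W2,
    c_ref: float = DEFAULT_C_REF,
    input_gain: float | None = None,
    dt: float = DEFAULT_DT_MS,
    duration: float = DEFAULT_DURATION_MS,
    settle: float = 0.0,
    use_all_patterns: bool = False,
) -> NetworkModel:
    """One-pass fit: weights, neuron map, reference code and decision bound.

    ``use_all_patterns=True`` averages the whole training set (the strict
    literal reading of the pseudocode) instead of the positive class, and
    likewise computes the response mode over every pattern.
    ``input_gain=None`` triggers automatic calibration.
    """
    if ts.n_patterns == 0:
        raise ValueError("cannot fit an empty pattern set")
    ts = ts.standardized()
    if cfg is None:
        cfg = suggest_delta_kappa(ts.n_samples)

    if input_gain is None:
        input_gain = calibrate_input_gain(
            ts, cfg, w2=w2, c_ref=c_ref, dt=dt, duration=duration,
            settle=settle, use_all_patterns=use_all_patterns,
        )

    model = _untrained_model(
        ts, cfg, w2, c_ref, input_gain, dt, duration, settle, use_all_patterns
    )

    mode_rows = ts.patterns if use_all_patterns else ts.positives()
    codes = _codes_for(model, mode_rows, cfg.latency_bin)
    responding = [c for c in codes if not isinstance(c, NoResponse)]
    if not responding:
        raise CalibrationError(
            "no reference pattern evoked 2 output spikes within "
            f"{duration:g} ms at input_gain={input_gain:g}"
        )
    mode = ResponseCode(
        _component_mode([c[0] for c in responding]),
        _component_mode([c[1] for c in responding]),
    )

    pos_codes = _codes_for(model, ts.positives(), cfg.latency_bin) \
        if use_all_patterns else codes
    bad = sum(1 for c in pos_codes if isinstance(c, NoResponse))
    if bad:
        raise CalibrationError(
            f"{bad} of {len(pos_codes)} positive training patterns evoked "
            f"fewer than 2 output spikes within {duration:g} ms at "
            f"input_gain={input_gain:g}; adjust input_gain, delta or kappa"
        )
    threshold = max(squared_error(ResponseCode(*c), mode) for c in pos_codes)

    return NetworkModel(
        w1=model.w1, neuron_map=model.neuron_map, w2=w2, c_ref=c_ref,
        input_gain=float(input_gain), dt=dt, duration=duration, settle=settle,
        code_mode=mode, se_threshold=float(threshold),
    )


# --- evaluation ------------------------------------------------------------


@dataclass(frozen=True)
class Evaluation:
    """Per-pattern scores plus the aggregate confusion counts and accuracy."""

    scored: tuple[ScoredResponse, ...]
    confusion: ConfusionCounts
    accuracy: float
    max_sampling_hz: float | None
    _labels: tuple[bool, ...] = field(default=(), repr=False)

    @property
    def positive_ses(self) -> list[float]:
        return [
            s.se
            for s, is_pos in zip(self.scored, self._labels)
            if is_pos and not isinstance(s.se, NoResponse)
        ]

    @property
    def negative_ses(self) -> list[float]:
        return [
            s.se
            for s, is_pos in zip(self.scored, self._labels)
            if not is_pos and not isinstance(s.se, NoResponse)
        ]


def evaluate(
    model: NetworkModel, ts: PatternSet, bin_ms: float = 1.0
) -> Evaluation:
    """Classify a labeled set with a trained model and tally the confusion.

    The maximal-sampling-rate figure is derived from the latency codes of the
    true-positive patterns that produced a response.
    """
    if not model.is_trained:
        raise ValueError("evaluate requires a trained model (code_mode set)")
    ts = ts.standardized()
    if ts.n_patterns == 0:
        raise ValueError("cannot evaluate an empty pattern set")

    trains = forward_batch(model, ts.patterns)
    scored: list[ScoredResponse] = []
    tp = tn = fp = fn = 0
    pos_codes: list[ResponseCode] = []
    for train, label in zip(trains, ts.labels):
        raw = extract_latencies(train, k=2, bin_ms=bin_ms)
        if isinstance(raw, NoResponse):
            code: ResponseCode | NoResponse = NO_RESPONSE
            se: float | NoResponse = NO_RESPONSE
            predicted = False
        else:
            code = ResponseCode(*raw)
            se = squared_error(code, model.code_mode)
            predicted = classify(se, model.se_threshold)
            if label == 1:
                pos_codes.append(code)
        scored.append(ScoredResponse(code=code, se=se, predicted=predicted))
        if label == 1:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted

    confusion = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    acc = (tp + tn) / confusion.total
    fmax = max_sampling_frequency(pos_codes) if pos_codes else None
    return Evaluation(
        scored=tuple(scored),
        confusion=confusion,
        accuracy=acc,
        max_sampling_hz=fmax,
        _labels=tuple(bool(x) for x in ts.labels),
    )
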