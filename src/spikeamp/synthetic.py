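"""Synthetic amperometric pattern sets for training and benchmarks.

Amperometric recordings of exocytosis show, per vesicle-fusion event, a
transient current: a low baseline of a few pA, a fast rise to a peak of
several tens of pA, then a roughly exponential decay back to baseline, all
below the ~100 pA ceiling of the technique.  The generator emits such
positive patterns plus five families of negative (non-fusion) waveforms in
the same amplitude range — flat noise, slow drift, double-bump transients,
truncated rises and late peaks — so the two classes overlap in amplitude and
must be separated by shape.

A pattern set models one recording: the shape parameters (baseline level,
peak amplitude, peak position, decay constant, noise level) are drawn once
per set from their configured ranges, the way a single electrode and cell
fix them in practice; individual events then vary by a ~10% relative jitter
plus additive sample noise.  Negatives generated alongside positives share
the recording-level amplitude draw, keeping the two classes matched in
scale.  Every stochastic draw flows through a seeded generator, so a given
seed reproduces a pattern set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .training import PatternSet

__all__ = [
    "FusionShapeParams",
    "NegativeStyle",
    "make_positive",
    "make_negative",
    "make_benchmark",
    "BENCHMARK_SIZES",
]

#: the architecture sweep the benchmark mirrors: 10-1 .. 40-1
BENCHMARK_SIZES = (10, 15, 20, 25, 30, 35, 40)

#: amperometric ceiling (pA): generated samples never exceed it
MAX_CURRENT_PA = 100.0

#: event-to-event relative jitter of amplitudes within one recording
EVENT_JITTER = 0.10


@dataclass(frozen=True)
class FusionShapeParams:
    """Shape family of a single vesicle-fusion transient.

    Ranged fields are (low, high) bounds for the recording-level draw.
    ``decay_tau`` is expressed as a fraction of the window length, so shapes
    are self-similar across sampling sizes N.
    """

    n_samples: int = 20
    peak_amplitude: tuple[float, float] = (30.0, 70.0)
    baseline: tuple[float, float] = (2.0, 8.0)
    rise_fraction: tuple[float, float] = (0.2, 0.35)
    decay_tau: tuple[float, float] = (0.10, 0.20)
    noise_sd: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        for name in ("peak_amplitude", "baseline", "rise_fraction",
                     "decay_tau", "noise_sd"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is inverted")
            if lo < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.rise_fraction[0] and self.rise_fraction[1] < 1.0):
            raise ValueError("rise_fraction must lie strictly inside (0, 1)")


class NegativeStyle(str, Enum):
    FLAT_NOISE = "flat_noise"
    SLOW_DRIFT = "slow_drift"
    DOUBLE_BUMP = "double_bump"
    TRUNCATED_RISE = "truncated_rise"
    LATE_PEAK = "late_peak"


@dataclass(frozen=True)
class _Recording:
    """One recording-level draw of the shape parameters."""

    baseline: float
    peak: float
    rise_fraction: float
    decay_tau: float
    noise_sd: float


def _draw_recording(params: FusionShapeParams, rng: np.random.Generator) -> _Recording:
    def u(bounds):
        lo, hi = bounds
        return lo if lo == hi else float(rng.uniform(lo, hi))

    return _Recording(
        baseline=u(params.baseline),
        peak=u(params.peak_amplitude),
        rise_fraction=u(params.rise_fraction),
        decay_tau=u(params.decay_tau),
        noise_sd=u(params.noise_sd),
    )


def _jitter(rec: _Recording, rng: np.random.Generator) -> _Recording:
    """Per-event variation around the recording-level parameters."""
    j = lambda x: x * (1.0 + rng.uniform(-EVENT_JITTER, EVENT_JITTER))
    rise = rec.rise_fraction + rng.uniform(-0.02, 0.02)
    return _Recording(
        baseline=j(rec.baseline),
        peak=j(rec.peak),
        rise_fraction=float(np.clip(rise, 0.05, 0.95)),
        decay_tau=j(rec.decay_tau),
        noise_sd=rec.noise_sd,
    )


def _fusion_template(n: int, ev: _Recording) -> np.ndarray:
    """Noiseless fusion shape: baseline, short linear rise, exponential decay."""
    x = np.full(n, ev.baseline)
    peak_idx = int(round(ev.rise_fraction * n))
    peak_idx = min(max(peak_idx, 1), n - 1)
    rise_len = max(1, int(round(0.1 * n)))
    start = max(0, peak_idx - rise_len)
    x[start : peak_idx + 1] = np.linspace(ev.baseline, ev.peak, peak_idx - start + 1)
    tau = max(ev.decay_tau * n, 1e-6)
    k = np.arange(peak_idx + 1, n)
    x[peak_idx + 1 :] = ev.baseline + (ev.peak - ev.baseline) * np.exp(
        -(k - peak_idx) / tau
    )
    return x


def _finalize(x: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    return np.clip(x, 0.0, MAX_CURRENT_PA)


def make_positive(
    params: FusionShapeParams,
    count: int,
    rng: np.random.Generator | None = None,
    recording: _Recording | None = None,
) -> PatternSet:
    """Generate ``count`` single-fusion transients, all labeled positive."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if recording is None:
        recording = _draw_recording(params, rng)
    n = params.n_samples
    rows = np.empty((count, n))
    for i in range(count):
        ev = _jitter(recording, rng)
        rows[i] = _finalize(_fusion_template(n, ev), ev.noise_sd, rng)
    return PatternSet(rows, np.ones(count, dtype=int))


def _negative_template(
    style: NegativeStyle, n: int, ev: _Recording
) -> np.ndarray:
    if style == NegativeStyle.FLAT_NOISE:
        return np.full(n, ev.baseline)
    if style == NegativeStyle.SLOW_DRIFT:
        # monotone ramp spanning the full window — no sharp transient
        return np.linspace(ev.baseline, ev.peak, n)
    if style == NegativeStyle.DOUBLE_BUMP:
        # two flicker/partial-fusion transients: full-height but brief spikes
        # lacking the slow decay tail that carries a real fusion's charge
        idx = np.arange(n, dtype=float)
        c1 = ev.rise_fraction * n
        c2 = min(n - 1.5, c1 + 0.4 * n)
        width = 0.45
        bumps = (ev.peak - ev.baseline) * np.exp(-0.5 * ((idx - c1) / width) ** 2)
        bumps += 0.8 * (ev.peak - ev.baseline) * np.exp(
            -0.5 * ((idx - c2) / width) ** 2
        )
        return ev.baseline + bumps
    if style == NegativeStyle.TRUNCATED_RISE:
        # rises like a fusion but never decays: plateau at the peak
        x = _fusion_template(n, ev)
        x[int(np.argmax(x)) :] = ev.peak
        return x
    if style == NegativeStyle.LATE_PEAK:
        late = min(0.85, ev.rise_fraction + 0.45)
        shifted = _Recording(ev.baseline, ev.peak, late, ev.decay_tau, ev.noise_sd)
        return _fusion_template(n, shifted)
    raise ValueError(f"unknown negative style {style!r}")


def make_negative(
    params: FusionShapeParams,
    styles: Sequence[NegativeStyle] = tuple(NegativeStyle),
    count: int = 40,
    rng: np.random.Generator | None = None,
    recording: _Recording | None = None,
) -> PatternSet:
    """Generate non-fusion waveforms, cycling through the requested styles."""
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    styles = tuple(styles)
    if not styles:
        raise ValueError("at least one negative style is required")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if recording is None:
        recording = _draw_recording(params, rng)
    n = params.n_samples
    rows = np.empty((count, n))
    for i in range(count):
        ev = _jitter(recording, rng)
        rows[i] = _finalize(
            _negative_template(styles[i % len(styles)], n, ev), ev.noise_sd, rng
        )
    return PatternSet(rows, np.zeros(count, dtype=int))


def make_benchmark(
    n_samples: int,
    n_pos: int = 40,
    n_neg: int = 40,
    seed: int = 0,
    shape: FusionShapeParams | None = None,
    styles: Sequence[NegativeStyle] = tuple(NegativeStyle),
) -> PatternSet:
    """The 40+40 benchmark design: stratified, shuffled, labeled.

    Positives and negatives share one recording-level parameter draw, so the
    classes are amplitude-matched and differ in shape only.  ``n_samples``
    outside the 10..40 architecture sweep is allowed but the benchmark
    mirrors the studied sizes {10, 15, 20, 25, 30, 35, 40}.
    """
    if shape is None:
        shape = FusionShapeParams(n_samples=n_samples, seed=seed)
    elif shape.n_samples != n_samples:
        raise ValueError(
            f"shape.n_samples={shape.n_samples} conflicts with n_samples={n_samples}"
        )
    rng = np.random.default_rng(seed)
    recording = _draw_recording(shape, rng)
    pos = make_positive(shape, n_pos, rng=rng, recording=recording)
    neg = make_negative(shape, styles, n_neg, rng=rng, recording=recording)
    patterns = np.vstack([pos.patterns, neg.patterns])
    labels = np.concatenate([pos.labels, neg.labels])
    order = rng.permutation(patterns.shape[0])
    return PatternSet(patterns[order], labels[order])
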