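"""Weight-mismatch robustness: accuracy vs percentage perturbation of weights.

Semiconductor fabrication perturbs transistor threshold voltages and hence
the current-mirror scaling factors that realize synaptic weights.  The sweep
emulates this by scaling every input weight w1(i) and the shared output
weight w2 by a random factor per draw and re-evaluating the frozen
classifier (the trained reference code, decision threshold and neuron map
are never refit — fabricated hardware keeps its routing).

Two perturbation modes:

* SYSTEMATIC (default): gate-oxide variation has a gradient character and is
  alike for devices in the same substrate area, so each weight is scaled by
  (1 + u * percent/100) with u ~ Uniform(0, 1) — every deviation shares the
  sign of the stated percentage.
* INDEPENDENT: each weight is scaled by (1 + x) with
  x ~ Uniform(-1, 1) * |percent|/100, for sensitivity checks with
  sign-symmetric dispersion.

Synapse capacitances are left untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .network import NetworkModel
from .training import Evaluation, PatternSet, evaluate

__all__ = [
    "MismatchMode",
    "MismatchSweepConfig",
    "MismatchResult",
    "perturb_weights",
    "run_sweep",
]

DEFAULT_PERCENT_GRID = (-30, -25, -20, -15, -10, -5, 0, 5, 10)


class MismatchMode(str, Enum):
    SYSTEMATIC = "systematic"
    INDEPENDENT = "independent"


@dataclass(frozen=True)
class MismatchSweepConfig:
    percent_grid: tuple[float, ...] = DEFAULT_PERCENT_GRID
    samples_per_point: int = 50
    seed: int = 0
    mode: MismatchMode = MismatchMode.SYSTEMATIC
    #: optional fabrication countermeasure: pre-scale all weights by this
    #: factor before perturbing (e.g. 0.9 for the suggested -10% correction)
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.samples_per_point < 1:
            raise ValueError("samples_per_point must be >= 1")
        if self.correction_factor <= 0:
            raise ValueError("correction_factor must be positive")


@dataclass(frozen=True)
class MismatchResult:
    percent: float
    mean_acc: float
    min_acc: float
    max_acc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_acc <= self.mean_acc <= self.max_acc <= 1.0):
            raise ValueError("accuracy summary must satisfy 0 <= min <= mean <= max <= 1")


def perturb_weights(
    model: NetworkModel,
    percent: float,
    rng: np.random.Generator,
    mode: MismatchMode = MismatchMode.SYSTEMATIC,
) -> NetworkModel:
    """One random fabrication draw: scaled w1 and w2, frozen everything else."""
    if not model.is_trained:
        raise ValueError("perturb_weights requires a trained model")
    if percent == 0:
        return model
    n = model.n_inputs + 1  # all input weights plus the shared w2
    if mode == MismatchMode.SYSTEMATIC:
        factors = 1.0 + rng.uniform(0.0, 1.0, size=n) * (percent / 100.0)
    else:
        factors = 1.0 + rng.uniform(-1.0, 1.0, size=n) * (abs(percent) / 100.0)
    return model.with_weights(
        w1=model.w1 * factors[:-1], w2=model.w2 * factors[-1]
    )


def run_sweep(
    model: NetworkModel,
    eval_set: PatternSet,
    cfg: MismatchSweepConfig,
) -> list[MismatchResult]:
    """Monte-Carlo accuracy sweep over the percentage grid.

    Each grid point draws ``samples_per_point`` perturbed copies of the
    (optionally pre-corrected) model and evaluates them against the frozen
    trained code and threshold.
    """
    if not model.is_trained:
        raise ValueError("run_sweep requires a trained model")
    base = model
    if cfg.correction_factor != 1.0:
        base = model.with_weights(
            w1=model.w1 * cfg.correction_factor,
            w2=model.w2 * cfg.correction_factor,
        )
    rng = np.random.default_rng(cfg.seed)
    results = []
    for percent in cfg.percent_grid:
        accs = np.empty(cfg.samples_per_point)
        for j in range(cfg.samples_per_point):
            perturbed = perturb_weights(base, percent, rng, cfg.mode)
            accs[j] = evaluate(perturbed, eval_set).accuracy
        results.append(
            MismatchResult(
                percent=float(percent),
                mean_acc=float(accs.mean()),
                min_acc=float(accs.min()),
                max_acc=float(accs.max()),
            )
        )
    return results
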