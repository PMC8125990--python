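"""Capacitive synapse: presynaptic voltage trace -> postsynaptic current.

The synapse output is the sum of a resistive and a capacitive component,

    I_soma = V / R + Cref * dV/dt,

where R is the reciprocal of the synaptic weight (so the resistive term is
weight * V — stated explicitly because it silently flips the role of large vs
small weights) and Cref is a shared capacitance, identical for every synapse
(default 0.0083 model units).  dV/dt is realized as a backward first
difference at the simulation step — the simplest causal estimator consistent
with an online hardware synapse.  The first output sample has no derivative
available and carries the resistive term only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SynapseParams", "CurrentTrace", "synapse_current", "DEFAULT_C_REF"]

DEFAULT_C_REF = 0.0083


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-like gain (1/R) and synapse capacitance.

    The weight's sign is unrestricted: negative weights are legal and are how
    inhibition-induced neurons receive inhibitory drive.
    """

    weight: float
    c_ref: float = DEFAULT_C_REF

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError(f"weight must be finite, got {self.weight!r}")
        if self.c_ref < 0:
            raise ValueError(f"c_ref must be non-negative, got {self.c_ref}")


@dataclass(frozen=True)
class CurrentTrace:
    """A current series (pA-scale model units) sampled at dt (ms)."""

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size < 1:
            raise ValueError("a current trace needs at least one sample")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")


def synapse_current(
    v_pre: np.ndarray,
    params: SynapseParams,
    dt: float,
    spike_mask: np.ndarray | None = None,
) -> CurrentTrace:
    """Convert a presynaptic membrane-voltage trace (mV, sampled at dt) to current.

    output[k] = weight * V[k] + c_ref * (V[k] - V[k-1]) / dt   for k >= 1
    output[0] = weight * V[0]

    By default the trace is differentiated literally, including the
    discontinuous post-spike reset.  Passing ``spike_mask`` (True at spiking
    samples) zeroes the derivative on the sample following each spike, so
    the reset jump is not transmitted — the convention the network uses,
    since summed reset transients otherwise cancel other neurons' upstrokes.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v = np.asarray(v_pre, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("v_pre must be a 1-D trace with at least 2 samples")

    out = params.weight * v
    deriv = np.diff(v) / dt
    if spike_mask is not None:
        spike_mask = np.asarray(spike_mask, dtype=bool)
        if spike_mask.shape != v.shape:
            raise ValueError("spike_mask must match the voltage trace shape")
        deriv = np.where(spike_mask[:-1], 0.0, deriv)
    out[1:] += params.c_ref * deriv
    return CurrentTrace(samples=out, dt=dt)
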