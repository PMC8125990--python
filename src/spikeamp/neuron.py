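"""Izhikevich spiking-neuron model: the two regimes used by the classifier.

The membrane model is the two-variable Izhikevich system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_app
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

with v in mV, t in ms, and I_app interpreted on the pA scale of amperometric
input currents.  Two parameter sets are used:

* tonic spiking (TS): a=0.02, b=-0.1, c=-65, d=6 — regular firing under
  sustained positive current; only valid for positive input, so negative
  drive is clamped to zero.
* inhibition-induced spiking (IIS): a=-0.02, b=-1, c=-60, d=8 — firing rate
  grows as the input current becomes more negative, complementary to TS.

Integration is forward Euler at a fixed step (default 0.1 ms), matching the
model's original published practice and its 13-FLOP-per-step cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "NeuronKind",
    "NeuronParams",
    "NeuronState",
    "SpikeTrain",
    "TONIC_SPIKING_PARAMS",
    "INHIBITION_INDUCED_PARAMS",
    "NumericalBlowupError",
    "SPIKE_APEX_MV",
    "resting_state",
    "step",
    "simulate",
]

#: Spike cutoff of the membrane equation; also the apex value recorded in
#: voltage traces at spiking steps (the Euler overshoot past 30 mV is a
#: step-size artifact, so traces cap the excursion at the model's stated apex).
SPIKE_APEX_MV = 30.0

#: Divergence guard: the quadratic voltage term diverges for bad parameter /
#: current combinations; |v| beyond this without crossing the spike threshold
#: aborts the simulation instead of silently producing nonsense.
BLOWUP_GUARD_MV = 500.0

DEFAULT_DT_MS = 0.1


class NeuronKind(str, Enum):
    TONIC_SPIKING = "tonic_spiking"
    INHIBITION_INDUCED = "inhibition_induced"


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich constants (a, b, c, d) tagged with the firing regime."""

    a: float
    b: float
    c: float
    d: float
    kind: NeuronKind

    @staticmethod
    def for_kind(kind: NeuronKind) -> "NeuronParams":
        if kind == NeuronKind.TONIC_SPIKING:
            return TONIC_SPIKING_PARAMS
        return INHIBITION_INDUCED_PARAMS


TONIC_SPIKING_PARAMS = NeuronParams(
    a=0.02, b=-0.1, c=-65.0, d=6.0, kind=NeuronKind.TONIC_SPIKING
)
INHIBITION_INDUCED_PARAMS = NeuronParams(
    a=-0.02, b=-1.0, c=-60.0, d=8.0, kind=NeuronKind.INHIBITION_INDUCED
)


@dataclass
class NeuronState:
    """Dynamic variables: membrane potential v (mV), recovery u."""

    v: float
    u: float


def resting_state(params: NeuronParams) -> NeuronState:
    """Conventional initialization v0 = c, u0 = b * v0."""
    return NeuronState(v=params.c, u=params.b * params.c)


class NumericalBlowupError(RuntimeError):
    """Raised when |v| exceeds the divergence guard without spiking."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) emitted over a simulated span."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    def count(self) -> int:
        return len(self)

    def rate_hz(self) -> float:
        """Mean firing rate over the simulated span."""
        if self.duration <= 0:
            return 0.0
        return len(self) / (self.duration / 1000.0)


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


def step(
    state: NeuronState,
    params: NeuronParams,
    i_app: float,
    dt: float = DEFAULT_DT_MS,
) -> tuple[NeuronState, bool]:
    """One forward-Euler update; applies the post-spike reset if v crosses 30 mV.

    Returns the new state and whether the neuron spiked on this step.  The
    recovery update uses the pre-step v, and the threshold is tested after
    both variables are advanced.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    _check_finite("state.v", state.v)
    _check_finite("state.u", state.u)
    _check_finite("i_app", i_app)

    v, u = state.v, state.u
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_app)
    u_new = u + dt * params.a * (params.b * v - u)

    if v_new >= SPIKE_APEX_MV:
        return NeuronState(v=params.c, u=u_new + params.d), True
    if abs(v_new) > BLOWUP_GUARD_MV:
        raise NumericalBlowupError(
            f"membrane potential diverged (|v| = {abs(v_new):.1f} mV > "
            f"{BLOWUP_GUARD_MV:.0f} mV guard) for {params.kind.value} neuron "
            f"at i_app = {i_app}"
        )
    return NeuronState(v=v_new, u=u_new), False


def simulate(
    params: NeuronParams,
    current: float | np.ndarray,
    duration: float,
    dt: float = DEFAULT_DT_MS,
    initial: NeuronState | None = None,
    record: bool = False,
) -> SpikeTrain | tuple[SpikeTrain, np.ndarray]:
    """Integrate the neuron over [0, duration] ms under a constant or sampled drive.

    ``current`` may be a scalar (held constant) or an array sampled at ``dt``
    covering the whole window (one value per step).  Tonic-spiking neurons
    clamp negative instantaneous current to zero before integration; the
    inhibition-induced regime receives the signed current unchanged.

    With ``record=True`` also returns the membrane-potential trace sampled at
    t = 0, dt, ..., duration (length n_steps + 1); spiking steps record the
    apex value 30 mV rather than the post-reset c, so the spike excursion is
    visible to downstream synapses.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")

    n_steps = int(round(duration / dt))
    drive = np.asarray(current, dtype=float)
    if drive.ndim == 0:
        drive = np.full(n_steps, float(drive))
    elif drive.ndim == 1:
        if drive.size < n_steps:
            raise ValueError(
                f"current series has {drive.size} samples but "
                f"{n_steps} steps are required to cover [0, {duration}] ms"
            )
        drive = drive[:n_steps]
    else:
        raise ValueError("current must be a scalar or 1-D series")
    if not np.all(np.isfinite(drive)):
        raise ValueError("i_app contains non-finite values")

    if params.kind == NeuronKind.TONIC_SPIKING:
        drive = np.maximum(drive, 0.0)

    state = initial if initial is not None else resting_state(params)
    spike_times: list[float] = []
    trace = np.empty(n_steps + 1) if record else None
    if record:
        trace[0] = state.v

    for k in range(n_steps):
        prev_v = state.v
        state, spiked = step(state, params, float(drive[k]), dt)
        if spiked:
            spike_times.append((k + 1) * dt)
        if record:
            trace[k + 1] = SPIKE_APEX_MV if spiked else state.v

    train = SpikeTrain(times=np.asarray(spike_times), duration=duration)
    if record:
        return train, trace
    return train
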