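"""The N-1 feed-forward network: N weighted inputs, N neurons, one output.

Topology: each of the N samples of a current pattern drives exactly one
first-layer neuron through a bare multiplicative weight w1(i); the neuron is
tonic-spiking when its weight is non-negative and inhibition-induced when the
weight is negative.  Every first-layer neuron projects through one capacitive
synapse (shared weight w2, shared capacitance Cref — zero dispersion, fixed
during learning) onto a single tonic-spiking output neuron, whose spike train
is the network's answer.  There are no lateral or backward connections, so
the stored-parameter count is exactly N variables (the input weights) plus
4N + 6 constants (a, b, c, d per first-layer neuron plus the output neuron's
four constants, w2 and Cref).

The input drive is held constant over the simulation window: the analog
front-end presents a static N-wide bus of consecutive samples per
classification window, so neuron i sees input_gain * w1(i) * pattern(i) for
the whole run.  ``input_gain`` is a single coupling factor mapping the
product of trained weights and pA-scale samples into the neurons' operating
range (a few tens of pA); it is calibrated once during training (see
``training``).

Units.  Membrane potential is in mV, time in ms and currents in pA
throughout.  The synapse capacitance Cref = 0.0083 is a physical capacitance
in nF (8.3 pF, a typical integrated-capacitor size), so its charging current
in pA is 1000 * Cref * dV/dt with dV/dt in mV/ms.  Under this reading the
calibrated network operates with first-layer drives inside the neuron
model's depicted operating range and the output neuron's latency code spans
tens of milliseconds; treating Cref as a bare pA/(mV/ms) coefficient instead
makes the output neuron unreachable at any input gain (the charge per
presynaptic spike would be ~0.8 pA*ms against a ~23 pA output rheobase).

The simulation is a single synchronous forward-Euler loop at dt = 0.1 ms:
advance every first-layer neuron one step, form each synapse current from
the recorded voltage sample and its backward difference (spiking steps
record the 30 mV apex), sum the N synapse currents, clamp the sum at zero
(the output neuron is tonic-spiking and only valid for positive current),
and advance the output neuron in the same step.  An optional settling
period lets the first layer run under drive before the response window
opens; by default it is zero, so every neuron starts the window at rest
(v0 = c, u0 = b*c) and the inhibition-induced neurons' slow recruitment
clock is part of the response code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from .coding import ResponseCode
from .neuron import (
    BLOWUP_GUARD_MV,
    DEFAULT_DT_MS,
    SPIKE_APEX_MV,
    INHIBITION_INDUCED_PARAMS,
    TONIC_SPIKING_PARAMS,
    NeuronKind,
    NumericalBlowupError,
    SpikeTrain,
)
from .synapse import DEFAULT_C_REF

__all__ = [
    "NetworkModel",
    "ComplexityReport",
    "DEFAULT_W2",
    "CREF_NF_TO_PA_PER_MV_MS",
    "forward",
    "forward_batch",
    "complexity",
    "model_to_dict",
    "model_from_dict",
]

DEFAULT_W2 = 0.0025
DEFAULT_DURATION_MS = 100.0

#: Cref is a capacitance in nF; with V in mV and t in ms its charging
#: current in pA is 1000 * Cref * dV/dt  (1 nF * 1 mV/ms = 1000 pA).
CREF_NF_TO_PA_PER_MV_MS = 1000.0

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NetworkModel:
    """A (possibly trained) N-1 network.

    ``code_mode`` and ``se_threshold`` are absent until training fixes the
    reference latency code and the decision bound.
    """

    w1: np.ndarray
    neuron_map: tuple[NeuronKind, ...]
    w2: float = DEFAULT_W2
    c_ref: float = DEFAULT_C_REF
    input_gain: float = 1.0
    dt: float = DEFAULT_DT_MS
    duration: float = DEFAULT_DURATION_MS
    settle: float = 0.0
    code_mode: ResponseCode | None = None
    se_threshold: float | None = None

    def __post_init__(self) -> None:
        w1 = np.asarray(self.w1, dtype=float)
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "neuron_map", tuple(self.neuron_map))
        if w1.ndim != 1 or w1.size < 1:
            raise ValueError("w1 must be a non-empty 1-D weight vector")
        if len(self.neuron_map) != w1.size:
            raise ValueError(
                f"neuron_map length {len(self.neuron_map)} does not match "
                f"{w1.size} input weights"
            )
        if not np.all(np.isfinite(w1)):
            raise ValueError("w1 contains non-finite weights")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.settle < 0:
            raise ValueError("settle must be non-negative")

    @property
    def n_inputs(self) -> int:
        return int(self.w1.size)

    @property
    def is_trained(self) -> bool:
        return self.code_mode is not None and self.se_threshold is not None

    def with_weights(self, w1: np.ndarray, w2: float) -> "NetworkModel":
        """Copy with replaced weights; the neuron map is deliberately kept
        (fabricated hardware retains its neuron types under mismatch)."""
        return replace(self, w1=np.asarray(w1, dtype=float), w2=float(w2))


@dataclass(frozen=True)
class ComplexityReport:
    """Algorithmic complexity: N variables and 4N + 6 constants."""

    n_variables: int
    n_constants: int

    def __str__(self) -> str:
        return f"{self.n_variables}v + {self.n_constants}c"


def complexity(n_inputs: int) -> ComplexityReport:
    """Parameter count of the N-1 architecture: (N variables, 4N+6 constants)."""
    if n_inputs < 1:
        raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
    return ComplexityReport(n_variables=n_inputs, n_constants=4 * n_inputs + 6)


def _layer_constants(neuron_map: Sequence[NeuronKind]):
    params = [
        TONIC_SPIKING_PARAMS
        if kind == NeuronKind.TONIC_SPIKING
        else INHIBITION_INDUCED_PARAMS
        for kind in neuron_map
    ]
    a = np.array([p.a for p in params])
    b = np.array([p.b for p in params])
    c = np.array([p.c for p in params])
    d = np.array([p.d for p in params])
    is_ts = np.array([p.kind == NeuronKind.TONIC_SPIKING for p in params])
    return a, b, c, d, is_ts


@njit(cache=False)
def _run_kernel(
    drive, a, b, c, d, w2, c_ref_pa, dt, n_settle, n_steps,
    oa, ob, oc, od, guard, out_spikes,
):  # pragma: no cover - exercised through forward_batch
    """Euler loop for a batch of patterns; returns (status, spike counts).

    status 0 = ok, 1 = first-layer divergence, 2 = output divergence.
    out_spikes is a preallocated (P, max_spikes) buffer of spike step indices.
    """
    P, N = drive.shape
    v = np.empty((P, N))
    u = np.empty((P, N))
    for p in range(P):
        for i in range(N):
            v[p, i] = c[i]
            u[p, i] = b[i] * c[i]
    rec_prev = v.copy()

    vo = np.full(P, oc)
    uo = np.full(P, ob * oc)
    counts = np.zeros(P, dtype=np.int64)
    max_spikes = out_spikes.shape[1]

    for k in range(n_settle + n_steps):
        in_window = k >= n_settle
        for p in range(P):
            io = 0.0
            for i in range(N):
                vi = v[p, i]
                ui = u[p, i]
                vn = vi + dt * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + drive[p, i])
                un = ui + dt * a[i] * (b[i] * vi - ui)
                if vn >= SPIKE_APEX_MV:
                    rec = SPIKE_APEX_MV
                    v[p, i] = c[i]
                    u[p, i] = un + d[i]
                else:
                    if abs(vn) > guard:
                        return 1, counts
                    rec = vn
                    v[p, i] = vn
                    u[p, i] = un
                if in_window:
                    io += w2 * rec + c_ref_pa * (rec - rec_prev[p, i]) / dt
                rec_prev[p, i] = rec
            if not in_window:
                continue
            if io < 0.0:
                io = 0.0
            vp = vo[p]
            up = uo[p]
            vn = vp + dt * (0.04 * vp * vp + 5.0 * vp + 140.0 - up + io)
            un = up + dt * oa * (ob * vp - up)
            if vn >= SPIKE_APEX_MV:
                vo[p] = oc
                uo[p] = un + od
                if counts[p] < max_spikes:
                    out_spikes[p, counts[p]] = k - n_settle + 1
                counts[p] += 1
            else:
                if abs(vn) > guard:
                    return 2, counts
                vo[p] = vn
                uo[p] = un
    return 0, counts


def forward_batch(model: NetworkModel, patterns: np.ndarray) -> list[SpikeTrain]:
    """Run the network on a batch of patterns (rows) in one synchronous loop.

    Returns one output-neuron spike train per row, with times measured from
    the opening of the response window (stimulus onset when ``settle`` is
    zero).  Identical model, pattern and dt give bit-identical trains
    whether run singly or batched.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    n_pat, n = patterns.shape
    if n != model.n_inputs:
        raise ValueError(
            f"pattern length {n} does not match network size {model.n_inputs}"
        )
    if not np.all(np.isfinite(patterns)):
        raise ValueError("patterns contain non-finite samples")

    dt = model.dt
    n_steps = int(round(model.duration / dt))
    n_settle = int(round(model.settle / dt))
    a, b, c, d, is_ts = _layer_constants(model.neuron_map)

    drive = model.input_gain * model.w1[None, :] * patterns  # (P, N)
    # tonic-spiking neurons are only valid for positive input currents
    drive[:, is_ts] = np.maximum(drive[:, is_ts], 0.0)

    out = TONIC_SPIKING_PARAMS
    max_spikes = max(64, n_steps // 4)
    buf = np.zeros((n_pat, max_spikes), dtype=np.int64)
    status, counts = _run_kernel(
        drive, a, b, c, d, model.w2,
        CREF_NF_TO_PA_PER_MV_MS * model.c_ref,
        dt, n_settle, n_steps,
        out.a, out.b, out.c, out.d, BLOWUP_GUARD_MV, buf,
    )
    if status == 1:
        raise NumericalBlowupError(
            "first-layer membrane potential diverged; reduce input_gain or "
            "the drive amplitude"
        )
    if status == 2:
        raise NumericalBlowupError("output membrane potential diverged")

    trains = []
    for p in range(n_pat):
        m = min(int(counts[p]), max_spikes)
        trains.append(
            SpikeTrain(times=buf[p, :m] * dt, duration=model.duration)
        )
    return trains


def forward(model: NetworkModel, pattern: np.ndarray) -> SpikeTrain:
    """Drive the network with one N-sample pattern; return the output spike train."""
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 1:
        raise ValueError("forward expects a single 1-D pattern")
    return forward_batch(model, pattern[None, :])[0]


# --- serialization ---------------------------------------------------------


def model_to_dict(model: NetworkModel) -> dict:
    """JSON-ready representation of a network model."""
    doc: dict = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "n_inputs": model.n_inputs,
        "w1": [float(x) for x in model.w1],
        "neuron_map": [kind.value for kind in model.neuron_map],
        "w2": model.w2,
        "c_ref": model.c_ref,
        "input_gain": model.input_gain,
        "dt": model.dt,
        "duration": model.duration,
        "settle": model.settle,
        "code_mode": None,
        "se_threshold": model.se_threshold,
    }
    if model.code_mode is not None:
        doc["code_mode"] = {"dt1": model.code_mode.dt1, "dt2": model.code_mode.dt2}
    return doc


def model_from_dict(doc: dict) -> NetworkModel:
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    code = doc.get("code_mode")
    return NetworkModel(
        w1=np.asarray(doc["w1"], dtype=float),
        neuron_map=tuple(NeuronKind(k) for k in doc["neuron_map"]),
        w2=float(doc["w2"]),
        c_ref=float(doc["c_ref"]),
        input_gain=float(doc["input_gain"]),
        dt=float(doc["dt"]),
        duration=float(doc["duration"]),
        settle=float(doc.get("settle", 0.0)),
        code_mode=None if code is None else ResponseCode(code["dt1"], code["dt2"]),
        se_threshold=None
        if doc.get("se_threshold") is None
        else float(doc["se_threshold"]),
    )
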