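# Methods

## Neuron model

Both neuron types are instances of the two-variable Izhikevich model

    dv/dt = 0.04 v² + 5 v + 140 − u + I_app
    du/dt = a (b v − u)
    if v ≥ 30 mV:  v ← c,  u ← u + d

with v in mV, t in ms and I_app on the pA scale of amperometric currents.
The coefficients of the voltage equation assume exactly these units.  Two
parameter sets are used:

| regime | a | b | c | d | behaviour |
|---|---|---|---|---|---|
| tonic spiking (TS) | 0.02 | −0.1 | −65 | 6 | regular firing above a rheobase of ≈ 22.6 pA; only valid for positive input, negative drive is clamped to zero |
| inhibition-induced (IIS) | −0.02 | −1 | −60 | 8 | fires intrinsically (first spike ≈ 60 ms from rest at zero input) and accelerates as the input becomes more negative; very deep inhibition (hundreds of pA) postpones firing beyond the analysis window |

The TS value b = −0.1 is deliberately the published value for this
application rather than the more widely quoted 0.2; it yields the expected
monotone f–I characteristic, and b remains a free field of `NeuronParams`.

Integration is forward Euler at dt = 0.1 ms.  Recovery uses the pre-step v;
the threshold is tested after both variables advance; a spike is stamped at
the step where the test fires, i.e. t = (k+1)·dt.  Default initial state is
v₀ = c, u₀ = b·v₀.  A divergence guard aborts with a diagnostic when |v|
exceeds 500 mV without crossing the spike threshold — the quadratic voltage
equation cannot recover gracefully from such excursions at this step size,
and without the guard the overshoot manufactures spurious spikes.

Step-size behaviour: spike *counts* over a 500 ms window are stable to ~5 %
under dt → dt/10, and the *first* spike time moves by less than 2·dt under
dt halving; later spike times accumulate phase drift of a few steps, which
is inherent to fixed-step Euler and harmless at the 1 ms latency
quantization used downstream.

## Synapse and units

Each synapse converts the presynaptic membrane-potential trace into a
current: a resistive term V/R with R the reciprocal of the weight (so the
term is weight·V — note that large weights mean *low* resistance), plus a
capacitive term Cref·dV/dt realized as a causal backward difference.  The
first output sample carries no derivative.  Voltage traces record the spike
apex at 30 mV on spiking steps (the Euler overshoot past the cutoff is a
step-size artifact), so the charge transmitted per presynaptic spike is
step-size independent.

**Units.** Cref = 0.0083 is read as a physical capacitance in nF
(8.3 pF — a typical integrated-capacitor size).  With V in mV and t in ms,
the charging current in pA is 1000·Cref·dV/dt.  This conversion is applied
at the network layer, where currents are physically pA; the standalone
`synapse_current` keeps the dimensionless textbook formula.  The conversion
is load-bearing: without it the charge per presynaptic spike is
Cref·(30−c) ≈ 0.79 pA·ms against an output rheobase of ≈ 22.6 pA, so the
output neuron can only be driven by kilohertz population rates, which
requires first-layer drives of thousands of pA (far outside the model's
operating range), destabilizes deeply inhibited IIS neurons at dt = 0.1 ms,
and compresses all output latencies to 1–2 ms.  With the nF reading the
calibrated network runs at first-layer drives of tens of pA and produces
latency codes spanning tens of milliseconds, which is the regime the
architecture's published behaviour describes.

The literal backward difference transmits the post-spike reset jump as a
large negative transient.  `synapse_current` keeps this literal behaviour
(an optional spike mask suppresses it); at the network's calibrated
operating point suppressing or transmitting the reset makes no measurable
difference to the output code, so the network uses the literal form.

## Network

Fig-3-style topology: N inputs → N first-layer neurons → 1 output, no
lateral or backward connections.  Input coupling is a bare multiplicative
weight (capacitive synapses sit only between the layers); the drive
input_gain·w1(i)·pattern(i) is held constant across the window, modelling
the analog front-end's static N-wide sample bus.  The output neuron
receives the plain sum of the N synapse currents, clamped at zero because
it is tonic-spiking.  Stored parameters: N variable input weights plus
4N + 6 constants (4 per first-layer neuron, plus the output's four
constants, w2 and Cref) — complexity is linear in N by construction.

The simulation is one synchronous Euler loop (numba-compiled, batched over
patterns); identical inputs give bit-identical spike trains, batched or
not.  A `settle` field lets the first layer run under drive before the
response window opens; the default is 0 ms, so the window starts from rest
and the IIS neurons' slow recruitment clock (their ~50–80 ms first-spike
latency from rest) is part of the response code.

## Training

Algorithm (one pass, no iteration):

1. average the positive patterns sample-wise → AVG;
2. w1 = δ(κ − AVG);
3. route: w1(i) < 0 → IIS, else TS (zero maps to TS and silences the input);
4. assign shared w2 = 0.0025 and Cref = 0.0083;
5. run the network over the training set, read two-latency codes quantized
   to the 1 ms bin, store the per-component mode over positive responses
   (ties break toward the earlier latency);
6. decision threshold = the largest SE any positive training pattern
   produced against the mode; classify positive iff SE ≤ threshold
   (inclusive, so boundary positives are accepted); fewer than two output
   spikes is a NO_RESPONSE outcome, always classified negative.

The pseudocode-literal variant that averages the *whole* training set (and
takes the mode over all responses) is available as `use_all_patterns=True`;
the default uses the positive class, which is what the published response
table describes.  Labels are used only for selecting the averaging subset,
setting the threshold and evaluating — the weight rule itself is
unsupervised.

δ and κ have no analytic rule; the suggestion is anchored at the reference
20-input configuration (δ = 1.4, κ = 26), scaled as δ ∝ 1/N and κ ∝ N, and
clipped to the calibrated ranges δ ∈ [0.95, 1.4], κ ∈ [26, 32] for
N ∈ [10, 40]; sizes outside that span extrapolate with a warning.

### Input-gain calibration

`input_gain`, the single coupling factor between weighted pA-scale samples
and the neurons' dynamic range, is fixed by a self-check that uses positive
patterns (and the all-zero pattern) only.  Scanning a geometric gain grid
(0.004–64, factor 1.25), the calibration requires every positive pattern to
evoke at least two output spikes, and prefers, in order: operating points
whose positive mode is *stimulus-driven* — distinct from the background
code evoked by an all-zero pattern and at least five bins off the one-bin
saturation floor; at least two bins of background separation, provided the
positive class stays coherent (SE spread ≤ 8 bin²); the smallest positive
SE spread; the highest fraction of positives exactly on the mode; the
smallest gain.  At the selected point the deep inhibition that a fusion
peak exerts on its IIS neurons delays the IIS recruitment clock by one to
three latency bins relative to background, giving a tight, late positive
mode (e.g. (61, 1) ms); waveforms with their energy away from the trained
peak drive TS neurons instantly (codes near (1–3, 1) ms, SE in the
hundreds), and low-energy waveforms hug the background code.

## Synthetic data

The generator emulates one amperometric recording per pattern set: the
shape parameters — baseline 2–8 pA, peak 30–70 pA, peak position 0.2–0.35
of the window, decay constant 0.10–0.20 of the window, noise SD 1–3 pA —
are drawn once per set, and individual events vary by ±10 % relative jitter
plus additive Gaussian sample noise, clipped to [0, 100] pA.  The
recording-level structure matches the published response table, where more
than half the positive patterns produced identical codes (a homogeneous
event family); the short decay constant reproduces the published TS/IIS
splits (1–5 IIS neurons across N = 10–40, i.e. an above-κ span of 2–4
samples).  Negatives share the recording's amplitude draw, so the classes
overlap in amplitude and differ in shape only: flat noise, slow drift,
double bumps (two brief full-height flickers without the slow decay tail
that carries a real fusion's charge), truncated rises and late peaks.

What the generator does **not** model: correlated (1/f) electrode noise,
overlapping fusion events, pre-spike foot signals, baseline wander within a
single window, and amplitude distributions heavier-tailed than ±10 % within
a recording.  Passing tests therefore show that the pipeline separates
shape families under matched amplitudes and realistic sample noise — not
that it handles every pathology of real recordings.

## Mismatch analysis

Fabrication dispersion is modelled by scaling every input weight and the
shared output weight per draw: systematically, factor 1 + u·p/100 with
u ~ U(0, 1) sharing the sign of the stated percentage p (gate-oxide
variation has a gradient character within a substrate area), or
independently, 1 + U(−1, 1)·|p|/100.  Capacitances and the neuron map stay
fixed, and the trained mode and threshold are never refit.  The sweep
records mean/min/max accuracy over (default) 50 draws per grid point, with
an optional pre-scaling factor for the suggested fabrication-time weight
correction.

A known divergence from the published robustness profile: in this
implementation mean accuracy under −20 % systematic dispersion is slightly
*below* that under +5 %, i.e. the asymmetry is inverted.  Mechanism: the
positive code is carried by the delay that deep IIS inhibition imposes on
the recruitment clock; shrinking weights weakens that inhibition and drifts
positive responses toward the background code, while growing weights only
deepen it.  The direction of the asymmetry is an emergent property of the
operating point, not a tunable.

## Problem sizes and determinism

The test suite and the acceptance script use the published experimental
scale throughout: 40 positive + 40 negative patterns, N = 20 (sizes 10–40
in the architecture sweep), 100 ms windows at dt = 0.1 ms, 50 draws per
mismatch grid point.  All randomness flows through seeded NumPy generators;
a fixed seed reproduces pattern sets, fits and sweeps byte-for-byte.

## Known limitations

* The latency scale of the fitted models (background ≈ 50–60 ms, positive
  mode a few bins later, Δt2 of 1–4 ms) differs from the published worked
  example's (3, 3) ms mode; the published operating point is not
  reproducible from the printed constants alone (see the unit discussion),
  and the classifier here lives on the IIS-clock side of the dynamics.
  Consequently the derived maximal sampling rate (~16 Hz for the worked
  model) is lower than the published 100 Hz figure, which follows from the
  printed Table values.
* Recordings whose positives are barely distinguishable from background
  (weak peaks, high noise) calibrate to 1-bin separation and score
  0.84–0.95 rather than ≥ 0.96; across 20 benchmark seeds the accuracy is
  0.98 ± 0.04 with 17/20 at or above 0.96.
* `extract_latencies` supports k > 2 latencies, but the classifier uses
  exactly two; no claim is made about larger codes.
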