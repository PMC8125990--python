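# spikeamp

A linear-complexity spiking neural network (SNN) classifier for amperometric
current waveforms, aimed at edge processing of exocytosis recordings: deciding,
directly at the sensor, whether a sub-100 pA current transient recorded by a
carbon-nanotube electrode is a vesicle-fusion event or not.

The network is a minimal N-1 architecture built from Izhikevich neurons:

* N inputs, one per signal sample, each feeding exactly one first-layer neuron
  through a single weight `w1(i)`;
* a first layer mixing **tonic-spiking** (TS: a=0.02, b=−0.1, c=−65, d=6) and
  **inhibition-induced-spiking** (IIS: a=−0.02, b=−1, c=−60, d=8) neurons,
  routed by the sign of `w1(i)`;
* one tonic-spiking output neuron fed by N identical capacitive synapses
  (`I_soma = V/R + Cref·dV/dt`, with `R = 1/w2`, shared `w2 = 0.0025` and
  `Cref = 0.0083 nF`), so only the N input weights are variables:
  the algorithmic complexity is `N` variables + `4N + 6` constants.

Training is a single analytic pass with no teacher, no epochs and no
gradients: the input weights are mapped from the sample-wise average of the
positive patterns by `W1 = δ(κ − AVG)`, neurons are routed by weight sign, and
the network's answer is read as a **two-latency code** (Δt1, Δt2) — time to
the output neuron's first spike and the first interspike interval.  The mode
of the positive responses becomes the reference code; a pattern is accepted
as a fusion event iff its squared latency error
`SE = (Δt1 − Δt1ₘ)² + (Δt2 − Δt2ₘ)²` does not exceed the largest SE any
positive training pattern produced.  A weight-mismatch module emulates
semiconductor fabrication dispersion and re-evaluates the frozen classifier
under percentage perturbations of all weights.

A synthetic generator produces labeled amperometric pattern sets (single
fusion transients vs amplitude-matched non-fusion waveforms: flat noise,
drift, double bumps, truncated rises, late peaks), so everything runs
without external data.

## Worked example

```python
import spikeamp as sa

bench = sa.make_benchmark(20, n_pos=40, n_neg=40, seed=0)  # one "recording"
model = sa.fit(bench)          # analytic one-pass fit, auto-calibrated gain
ev = sa.evaluate(model, bench)
```

The fitted 20-1 model, via `spikeamp.io.training_report`, prints:

```
network size: 20-1
tonic spiking neurons: 18
inhibition-induced neurons: 2
TS weight range: 5.14 .. 29.48
IIS weight range: -21.57 .. -2.46
w2: 0.0025
Cref: 0.0083
input gain: 0.0582077
response mode: [61.0, 1.0] ms
SE threshold: 0.0 ms^2
```

and evaluation on the 80 patterns gives

```
TP=40 TN=40 FP=0 FN=0 ACC=1.0000
max sampling frequency: 16.1 Hz
complexity: 20v + 86c
```

Reading: 18 of the 20 inputs got positive weights (tonic-spiking neurons,
sample values below the offset κ) and the 2 peak samples got negative
weights (inhibition-induced neurons).  Every positive pattern evoked the
same latency code (61 ms, 1 ms) — hence the zero SE threshold — while
non-fusion patterns either fired the output almost immediately (SE in the
hundreds) or hugged the network's background response one latency bin away,
so all 80 patterns classify correctly.  The maximal sampling rate is the
reciprocal of the summed worst-case positive latencies.

The same flows are available from the shell:

```sh
spikeamp gen -n 20 --seed 0 -o bench.csv
spikeamp train bench.csv -m model.json
spikeamp evaluate model.json bench.csv
spikeamp sweep-sizes --seed 0
spikeamp mismatch model.json bench.csv --grid="-20,-10,0,5,10"
spikeamp neuron-demo --kind iis --currents="-30,-10,0,20,70"
```

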