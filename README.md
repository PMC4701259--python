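# emgspike

Surface-EMG gesture recognition with a hybrid spiking/formal neural network.

`emgspike` is for researchers and engineers building myoelectric
human–machine interfaces who want a biologically grounded alternative to
classical window-statistic features. It implements, end to end, a
recognition system in which a layer of spiking neurons — not a hand-crafted
statistic — turns raw multichannel sEMG into classifier-ready features, and
compares it against the standard sliding-window RMS baseline on identical
data splits.

## The model

**Feature extraction.** Each of the 8 sEMG channels drives one virtual
sensory neuron governed by the Izhikevich model

```
dV/dt = 0.04 V² + 5 V + 140 − u + I
du/dt = a (b V − u),        if V ≥ 30 mV:  V ← c,  u ← u + d
```

with the regular-spiking preset (a=0.02, b=0.2, c=−65, d=8). The drive
current combines a rectified, gain-scaled stimulator term and lateral
synaptic input from the other channels:

```
I = Σᵢ wᵢ gᵢ yᵢ(t) + k·|EMG(t)|,   gᵢ < 0 (inhibitory), k = 2×10⁶
```

Each neuron's spikes feed its own Tsodyks–Markram synapse — a unit resource
split into recovered/active/inactivated pools x, y, z with a facilitation
variable u_f — and the active fraction y(t) is both the inhibitory signal
broadcast to the other channels and the classification feature, sampled
every 50 ms. With the feature-extractor preset (U=0.05, τ_rec=1 ms,
τ_I=200 ms, τ_facil=1 ms) the synapse acts as a leaky spike integrator with
a 200 ms decay, so y(t) tracks each channel's recent firing rate. Mutual
inhibition (w=0.5, g=60) suppresses background firing and the in-phase
(common-mode) component shared by closely spaced electrodes, which carries
no pattern information.

**Baseline.** Per-channel sliding-window RMS, `sqrt(mean(xₙ²))`, over
100 ms windows advanced every 50 ms (40/20 samples at 400 Hz).

**Classifier.** A from-scratch sigmoid MLP (8 inputs → 9 hidden → 9 output
units, one per gesture) trained by backpropagation at learning rate 0.01
with test-set early stopping; the decision is the output unit with maximal
activation.

**Synthetic data.** Since real recordings require hardware, the package
ships a generator emulating the acquisition protocol: 4 series of 9
gestures (2–3 s each, random order, relaxed rest between), rendered as
amplitude-modulated 20–150 Hz noise at 400 Hz or 2000 Hz, with per-channel
activation patterns, shared common-mode noise and baseline noise at
physiological voltage scales.

## Worked example

```python
from emgspike import PipelineConfig, run_training_pipeline, compare

reports = {}
for extractor in ("rms", "spiking_inhibitory"):
    cfg = PipelineConfig(extractor=extractor, sample_rate=400.0, seed=1)
    pipeline, reports[extractor] = run_training_pipeline(cfg)
    print(f"{extractor}: {reports[extractor].accuracy_pct:.2f}% "
          f"over {reports[extractor].n_windows} windows")
print(f"DELTA: {compare(reports['spiking_inhibitory'], reports['rms']):+.2f} points")
```

prints

```
rms: 99.55% over 665 windows
spiking_inhibitory: 98.50% over 666 windows
DELTA: -1.05 points
```

i.e., on the default synthetic session (3 series train, 1 series test) the
spiking feature extractor with lateral inhibition classifies 98.5% of
50 ms test windows correctly, within about one percentage point of the RMS
baseline on the same split — the two extractors are interchangeable in
accuracy, while the spiking one emits a spike-based, neuromorphic-ready
signal. Each report also carries the 9×9 confusion matrix and per-class
recall.

The same workflow is available from the shell:

```
emgspike generate --seed 1 --out session.csv
emgspike extract --recording session.csv --extractor spiking-inhibitory --out feats.csv
emgspike compare --seed 1 --out paired.json
```

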