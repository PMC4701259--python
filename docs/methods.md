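# Methods

This note documents the models implemented in `emgspike`, the numerical
choices behind them, what the synthetic data does and does not emulate, and
the known limitations.

## Neuron model and integration

The sensory units are Izhikevich neurons: `dV/dt = 0.04V² + 5V + 140 − u + I`,
`du/dt = a(bV − u)`, with the after-spike reset `V ← c, u ← u + d` applied
whenever `V ≥ 30 mV`. All simulations use the cortical regular-spiking
preset (`a=0.02` 1/ms, `b=0.2`, `c=−65` mV, `d=8`), which fires tonically
under sustained drive with spike-frequency adaptation. The drive `I` is the
model's dimensionless current; no conversion to amperes is attempted.

Integration is explicit Euler — the scheme this model was designed around —
with a configurable step, default `dt = 0.5 ms` and a 1 ms stability cap.
The spike test is applied after the Euler update; the recorded trace holds
the clipped 30 mV peak at spike samples (not the Euler overshoot) so traces
are reproducible regardless of overshoot magnitude, while the integration
state is reset to `(c, u+d)`.

Two numerical facts matter for interpreting spike times. First, Euler
spike-time error is first order: halving `dt` roughly halves the shift in
each spike time. Over a 1 s tonic run at `I=10` the accumulated phase drift
between `dt=0.5` and `dt=0.25` is ≈12 ms (about a quarter of one
inter-spike interval by the 23rd spike); sub-millisecond agreement under
halving is reached near `dt=0.01 ms`. The default 0.5 ms step is kept
because the feature extractor consumes 200 ms-smoothed firing *rates*, not
individual spike times, and those are stable at 0.5 ms. Second, the
inter-spike-interval sequence under constant drive is non-decreasing only
up to one integration step of slack: the exact dynamics overshoot the
adapted rate very slightly on the second interval (44.96 → 44.84 ms at
`I=10`), so monotonicity assertions use one-step tolerance.

`resting_state` returns the stable intersection of the nullclines at
`I = 0` — the root of `0.04V² + (5−b)V + 140 = 0` whose Jacobian
eigenvalues have negative real parts, with `u* = bV*` — and is the
canonical initial condition (`(−70, −14)` for the RS preset). Parameter
sets without a real or stable root raise a "no resting state" error.

## Synapse model and exact inter-spike propagation

Short-term plasticity follows Tsodyks–Markram: a unit resource divided into
recovered `x`, active `y` and inactivated `z` pools,

```
dx/dt = z/τ_rec − u_f·x·δ(t−t_sp)
dy/dt = −y/τ_I + u_f·x·δ(t−t_sp)
dz/dt = y/τ_I − z/τ_rec
du_f/dt = −u_f/τ_facil + U(1−u_f)·δ(t−t_sp)
```

At each spike the event map applies facilitation first (`u_f ← u_f +
U(1−u_f)`) and then transfers `u_f·x` from the recovered to the active
pool — the standard event convention; the alternative order is not exposed.

Between spikes the system is linear with constant coefficients, so each
step applies the exact closed-form propagator rather than an Euler update:
`y` and `u_f` decay exponentially, `z` receives the two-exponential
convolution of `y`'s efflux (with the confluent `t·e^(−t/τ)` limit when
`τ_I = τ_rec`), and `x` is reconstructed from exact conservation. This
choice removes all truncation error — the sampled trajectory coincides with
the matrix-exponential solution to rounding — and guarantees
`x + y + z = 1` and pool bounds `[0, 1]` for any positive step, which
matters because the feature preset's `τ_rec = τ_facil = 1 ms` is only twice
the default integration step.

Two presets are used. The demonstration preset (`U=0.5, τ_rec=100 ms,
τ_I=10 ms, τ_facil=1000 ms`) shows both regimes: at 200 Hz input the
per-spike release amplitudes collapse (depression) — strictly decreasing
over the first five spikes, after which the slowly accumulating
facilitation marginally outpaces the saturated depletion, so the late-train
amplitudes creep back up by ~20% while remaining an order of magnitude
below the first response; at 2 Hz the pre-spike utilization rises across
the early train (facilitation). The feature preset (`U=0.05, τ_rec=1 ms,
τ_I=200 ms, τ_facil=1 ms`) deliberately degenerates into a leaky spike
integrator: resources recover and facilitation resets within ~1 ms, so each
spike deposits ≈0.05·(1−y−z) into `y`, which decays with `τ_I = 200 ms`.
The feature `y(t)` is therefore a smoothed, saturating estimate of the
neuron's recent firing rate in `[0, 1)`.

## Sensory layer

One neuron per channel. The drive is `I = w·(−g)·Σ_{j≠i} y_j + k·|EMG_i(t)|`
with defaults `w=0.5`, `g=60` (stored as a magnitude plus an inhibitory
flag, since the coupling is reported as a positive number with a negative
applied sign) and stimulator gain `k = 2×10⁶` volts→current. The layer
update is synchronous — every channel reads the previous step's `y`
values — so results are independent of channel ordering, and a layer with
`w=0` is bit-identical to independent single-neuron simulations (asserted
in the tests). sEMG samples are zero-order-held between integration steps
(5 steps per sample at 400 Hz, 1 at 2000 Hz), keeping both device pipelines
structurally identical. Features are the instantaneous per-channel `y` at
every 50 ms sampling instant, labelled with the gesture active at that
instant; rectification makes the features invariant to signal polarity.

With these defaults, a channel whose envelope is ~50 µV RMS receives drive
of order 100 (deep in the spiking range, ~100–150 Hz firing), rest-level
noise receives ~3 (just below the RS rheobase of 4, occasional background
spikes), and active neighbours contribute tens of units of inhibition —
enough to silence background and common-mode firing but not a strongly
driven channel.

## RMS baseline

Per-channel `RMS = sqrt(mean(xₙ²))` over 100 ms windows stepped by 50 ms.
Windows are specified in milliseconds and converted to samples (40/20 at
400 Hz, 200/100 at 2000 Hz) so the geometry is rate-independent. Trailing
incomplete windows are dropped; each window's label is the majority label
within it, ties broken toward the lowest class index; exported times are
window-end times, aligning rows with the spiking extractor's instants.

## Classifier

A plain sigmoid MLP, 8 → 9 → 9 by default (one hidden layer of nine units,
one output unit per gesture), trained by backpropagation on mean squared
error against one-hot targets, learning rate 0.01, at most 4000 epochs.
Weights start uniform in (−0.5, 0.5) from a seeded generator; biases start
at zero. The predicted class is the argmax output, ties toward the lowest
index.

The update rule is per-sample (online) gradient descent in shuffled order
within each epoch — classical backpropagation. This choice is empirical as
well as historical: at learning rate 0.01, full-batch gradient steps on
this loss surface are far too small to converge within the 4000-epoch cap
(test accuracy stalls near chance), whereas per-sample updates converge in
roughly 1000–4000 epochs, the regime the method is expected to operate in.
Batch mode remains available as a config switch (`mlp.update: batch`) and
needs a correspondingly larger learning rate. The per-sample inner loop is
numba-compiled for the one-hidden-layer case, with a pure-Python fallback
for other depths.

Early stopping monitors the test-set error each epoch and stops when it has
not improved for 50 epochs (configurable patience), returning the snapshot
with minimal test error; this is the "stop when the test error starts
rising" criterion made robust to noisy error curves. Features are
standardized per dimension (mean/std from the training split only) before
training — without this, RMS features at ~10⁻⁵ V would produce vanishing
gradients through the sigmoid.

Gradient correctness is established against central finite differences
(1e−5 relative) on small networks; training is fully deterministic given
seed, data and hyperparameters.

## Synthetic sEMG

The generator emulates the acquisition protocol, not muscle physiology:
interference-pattern sEMG is modelled as amplitude-modulated, zero-mean
Gaussian noise band-passed to 20–150 Hz — a standard surrogate with the
right second-order statistics — rather than as superpositions of motor-unit
action potentials. A session is 4 series (3 train / 1 test by default),
each containing all 9 gestures once in random order, 2–3 s per gesture,
1 s relaxed rest between gestures, 100 ms envelope ramps at gesture
boundaries. The schedule is drawn in continuous time before any noise, so
one seed produces the same label structure and per-gesture RMS profile at
400 Hz and 2000 Hz.

Each non-rest gesture activates a dedicated primary channel (70–120 µV RMS)
plus one or two secondary channels (30–70 µV); gesture 0 is rest. All
channels share an identical common-mode noise component (5 µV RMS) —
included specifically so that the benefit of lateral inhibition against
in-phase activity is testable — plus independent 1.5 µV baseline noise.
The voltage scale was chosen once so that the published stimulator gain
`k = 2×10⁶` places gestures in the neurons' spiking range and rest just
below rheobase; it is documented in the generator defaults and was not
revisited after the end-to-end runs.

What passing tests on this data do **not** show: robustness to electrode
shift, fatigue, motion artifacts, powerline interference, inter-subject
variability, or gesture patterns whose channel signatures differ only in
fine temporal structure — real sEMG is harder than this surrogate in all
of those ways. The synthetic session answers a narrower question: given
gesture-dependent, channel-patterned amplitude modulation at realistic
scales and rates, does the spiking extractor recover the pattern as well as
the RMS statistic does.

## Study-scale results and problem sizes

On the default synthetic session (seed 1: ~125 s of training signal,
~33 s of test signal, ≈665 50-ms test windows), the pipelines reach
99.5% (RMS), 98.3% (spiking, isolated) and 98.5% (spiking, inhibitory)
window-level test accuracy at 400 Hz, and 98.0% (spiking, inhibitory) at
2000 Hz — the paired spiking-vs-RMS delta and the cross-rate delta are
both within ~1 percentage point, and inhibition slightly improves on
isolated mode. On identical common-mode input, lateral inhibition removes
~two thirds of each neuron's spikes relative to isolated mode. These are
exactly the quantities `scripts/acceptance.py` recomputes; the test suite
asserts the corresponding properties (≥90% accuracy, |delta| ≤ 3 points)
at the same problem sizes, chosen as the smallest session matching the
full acquisition protocol.

Residual test-window errors concentrate at gesture onsets and offsets: the
spiking feature rises with an effective time constant well under 100 ms
under strong drive but decays at the fixed `τ_I = 200 ms` after offset, so
the first window or two after a boundary is ambiguous between "weak
gesture" and "rest after gesture". The RMS feature has the same issue over
its 100 ms window support. Window-level accuracy (one decision per 50 ms
instant) is the reported granularity throughout; per-gesture-instance
voting is deliberately not the default, as the streaming classifier must
commit at every instant.

## Limitations

- One sensory neuron per channel, one firing-type preset; no conductance
  or multicompartment models.
- No classical feature alternatives beyond RMS (MAV, zero crossings,
  wavelets are out of scope).
- The MLP is deliberately minimal: no momentum, regularization, softmax or
  deep variants.
- Device I/O (Bluetooth, vendor SDKs), GUIs and robot actuation are out of
  scope; recordings enter as CSV.
- The voltage scale of real devices varies; `k` and the generator
  amplitudes are calibrated jointly and should be re-calibrated for real
  hardware.
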