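# Methods

`stndetect` is a self-contained pipeline for detecting the parkinsonian
state from subthalamic-nucleus (STN) spike timing in the time domain: it
synthesizes labeled spike-timing data, trains spiking classifiers whose
activations are sharpened into binary threshold units during training, and
verifies that inference survives mapping onto simulated memristive
crossbar hardware.  This note records the models, the defaults and why
they are what they are, the numerical choices, and what the tests do and
do not establish.

## The detection problem

Parkinsonian STN activity differs from healthy activity in two robust
ways: firing rates are higher, and spectral power in the beta band
(13-30 Hz) is elevated.  Conventional detectors estimate beta power in the
frequency domain; here the classifier consumes raw spike times.  Each
input is one neuron's spike-time vector over a fixed window of
T_max = 2,500 ms, zero-padded to a fixed length L_max = 128 (above the
largest expected spike count — about 75 spikes at 30 Hz over 2.5 s — with
margin; genuine spikes are strictly positive times, so 0 is unambiguous
padding).  The label is binary: 0 healthy, 1 PD.

## Synthetic data

Two generators provide labeled data.  Neither ingests real
electrophysiology; both are calibrated to the qualitative biomarkers
above.

**Phenomenological generator** (`spikegen`).  Healthy neurons follow a
renewal process with a 3 ms dead time whose gaps are
`refractory + Exp(1/rate − refractory)`, so the mean rate equals the
nominal rate exactly.  PD neurons follow an inhomogeneous Poisson process
with rate `rate_pd · (1 + mod_depth · sin(2π·beta_freq·t + φ))`, a
uniform random phase per neuron, thinning for the modulation and the same
dead time.  Defaults: `rate_healthy = 10 Hz`, `rate_pd = 25 Hz`,
`beta_freq = 20 Hz`, `mod_depth = 0.8`, `refractory = 3 ms`.  The source
literature for this task reports no numeric rates, only the rate and
beta-power asymmetries; these defaults sit in the physiological range for
STN units, produce visibly sparser healthy rasters, and are exposed in
configuration.  The target asymmetries themselves (denser PD firing,
elevated PD beta power) are qualitative, so the generator is validated on
ordering properties, not on matching particular rates.  Because the two classes differ strongly in rate, the
classification problem these defaults induce is easier than real MER
data; high accuracies on this data demonstrate that the pipeline learns
the encoded biomarkers, not clinical performance.

**Circuit generator** (`circuit`).  A 6-region
cortex–basal-ganglia–thalamus network (regular/inhibitory cortex,
direct/indirect-pathway striatum, STN, GPe, GPi, thalamus; 10 neurons per
region by default) of Izhikevich single-compartment neurons with
current-based exponential synapses (τ_exc = 5 ms, τ_inh = 12 ms, 3 ms
conduction delay).  Connectivity follows the classical pathway wiring:
cortex and striatum connect stochastically (in-degree 3, drawn without
replacement, no self-edges); each GPe neuron receives inhibition from
exactly two other GPe neurons and from all indirect-pathway striatal
neurons; each GPi neuron from all direct-pathway striatal neurons and
from GPe; thalamus receives only GPi inhibition; half of the GPe and GPi
populations (configurable fraction) receive STN excitation.  A dopamine
scalar (healthy 1.0, PD 0.2) controls the state: depletion multiplies the
striato-pallidal (iSTR→GPe) inhibitory efficacy, the hyperdirect
cortico-STN gain, and the reciprocal STN–GPe loop gains
(`1 + k·(1 − dopamine)` per projection).  With the shipped gains the
depleted network raises mean STN rate by ~25-30 % and roughly triples STN
population beta power — the two biomarkers — without any oscillatory
input.  The neuron model is a deliberately reduced stand-in for
conductance-based biophysics: the simulator is validated on biomarker
properties (rate and beta asymmetry, dt-robustness of rates), never on
membrane trajectories.  Integration is fixed-step (dt = 0.1 ms) with the
standard two-half-step update of the quadratic membrane equation; white
membrane noise scales as 1/√dt so its integrated variance is step-size
independent.  Spike times are recorded at spike-reset events and reported
in (0, duration].

To emulate recordings of 15-neuron groups from a 10-neuron STN region,
the circuit generator runs multiple independently seeded network
realizations and pools the per-neuron trains.

## Detector architectures and sharpened training (`sharpnet`)

Three architectures are shipped: an 8-layer spiking LSTM
(`slstm8`: two recurrent layers of 64, dense 256-128-64-32-16, 2-unit
output), a 7-layer spiking LSTM (`slstm7`, one dense layer fewer) and a
7-layer feedforward spiking network (`snn7`: 256-128-64-64-32-16-2).
The layer counts define the named architectures; the widths are this
package's choice and are fully overridable (`width_scale` or explicit
widths).

Activations are bounded rectified linear units
`h_{α,β}(x) = 1 if x ≥ β; (x−α)/(β−α) if α < x < β; 0 if x ≤ α`,
symmetric about 0.5 (|β−0.5| = |α−0.5|), initialized at (α, β) = (0, 1).
During training the half-width w = (β−α)/2 is reduced ("sharpening")
until the unit is a hard 0/1 threshold at 0.5 (at w = 0 the value at
exactly 0.5 is defined as 1).  Sharpening is adaptive: it starts at a
configurable epoch (default 20), advances the input-most unsharpened
layer by Δw = 0.01 per epoch, and pauses in any epoch where the relative
training-loss change over a 3-epoch patience window exceeds 5 % — the
pause protects accuracy by only narrowing units while optimization is
quiescent.  Cumulative sharpness is monotone
non-decreasing by construction.  A fully sharpened network emits only
{0,1} hidden activations on any input.

Input encoding: the padded time vector is scaled by 1/T_max into [0, 1]
and consumed as a length-L_max sequence of scalars by the recurrent
architectures (flattened for `snn7`).  Predictions are therefore
invariant to rescaling spike times and T_max together.

LSTM layers keep smooth sigmoid/tanh gates; only the layer's output
activation carries a bRELU state, applied to `o·tanh(c) + 0.5` so that a
sharpened unit spikes exactly when its signed output exceeds zero.  The
dense stack reads the **time-average** of the last recurrent layer's
spiking outputs — a firing-rate readout.  This matters: with the final
hidden state instead, the zero-padding tail (often ~100 steps) drives
the recurrent state to an input-independent fixed point and the readout
carries no information.

Training is plain NumPy: backpropagation(-through-time) with adadelta
(lr 0.05, ρ = 0.95, ε = 1e-6), batch size 128, 100 epochs at full scale.
Two numerical choices proved necessary for stable convergence of deep
stacks of bounded units and are on by default:

* **Mean-only batch normalization** on every dense/output layer:
  pre-activations are batch-centered, a learned offset (initialized to
  the bRELU midpoint 0.5) sets the operating point, and a debiased
  running mean is used at inference.  Without it, the feature means of
  the deep bounded stack wander faster than gradients restore them and
  validation accuracy oscillates between chance and ceiling.  Centering
  is a software bias at inference time, so crossbar mapping is
  unaffected.
* **Softmax decode for the loss**: the loss is the mean squared error
  between the softmax of the two output pre-activations and the one-hot
  target.  Direct MSE on the bounded outputs (available as
  `decode="direct"`) leaves the common offset of the two output units as
  a stiff, weakly damped direction under adadelta's constant-magnitude
  steps; the softmax is shift-invariant and removes that direction
  entirely.  Binary predictions are the argmax of the pre-threshold
  output activations either way (ties resolve to class 0 and are
  logged); ranking scores for AUC are the PD unit's pre-threshold
  activation.

Initialization: Glorot-uniform weights; the recurrent input projection
uses a 1/√fan_in limit because the first layer sees a single scalar per
step; forget-gate biases start at 1.  All randomness flows from the
training seed; two runs with equal seeds produce bit-identical weights.

## Evaluation (`evalkit`)

Confusion counts take PD as the positive class.
The ten derived measures (ACC, MCR, AUC, precision, recall/sensitivity,
specificity, FPR, FNR, F1, MCC) follow the textbook formulas; zero
denominators yield NaN and are flagged, never silently zeroed.  AUC is
the Mann–Whitney rank statistic on scores; without scores it is reported
undefined rather than fabricated.  Report tables round to 4 decimals.

**Timing noise.**  Robustness is probed by replacing every nonzero spike
time with `x = v + N(μ, σ)` (padding zeros untouched), clipping into
(0, T_max] — replacement, never deletion, so sample cardinality is
stable — and leaving entry order unsorted, as the perturbation operates
in place on the stored matrix.  Settings (μ, σ) ∈ {(7, 4), (15, 12),
(30, 25)} ms; noise applies to both partitions by default
(`applies_to` is configurable).  Noised values are
rounded to the 0.001 ms storage resolution so files round-trip exactly.

**Spectra.**  Spike trains are binned at 1 ms, smoothed with a Gaussian
spike-density kernel (σ = 5 ms, configurable; it attenuates the
harmonics of regular firing which would otherwise leak into band
comparisons — a perfect impulse comb has equal-power harmonics), and
analyzed with a Welch periodogram (1,000 ms windows, 50 % overlap).
Beta-band power is the trapezoidal integral over [13, 30] Hz; an empty
train has zero power.

## Crossbar inference (`xbar`)

Weights map onto differential pairs of conductance matrices: [0, max|W|]
maps linearly onto [1/R_off, 1/R_on]; positive entries program the
positive crossbar, negative magnitudes the negative one, idle cells rest
at the minimum conductance, whose offset cancels in the differential
current.  Each conductance is rounded to the nearest of 2^precision_bits
uniform levels, so per-weight reconstruction error is bounded by half an
LSB times the recorded scale.  Device defaults: R_on = 6 kΩ,
R_off = 150·R_on, 0.5 V read voltage, 2-bit precision, 128×128 subarrays
(an alternative 12 kΩ device is exercised in tests).  Inference applies activations (already in [0, 1]) as
read-voltage-scaled word-line inputs, computes bit-line currents tile by
tile with partial-current summation, and rescales by 1/(V_read·scale)
before the software bias/threshold stages — numerically identical to
software inference in the fine-quantization limit.  Tiling equals the
untiled differential product up to double-precision rounding of the
(strongly cancelling) current subtraction; tests anchor the tolerance to
the uncancelled current scale.  Stochastic device non-idealities (write
variation, drift, line resistance) are not modeled.  Hardware cost
estimation (area, latency, energy) requires an external
micro-architecture simulator and is out of scope.

## Problem sizes used by the shipped tests and acceptance script

Full-scale experiments use 30,000 samples (1,000 groups × 15 neurons ×
2 conditions) and 100 epochs.  The package's own experiments run a
documented desk scale, chosen once as the smallest configuration at which
the pipeline's behavior is unambiguous:

* classification: 4,000 samples (200 groups × 10 neurons per condition),
  25 epochs, halved widths, 3 seeds — validation accuracy at the 60-40
  and 75-25 splits;
* noise robustness: 1,500 samples, 15 epochs, quarter widths, 3 seeds
  per noise setting;
* biomarker checks: 200 samples per class per generator (the circuit
  generator pools 20 independently seeded simulations per state);
* crossbar agreement: 1,000 samples through a quarter-width feedforward
  detector at 8- and 16-bit quantization.

At desk scale the sharpening schedule (start epoch 20) has little time
to act before training ends; sharpening behavior is exercised separately
with aggressive schedules in unit tests.

## Known limitations

* The generators encode the two target biomarkers directly; passing
  tests show pipeline correctness under those statistics, not clinical
  detection performance on recorded MER/LFP data.
* The circuit model's PD mechanism is a tuned stand-in; its dopamine
  gains were set to reproduce the qualitative biomarkers, not fitted to
  rat recordings.
* Whetstone-style sharpening is defined for feedforward networks; the
  recurrent extension here (sharpening only each LSTM layer's output
  activation) is the minimal consistent one, and gate nonlinearities
  remain smooth even at full sharpness.
* AUC for a fully binarized network degenerates toward the accuracy of
  the binary outputs; scores are therefore taken pre-threshold.
* The held-out "shifted" test distribution (10-neuron groups, 0-2,000
  ms, same generator parameters) probes generalization across recording
  window and group size only; it does not capture cross-model shifts
  such as testing on data from a different simulator.
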