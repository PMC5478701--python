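# Methods

## The model

`erbp` simulates deep feed-forward spiking neural networks that learn
classification with an event-driven, error-modulated plasticity rule.  The
network has four neuron types:

* **Data (encoder) neurons.**  Stochastic spike-response units with an
  exponential hazard of the input intensity `d ∈ [0, 1]`:
  `ν_d = τ_refr⁻¹ exp(β d + γ)` with an absolute refractory period.  Pixel
  (feature) intensities become spike trains without any other preprocessing.

* **Hidden and prediction neurons.**  Two-compartment, current-based leaky
  integrate-and-fire units:

      C dV/dt = −g_V V + I + noise        (soma; spikes, reset to 0, hold
                                           at 0 for τ_refr after a spike)
      τ_syn dI/dt = −I + Σ_j w_ij s_j(t)  (shared linear synapse state)
      C dU/dt = −g_U U + feedback spikes  (dendrite; read only by learning)

  The dendritic potential `U` integrates spikes from the error-coding
  neurons — one-to-one with weight `w_E` for prediction neurons, through a
  fixed random matrix `G` with paired signs (`+g_ik` from the positive and
  `−g_ik` from the negative error neuron of class `k`) for hidden neurons.
  The paired signs make the summed feedback of each error pair exactly
  zero, so spontaneous error activity cannot bias learning.  `U` is never
  coupled to `V` except through the plasticity rule; zeroing it (and the
  feedback wiring) after training provably cannot change inference, which
  the test suite checks prediction-by-prediction.

* **Error-coding pairs.**  One pair of non-leaky integrate-and-fire
  neurons per class integrates the prediction/label spike difference with
  weight `±w_L`, fires on crossing `V_T_E` with a subtractive reset, and is
  floored at `−V_T_E`.  The pair rate-codes the signed error
  `ν_E+ − ν_E− ≈ ν_P − ν_L`.  Labels are supplied as a regular spike train
  at the refractory-bounded maximum rate `1/τ_refr` for the true class, so
  the implicit target is "fire at the ceiling for the true class, stay
  silent otherwise".

**The learning rule.**  On every presynaptic spike at a plastic synapse,

    w_ij ← w_ij − η U_i Θ(I_i),     Θ(I) = 1 iff b_min < I < b_max,

one addition and two comparisons per synapse.  The boxcar gate `Θ` is a
binary surrogate for the derivative of the refractory-bounded activation
function, evaluated on the total synaptic current.  The sign is descent:
`U` encodes the (randomly projected) error `Σ_k g_ik e_k`, and the update
moves against it.  Optionally every weight is confined to a fixed-point
grid (256 equally spaced values in [−0.5, 0.5] nA) with randomized
rounding, which is unbiased in expectation and keeps every stored weight on
the grid after every event.

**The analytic activation.**  Under a diffusion approximation (mean input
`μ`, stationary membrane noise `σ_OU`, `τ_m ≪ τ_syn`), the firing rate of
the noisy I&F neuron is

    ν(μ) = τ_refr⁻¹ · ½ (1 + erf(μ / (σ_OU √2))),

with `μ` measured in membrane units relative to threshold.  `σ_OU` is kept
as a free parameter of this oracle: the implemented noise is filtered shot
noise whose membrane-level variance has no exact closed form once
threshold, reset and the finite membrane time constant enter.

**The rate-based reference model.**  A conventional layered network with
activities normalized to [0, 1], squared-error loss, and three backward
passes: exact backpropagation (validated against central finite differences
to ≤ 1e-5 relative error), direct random feedback (the output error
projected to every hidden layer through fixed random matrices), and both
with an optional boxcar surrogate derivative.  It serves two roles: the
gradient oracle for alignment diagnostics, and the desk-scale stand-in for
batch-trained artificial-network baselines.

## Units and conventions

All quantities carry the configured physical units: pF, nS, mV, nA, ms.
With these units `nS·mV = pA`, so currents in nA are scaled by 1000 inside
the voltage equation.  A spike is a unit-area impulse carrying charge
`q = 1 nA·ms` per unit weight: through the synaptic filter it increments
`I` by `w·q/τ_syn` (exact integration of the filter), and at direct voltage
targets (error-neuron inputs, dendrites) it steps the potential by
`1000·w·q/C` mV — e.g. `w_L = 0.09 nA` moves an error membrane by 90 mV
against a 100 mV threshold, so roughly nine error spikes result from ten
unmatched label spikes.

Integration is forward Euler at `dt = 0.1 ms` (configurable), which
resolves the fastest time constant (`τ_m = 1 ms`; the dendritic leak
`C/g_U = 0.2 ms` is decay-only and unconditionally stable at this step).
Within a step the layers update in feed-forward order using same-step
spikes; error spikes reach the dendrites on the following step.  Spikes are
timestamped at the end of their step, and refractory holds guarantee
inter-spike intervals of at least `τ_refr` in every raster (asserted in
tests).

Background noise, when enabled (`σ_w > 0`), is a Poisson event stream
delivered through the standard synaptic filter like any other spike, with
per-step Poisson event counts so arbitrary rates are well defined.  Two
realizations exist: a single excitatory stream (which carries a mean
current `σ_w ν_bg q` in addition to its variance) and a balanced `±σ_w`
pair with exactly zero mean, matching the zero-mean white-noise term of the
diffusion analysis.  The single-signed realization is the default for
network simulations; the balanced one is used when validating the analytic
activation, where the mean must be controlled exactly.

## Default parameters

| symbol | value | meaning |
|---|---|---|
| C | 1 pF | membrane capacitance (soma and dendrite) |
| g_V / g_U | 1 / 5 nS | somatic / dendritic leak |
| V_T, V_T_E | 100 mV | firing thresholds |
| τ_refr | 3.9 ms (4.0 data) | absolute refractory period |
| τ_syn | 4 ms | synaptic time constant |
| w_E, w_L± | ±0.09 nA | error→prediction and prediction/label→error weights |
| b_min, b_max | ∓1.15 nA (±25 for a 2nd hidden block) | boxcar gate bounds |
| σ_w | 0.05 nA (additive mode), 0 (blank-out mode) | background noise weight |
| p | 0.45 (blank-out mode), 0 (additive) | transmission failure probability |
| η | 1e-3 nS (blank-out), 6e-4 (additive) | hidden-block learning rate |
| init | U(±√(num/(rows+cols))), num = 7 (blank-out) / 6 | weight initialization |
| presentation | 250 ms/sample, learning gated off for the first 50 ms | protocol |

The 50 ms plasticity gate after each sample onset covers the "loop
duration" — the delay until the error population settles after a stimulus
switch; `Network.measure_loop_duration` estimates it from an
onset-triggered average of the error-population rate (for the default
64-32-3 network it is a few milliseconds, set by the first label/error
spikes; it grows with depth).

## The synthetic task and what it does (not) show

The generator draws one random binary prototype per class (density 0.5
over 64 features) and emits samples as the prototype with independent
per-feature flips (probability 0.1), 60 training and 60 test samples,
balanced.  The Bayes rule of this generative model is nearest-prototype in
Hamming distance; its error (Monte-Carlo estimated) is numerically zero at
these settings, so trained accuracy is interpretable on an absolute scale.
The task emulates what the encoder assumes about image data — per-sample
intensity vectors in [0, 1] with integer labels — but not the correlated
pixel structure, class overlap or sample diversity of real image sets:
passing the learning checks here shows the rule, error pathway, decoders
and accounting work end to end at desk scale, not that benchmark-grade
accuracy would follow on full image datasets.

Two calibrations are task-level, mirroring how the image experiments were
set up (input intensities scaled per task; learning rates grid-searched per
task):

* **Encoder scaling.**  For the synthetic task the model facade uses
  `β = 4, γ = −3`, so zero-intensity features are nearly silent (~12 Hz
  hazard) and active features drive the encoder near its refractory bound
  (~180 Hz).  The published image-task constants (`β = 0.5, γ = −0.215`)
  remain the defaults of `EncoderParams` and `RunConfig`; at desk scale
  they leave a 1.3× rate contrast that is too weak to learn from in tens of
  epochs.

* **Per-block learning rate.**  At small layer counts the Glorot-scaled
  feedback bound `√(6/(N_E+N_H))` is ~0.40 nA while the prediction
  dendrites receive ±0.09 nA, so hidden dendritic errors are ~4× larger
  than output ones and the hidden code reorganizes faster than the readout
  can track — the diagnosed failure mode is a stable but wrongly permuted
  readout.  Feedback alignment needs the readout to adapt fastest; the
  output block therefore trains at `η_out = 3e-2 nS` while hidden blocks
  keep the published `1e-3`.  With this calibration the 64-32-3 blank-out
  network reaches 100% train/test accuracy on the task in ~10 epochs, and
  its final accuracy matches the rate-model direct-RBP reference trained on
  the same data.

## Numerical and design choices

* **Strict boxcar bounds** (`b_min < I < b_max`), exact values on the
  boundary gate to zero.
* **Randomized rounding** returns exact grid values unchanged; off-grid
  values round up with probability proportional to the fractional
  position.  Quantization is applied at initialization and immediately
  after every event-driven increment (the online rule has no batch
  boundary).
* **Blank-out noise** is applied to transmission only (independently per
  synapse and spike); plasticity triggers on all presynaptic spikes.  A
  flag can subject plasticity to the same mask.
* **Error-membrane floor** at `−V_T_E` (symmetric about zero).
* **State carry-over**: membranes, currents and dendrites persist across
  sample presentations (a continuous input stream); a config flag resets
  instead.  Label trains start at sample onset with phase 0.
* **Decoders**: spike counts in a window starting `2τ_syn` after onset
  (argmax, ties to the lowest index), or the first spike after `2τ_syn`
  with the counts decoder as fallback for silent rasters.
* **Operation accounting**: a SynOp is one delivered spike across one
  synapse (blanked transmissions do not count; error-pathway fan-out is
  included and can be excluded).  The rate model counts only
  matrix-multiply MACs (forward products plus backward projections, not
  weight updates).
* **Alignment diagnostics** compare realized per-epoch weight changes with
  the negative batch gradient of a "rate image" of the spiking network:
  same weights scaled by `q/τ_refr`, erf activation thresholded at
  `V_T g_V = 0.1 nA` with width `σ_c = 0.3 nA` (the scale of the observed
  synaptic-current fluctuations).  Angles start slightly above 90° under
  fresh random feedback and fall below 90° as the readout aligns — the
  feedback-alignment signature.

## Validation against the analytic activation, and a known limitation

The activation-curve experiment drives one neuron per grid point (nine
clamped mean currents spanning `[0, 2 V_T g_V]`, 10 s each, balanced
background noise) through the same integrator the network uses and compares
rates against the erf activation with matching mean and a single fitted
`σ_OU`.  The sub-threshold half of the curve agrees closely (the fitted
width also lands on the analytic shot-noise value, ~25 mV).  Above
threshold the simulation sits a uniform ~15% below the analytic ceiling:
after the reset-and-hold refractory period the membrane needs
`τ_m ln(V_ss/(V_ss − V_T))` to climb back to threshold, lengthening the
inter-spike interval to `τ_refr + τ_m ln 2` at twice-threshold drive — a
factor the diffusion-approximation rate does not model (it is exact only as
`τ_m/τ_refr → 0`).  The suite asserts a 10% per-point agreement bound and
therefore fails on the supra-threshold points by design; the deficit is
reproduced quantitatively by the closed-form inter-spike interval above,
which the unit tests assert instead.  This discrepancy has no bearing on
learning: the rule uses the boxcar gate, not the analytic derivative.

## Problem sizes

Default test and acceptance runs use the 64-32-3 network on the 60+60
sample task for 20 epochs (≈ 4.5 million integration steps), 10-second
single-neuron validations, 20 random networks for the gradient oracle,
10-sample runs for exact update accounting, 2-epoch quantized runs for grid
closure, and 200 fresh samples for the inference-invariance check.  These
sizes were chosen so the full validation recomputes from scratch in
minutes on one core while every check retains clear statistical margins.

## Known limitations

* Clock-driven integration: event times are quantized to `dt`; exact
  event-driven integration is not implemented.
* The analytic erf activation is an approximation (see above); `σ_OU` is
  not derived from first principles.
* Only feed-forward dense architectures; one error-coding layer; no
  convolutions, recurrence, momentum or learning-rate schedules.
* The EMNIST-style class merging used for letter datasets is out of scope;
  the IDX reader accepts any label alphabet.
* Full image-benchmark reproduction requires external data and long runs;
  the CLI accepts IDX files for such experiments but no benchmark figures
  are claimed.
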