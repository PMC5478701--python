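# erbp — event-driven random backpropagation in spiking networks

`erbp` is a simulator for deep feed-forward spiking neural networks that
learn classification with a local, event-driven plasticity rule, together
with a rate-based backpropagation reference model that serves as its
gradient oracle.  It is written for computational neuroscientists and
neuromorphic-hardware researchers who want to study how error-driven
learning can run on spiking substrates where only additions, comparisons
and spike events are available.

## The model in brief

Networks are built from two-compartment leaky integrate-and-fire neurons
(pF/nS/mV/nA/ms units throughout):

    C dV/dt = −g_V V + I(t) + noise          somatic potential → spikes
    τ_syn dI/dt = −I + Σ_j w_ij s_j(t)       shared synaptic current
    C dU/dt = −g_U U + error feedback        dendritic error store

One pair of non-leaky integrate-and-fire neurons per class rate-codes the
signed difference between prediction and label spike trains,
`ν_E+ − ν_E− ≈ ν_P − ν_L`.  Their spikes reach prediction dendrites
one-to-one (weight `w_E`) and hidden dendrites through a *fixed random*
matrix with paired signs — direct random feedback instead of transposed
weights.  Every presynaptic spike at a plastic synapse triggers

    Δw_ij = −η · U_i · Θ(I_i),    Θ(I) = 1  iff  b_min < I < b_max,

one addition and two comparisons per synaptic update.  The boxcar `Θ`
stands in for the derivative of the refractory-bounded activation
`ν(μ) = τ_refr⁻¹ ½(1 + erf(μ/σ_OU√2))`.  Two stochastic variants are
built in: additive background Poisson noise, and multiplicative "blank-out"
synapses that drop each transmission with probability `p = 0.45` (the
better-performing default).  Weights can be confined to a 256-level
fixed-point grid with unbiased randomized rounding.

The companion rate model implements exact backprop, direct random feedback
(RBP), and boxcar-surrogate variants on normalized activities, and is
validated against central finite differences.

## Worked example

Train the spiking classifier on the built-in synthetic task (3 random
binary prototypes over 64 features with 10% feature flips; 60 train / 60
test samples) and compare with the rate-model RBP reference:

```python
from erbp import ErbpClassifier, RateClassifier
from erbp.datasets import PrototypeTaskSpec, make_prototype_task

train, test = make_prototype_task(PrototypeTaskSpec())
res = ErbpClassifier(train, hidden=(32,)).fit(
    epochs=12, seed=0, test_data=test, snapshot_every=1)
print(res.summary())
```

prints

```
Event-driven RBP spiking classifier
=============================================
architecture      64-32-3
noise mode        blankout (p=0.45)
learning rate     0.001/0.03 nS
quantized         False
epochs / seed     12 / 0
decoder           counts
---------------------------------------------
train error       0.0000
test error        0.0167
SynOps            23,986,926
update events     27,803,377
=============================================
```

The network classifies every training sample and 59/60 test samples
correctly after twelve 250 ms presentations per sample per epoch, having
delivered ~24 million synaptic operations (spike × synapse events) and
evaluated ~28 million candidate one-addition weight updates.  The
rate-model reference on the same data
(`RateClassifier(train, hidden=(32,), rule="rbp").fit(epochs=20, seed=0,
test_data=test)`) reaches train/test error 0.0000/0.0000 with 2.7 million
MACs — the spiking network matches its accuracy.

`res.alignment(block=0)` returns the per-epoch angle between the realized
data→hidden weight updates and the true backpropagated gradient evaluated
at matched weights; in the run above it falls from ~88–92° to 82° over
twelve epochs — the feedback-alignment signature: random feedback starts
uninformative and the network aligns its forward weights to it.

A command-line interface wraps the same machinery:

    erbp train --config cfg.yaml --out run/     # logs, weights.h5, manifest
    erbp simulate-neuron                        # f-I curve vs analytic rate
    erbp make-data --out data/                  # synthetic task as IDX files
    erbp align                                  # angle diagnostics

`erbp train` also accepts MNIST-format IDX files via the config
(`dataset: idx`).

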