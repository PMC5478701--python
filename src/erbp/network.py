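"""Network assembly and the training/evaluation protocol.

A network is a stack of feed-forward layers (data encoder, one or two hidden
layers, prediction layer) plus one pair of error-coding neurons per class.
Label neurons emit a regular spike train at the refractory-bounded maximum
rate for the true class; the error pairs integrate the prediction/label
difference; their spikes are broadcast to the dendritic compartments --
one-to-one with weight ``w_E`` onto prediction neurons, and through a fixed
random matrix with paired signs onto hidden neurons.  Plasticity is the
event-driven rule in :mod:`erbp.plasticity`, disabled during the first
``learn_gate_delay`` ms of each sample presentation while the error loop
settles.

Samples are presented as a continuous stream: membrane, current and dendrite
states carry over between samples by default, as they would on always-on
neuromorphic hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neurons import (
    PA_PER_NA,
    Q_SPIKE,
    EncoderParams,
    LayerState,
    NeuronParams,
    encode_input,
    step_error_layer,
    step_two_compartment_layer,
)
from .plasticity import FeedbackWiring, QuantSpec, SynapseBlock, erbp_apply, init_weights

_EMPTY_IDX = np.empty(0, dtype=np.intp)

__all__ = [
    "NetworkSpec",
    "PresentationProtocol",
    "SpikeRaster",
    "Network",
    "build_network",
]


@dataclass(frozen=True)
class PresentationProtocol:
    """Timing of the sample-presentation protocol (all times in ms)."""

    sample_duration: float = 250.0
    learn_gate_delay: float = 50.0
    test_duration: float = 250.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.learn_gate_delay < self.sample_duration:
            raise ValueError("learn_gate_delay must lie in [0, sample_duration)")


@dataclass
class NetworkSpec:
    """Architecture and parameters of a spiking classifier network."""

    layer_sizes: list[int]
    params: NeuronParams = field(default_factory=NeuronParams)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    #: learning rate in nS; a scalar is shared by all blocks, a sequence
    #: gives one rate per block (readouts typically need a faster rate than
    #: hidden blocks at small network scale)
    eta: float | list[float] = 1e-3
    init_numerator: float = 7.0
    gate_bounds: list[tuple[float, float]] | None = None
    w_E: float = 0.09
    w_L: float = 0.09
    blankout_p: float = 0.45
    quantizer: QuantSpec | None = None
    carry_state: bool = True
    #: if True the blank-out mask also gates plasticity triggering
    blankout_gates_plasticity: bool = False

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 3:
            raise ValueError("need at least [data, hidden, prediction] layers")
        if any(n <= 0 for n in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.gate_bounds is None:
            # wider gate for the block into a second hidden layer
            bounds = []
            n_blocks = len(self.layer_sizes) - 1
            for b in range(n_blocks):
                wide = n_blocks >= 3 and b == 1
                bounds.append((-25.0, 25.0) if wide else (-1.15, 1.15))
            self.gate_bounds = bounds
        if len(self.gate_bounds) != len(self.layer_sizes) - 1:
            raise ValueError("gate_bounds must list one (b_min, b_max) per block")

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layer_sizes) - 2


class SpikeRaster:
    """Timestamped spike events per layer: lists of (time ms, neuron index)."""

    def __init__(self, layers: list[str] | None = None):
        self.events: dict[str, list[tuple[float, int]]] = {
            name: [] for name in (layers or [])
        }

    def add(self, layer: str, t: float, idx: np.ndarray) -> None:
        ev = self.events.setdefault(layer, [])
        ev.extend((t, int(i)) for i in idx)

    def layer_array(self, layer: str) -> np.ndarray:
        """Events of one layer as an (n, 2) array of (time, neuron)."""
        ev = self.events.get(layer, [])
        if not ev:
            return np.empty((0, 2))
        return np.asarray(ev, dtype=np.float64)

    def counts(self, layer: str, window: tuple[float, float], n: int) -> np.ndarray:
        """Per-neuron spike counts inside ``[t0, t1)``."""
        arr = self.layer_array(layer)
        out = np.zeros(n, dtype=np.int64)
        if arr.shape[0]:
            t0, t1 = window
            sel = (arr[:, 0] >= t0) & (arr[:, 0] < t1)
            np.add.at(out, arr[sel, 1].astype(np.intp), 1)
        return out

    def min_isi(self, layer: str) -> float:
        """Smallest inter-spike interval of any neuron in the layer."""
        arr = self.layer_array(layer)
        best = np.inf
        if arr.shape[0]:
            for i in np.unique(arr[:, 1]):
                t = arr[arr[:, 1] == i, 0]
                if t.shape[0] > 1:
                    best = min(best, float(np.diff(np.sort(t)).min()))
        return best

    def to_frame(self, layer: str) -> pd.DataFrame:
        arr = self.layer_array(layer)
        return pd.DataFrame(
            {"time_ms": arr[:, 0], "neuron_id": arr[:, 1].astype(int)}
        )


class Network:
    """A spiking classifier with event-driven plasticity.

    Build with :func:`build_network`.  The network owns all layer states,
    synapse blocks, feedback wiring, random streams and operation counters.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        init_ss, sim_ss, shuffle_ss, quant_ss = ss.spawn(4)
        init_rng = np.random.default_rng(init_ss)
        self.rng = np.random.default_rng(sim_ss)
        self.shuffle_rng = np.random.default_rng(shuffle_ss)
        self.quant_rng = np.random.default_rng(quant_ss)

        sizes = spec.layer_sizes
        n_blocks = len(sizes) - 1
        etas = (
            list(spec.eta)
            if isinstance(spec.eta, (list, tuple))
            else [spec.eta] * n_blocks
        )
        if len(etas) != n_blocks:
            raise ValueError("need one learning rate per synapse block")
        self.blocks: list[SynapseBlock] = []
        for b in range(n_blocks):
            W = init_weights(sizes[b + 1], sizes[b], spec.init_numerator, init_rng)
            blk = SynapseBlock(
                W=W,
                plastic=True,
                eta=etas[b],
                b_min=spec.gate_bounds[b][0],
                b_max=spec.gate_bounds[b][1],
                blankout_p=spec.blankout_p,
                quantizer=spec.quantizer,
            )
            blk.quantize_all(self.quant_rng)
            self.blocks.append(blk)

        self.feedback: list[FeedbackWiring] = [
            FeedbackWiring.glorot(sizes[1 + h], spec.n_classes, init_rng)
            for h in range(spec.n_hidden_layers)
        ]
        self.feedback_enabled = True
        self.dendrites_enabled = True

        # dynamical state
        self.layer_states: list[LayerState] = [
            LayerState.zeros(n) for n in sizes[1:]
        ]
        self.error_state = LayerState.zeros(spec.n_classes)
        self.data_last_spike = np.full(sizes[0], -np.inf)
        self._t = 0.0  # global simulation clock, ms
        self._prev_err = (
            np.zeros(spec.n_classes, dtype=bool),
            np.zeros(spec.n_classes, dtype=bool),
        )

        self.synops = 0
        self.synops_error = 0
        self.update_events = 0
        self.layer_names = (
            ["data"]
            + [f"hidden{h}" for h in range(spec.n_hidden_layers)]
            + ["prediction", "error_pos", "error_neg", "label"]
        )

    # ------------------------------------------------------------------ utils

    def reset_state(self) -> None:
        """Hard-reset all dynamical state (weights are kept)."""
        self.layer_states = [LayerState.zeros(n) for n in self.spec.layer_sizes[1:]]
        self.error_state = LayerState.zeros(self.spec.n_classes)
        self.data_last_spike = np.full(self.spec.layer_sizes[0], -np.inf)
        self._t = 0.0
        self._prev_err = (
            np.zeros(self.spec.n_classes, dtype=bool),
            np.zeros(self.spec.n_classes, dtype=bool),
        )

    def zero_dendrites(self, disable_feedback: bool = True) -> None:
        """Zero all dendritic compartments and optionally cut error feedback.

        The dendrite is read only by the plasticity rule, so with learning
        off this never changes somatic dynamics or predictions.
        """
        for st in self.layer_states:
            st.U[:] = 0.0
        if disable_feedback:
            self.feedback_enabled = False
            self.dendrites_enabled = False

    def weight_snapshot(self) -> list[np.ndarray]:
        return [blk.W.copy() for blk in self.blocks]

    # ------------------------------------------------------------- simulation

    def _transmit(self, block_idx: int, pre_spike_idx: np.ndarray) -> np.ndarray:
        """Feed-forward current increments (nA) from this step's pre spikes.

        Applies per-synapse blank-out to transmission and counts SynOps for
        every delivered (non-blanked) spike-synapse event.
        """
        blk = self.blocks[block_idx]
        if pre_spike_idx.size == 0:
            return 0.0
        Wcols = blk.W[:, pre_spike_idx]
        if blk.blankout_p > 0.0:
            mask = self.rng.random(Wcols.shape) >= blk.blankout_p
            self.synops += int(mask.sum())
            return (Wcols * mask).sum(axis=1) * (Q_SPIKE / self.spec.params.tau_syn)
        self.synops += Wcols.size
        return Wcols.sum(axis=1) * (Q_SPIKE / self.spec.params.tau_syn)

    def run_sample(
        self,
        intensities: np.ndarray,
        label: int | None,
        protocol: PresentationProtocol,
        learn: bool = False,
        record: bool | set[str] = False,
        duration: float | None = None,
        step_hook=None,
    ) -> tuple[SpikeRaster, int]:
        """Present one sample for ``duration`` ms (default sample_duration).

        When ``label`` is given, the label neuron of the true class fires a
        regular train with one spike per refractory period, phase 0 at
        onset.  Plasticity runs only when ``learn`` is set and at least
        ``learn_gate_delay`` ms have elapsed since onset.  Returns the
        raster (empty unless ``record``) and the number of candidate weight
        update events during the presentation.

        ``step_hook(t_rel, spikes_by_layer, states, learning_active)`` is
        called once per step after the dynamics update and before
        plasticity; it exists for diagnostics and independent accounting.
        """
        spec = self.spec
        intensities = np.asarray(intensities, dtype=np.float64)
        if intensities.shape[0] != spec.layer_sizes[0]:
            raise ValueError("intensities do not match the data layer size")
        if label is not None and not 0 <= label < spec.n_classes:
            raise ValueError(f"label {label} out of range")
        if not spec.carry_state:
            self.reset_state()

        dt = protocol.dt
        dur = protocol.sample_duration if duration is None else duration
        n_steps = int(round(dur / dt))
        label_period_steps = max(1, int(round(spec.params.tau_refr / dt)))
        raster = SpikeRaster(self.layer_names)
        params = spec.params
        n_cls = spec.n_classes
        dend_gain = PA_PER_NA * Q_SPIKE / params.C  # mV per nA of spike weight
        updates = 0
        t0 = self._t
        pos_prev, neg_prev = self._prev_err

        # encoder: hazard is fixed for the whole presentation, pre-draw the
        # Bernoulli field once (same law as stepwise draws)
        hazard = (
            np.exp(spec.encoder.beta * intensities + spec.encoder.gamma)
            / spec.encoder.tau_refr
        )
        p_spike = np.minimum(1.0, hazard * dt)
        enc_draws = self.rng.random((n_steps, intensities.shape[0]))
        enc_refr = spec.encoder.tau_refr
        data_last = self.data_last_spike

        states = self.layer_states
        blocks = self.blocks
        n_hidden = spec.n_hidden_layers
        gate = protocol.learn_gate_delay
        err_fan = sum(g.G.shape[0] for g in self.feedback) + 1
        no_err = np.zeros(n_cls, dtype=bool)
        hidden_names = [f"hidden{h}" for h in range(n_hidden)]
        pos = neg = no_err
        if record is True:
            rec_layers = set(self.layer_names)
        elif record:
            rec_layers = set(record)
        else:
            rec_layers = None

        for k in range(n_steps):
            t_rel = k * dt
            t = t0 + t_rel
            learning = learn and (t_rel >= gate)

            data_spikes = (enc_draws[k] < p_spike) & (t - data_last >= enc_refr)
            if data_spikes.any():
                data_last[data_spikes] = t
                prev_idx = data_spikes.nonzero()[0]
            else:
                prev_idx = _EMPTY_IDX
            spikes_by_layer = [data_spikes]

            if self.feedback_enabled and (pos_prev is not no_err) and (
                pos_prev.any() or neg_prev.any()
            ):
                err_diff = pos_prev.astype(np.float64) - neg_prev
            else:
                err_diff = None
            for li, st in enumerate(states):
                ff = self._transmit(li, prev_idx)
                if err_diff is not None and self.dendrites_enabled:
                    if li < n_hidden:
                        err_charge = dend_gain * (self.feedback[li].G @ err_diff)
                    else:  # prediction layer: one-to-one error wiring
                        err_charge = (dend_gain * spec.w_E) * err_diff
                else:
                    err_charge = 0.0
                st, sp = step_two_compartment_layer(
                    st, ff, err_charge, params, t, dt, self.rng
                )
                spikes_by_layer.append(sp)
                prev_idx = sp.nonzero()[0] if sp.any() else _EMPTY_IDX
            pred_spikes = spikes_by_layer[-1]

            has_label = label is not None and k % label_period_steps == 0
            if has_label or pred_spikes.any():
                label_spikes = np.zeros(n_cls, dtype=bool)
                if has_label:
                    label_spikes[label] = True
                self.error_state, pos, neg = step_error_layer(
                    self.error_state, pred_spikes, label_spikes, spec.w_L,
                    params, dt,
                )
                n_err = int(pos.sum() + neg.sum())
                if n_err:
                    self.synops_error += n_err * err_fan
            else:
                label_spikes = no_err
                pos = neg = no_err

            if step_hook is not None:
                step_hook(t_rel, spikes_by_layer, states, learning)

            if learning:
                for li, st in enumerate(states):
                    pre = spikes_by_layer[li]
                    if blocks[li].plastic and pre.any():
                        _, n_ev = erbp_apply(
                            blocks[li], pre.nonzero()[0], st.U, st.I,
                            self.quant_rng,
                        )
                        updates += n_ev

            if rec_layers is not None:
                if "data" in rec_layers and data_spikes.any():
                    raster.add("data", t_rel, data_spikes.nonzero()[0])
                for h in range(n_hidden):
                    sp = spikes_by_layer[1 + h]
                    if hidden_names[h] in rec_layers and sp.any():
                        raster.add(hidden_names[h], t_rel, sp.nonzero()[0])
                if "prediction" in rec_layers and pred_spikes.any():
                    raster.add("prediction", t_rel, pred_spikes.nonzero()[0])
                if "error_pos" in rec_layers and pos.any():
                    raster.add("error_pos", t_rel, pos.nonzero()[0])
                if "error_neg" in rec_layers and neg.any():
                    raster.add("error_neg", t_rel, neg.nonzero()[0])
                if "label" in rec_layers and label_spikes.any():
                    raster.add("label", t_rel, label_spikes.nonzero()[0])

            pos_prev, neg_prev = pos, neg

        self._prev_err = (pos_prev.copy(), neg_prev.copy())
        self._t = t0 + n_steps * dt
        self.update_events += updates
        return raster, updates

    # ----------------------------------------------------------- train / eval

    def train(
        self,
        dataset,
        epochs: int,
        protocol: PresentationProtocol,
        snapshot_every: int | None = None,
        test_dataset=None,
        eval_every: int | None = None,
        decoder: str = "counts",
        verbose: bool = False,
    ) -> pd.DataFrame:
        """Run the online training protocol.

        Every epoch presents each sample once in a freshly shuffled order.
        The log records, per epoch, the online training accuracy (decoded
        from the prediction raster while learning), cumulative SynOp and
        update counts, and -- when requested -- a held-out test error.
        Weight snapshots of every block are stored in ``self.snapshots``
        each ``snapshot_every`` epochs.
        """
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        rows = []
        self.snapshots: list[list[np.ndarray]] = []
        if snapshot_every:
            self.snapshots.append(self.weight_snapshot())
        window = (protocol.learn_gate_delay, protocol.sample_duration)
        for epoch in range(epochs):
            order = self.shuffle_rng.permutation(len(dataset))
            correct = 0
            for i in order:
                x, y = dataset[int(i)]
                raster, _ = self.run_sample(
                    x, int(y), protocol, learn=True, record={"prediction"}
                )
                c = raster.counts("prediction", window, self.spec.n_classes)
                if int(np.argmax(c)) == int(y):
                    correct += 1
            row = {
                "epoch": epoch + 1,
                "train_acc_online": correct / len(dataset),
                "synops": self.synops + self.synops_error,
                "updates": self.update_events,
            }
            if test_dataset is not None and eval_every and (epoch + 1) % eval_every == 0:
                row["test_err"] = self.evaluate(test_dataset, protocol, decoder)
            rows.append(row)
            if snapshot_every and (epoch + 1) % snapshot_every == 0:
                self.snapshots.append(self.weight_snapshot())
            if verbose:
                print(f"epoch {epoch + 1}: {row}")
        return pd.DataFrame(rows)

    def evaluate(
        self,
        dataset,
        protocol: PresentationProtocol,
        decoder: str = "counts",
    ) -> float:
        """Fraction misclassified with learning off (labels withheld)."""
        from .metrics import classify_by_counts, classify_by_first_spike

        n_wrong = 0
        t_settle = 2.0 * self.spec.params.tau_syn
        for x, y in dataset:
            raster, _ = self.run_sample(
                x, None, protocol, learn=False, record={"prediction"},
                duration=protocol.test_duration,
            )
            if decoder == "first_spike":
                pred = classify_by_first_spike(raster, t_settle, self.spec.n_classes)
            elif decoder == "counts":
                pred = classify_by_counts(
                    raster, (t_settle, protocol.test_duration), self.spec.n_classes
                )
            else:
                raise ValueError(f"unknown decoder {decoder!r}")
            if pred != int(y):
                n_wrong += 1
        return n_wrong / len(dataset)

    def predict(self, x: np.ndarray, protocol: PresentationProtocol,
                decoder: str = "counts") -> int:
        """Class prediction for a single sample (learning off)."""
        from .metrics import classify_by_counts, classify_by_first_spike

        raster, _ = self.run_sample(
            x, None, protocol, learn=False, record=True,
            duration=protocol.test_duration,
        )
        t_settle = 2.0 * self.spec.params.tau_syn
        if decoder == "first_spike":
            return classify_by_first_spike(raster, t_settle, self.spec.n_classes)
        return classify_by_counts(
            raster, (t_settle, protocol.test_duration), self.spec.n_classes
        )

    def measure_loop_duration(
        self,
        intensities: np.ndarray,
        label: int,
        protocol: PresentationProtocol,
        window_ms: float = 20.0,
        step_ms: float = 2.5,
        n_repeats: int = 20,
    ) -> float:
        """Delay from sample onset until error-layer activity stabilizes.

        Presents the sample ``n_repeats`` times from a silent network state
        (an onset-triggered average) and computes the error-pair population
        rate in a sliding window wide enough to wash out the label-train
        periodicity.  Returns the earliest time from which the rate stays
        within 25% of the tail plateau (with a Poisson floor).  Finite and
        below the sample duration whenever the error loop settles.
        """
        times = []
        for _ in range(n_repeats):
            self.reset_state()
            raster, _ = self.run_sample(
                intensities, label, protocol, learn=False,
                record={"error_pos", "error_neg"},
            )
            for layer in ("error_pos", "error_neg"):
                arr = raster.layer_array(layer)
                if arr.shape[0]:
                    times.append(arr[:, 0])
        if not times:
            return float(protocol.sample_duration)
        times = np.concatenate(times)
        starts = np.arange(0.0, protocol.sample_duration - window_ms, step_ms)
        rate = np.array([
            np.count_nonzero((times >= s) & (times < s + window_ms))
            for s in starts
        ]) / n_repeats
        tail = rate[len(rate) // 2:]
        plateau = tail.mean()
        band = max(0.25 * plateau, 3.0 * np.sqrt(max(plateau, 1.0) / n_repeats))
        settle_windows = max(1, int(round(window_ms / step_ms)))
        first_spike = float(times.min())
        for b in range(len(rate) - settle_windows + 1):
            if np.all(np.abs(rate[b:b + settle_windows] - plateau) <= band):
                # settled once the rate has entered the plateau band and
                # stayed there for a full window; never earlier than the
                # first error spike of the loop
                return float(max(starts[b], first_spike))
        return float(protocol.sample_duration)


def build_network(spec: NetworkSpec, seed: int) -> Network:
    """Assemble a network: weights, feedback wiring and fresh state.

    Deterministic given ``seed``; the feedback wiring satisfies the
    zero-sum-per-pair invariant by construction (asserted here).
    """
    net = Network(spec, seed)
    for fb in net.feedback:
        assert np.all(fb.pair_sum == 0.0)
    return net
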