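"""Decoding, operation accounting and alignment diagnostics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neurons import Q_SPIKE
from .ratenet import RateNet, backward_bp, forward

__all__ = [
    "OpCounter",
    "classify_by_counts",
    "classify_by_first_spike",
    "count_synops",
    "alignment_angle",
    "rate_image",
    "encoder_rate_activity",
    "erbp_alignment_series",
]


@dataclass
class OpCounter:
    """Cumulative operation counts; monotone nondecreasing over a run.

    ``synops``: delivered spike-synapse events in the spiking network;
    ``macs``: multiply-accumulates in the rate network (matrix products
    only); ``updates``: candidate weight-update events.
    """

    synops: int = 0
    macs: int = 0
    updates: int = 0

    def add(self, synops: int = 0, macs: int = 0, updates: int = 0) -> None:
        if min(synops, macs, updates) < 0:
            raise ValueError("operation counts only increase")
        self.synops += synops
        self.macs += macs
        self.updates += updates


def classify_by_counts(
    raster, window: tuple[float, float], n_classes: int
) -> int:
    """Argmax of prediction-layer spike counts in the window.

    Ties (including the all-silent raster) resolve to the lowest index.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty decoding window")
    counts = raster.counts("prediction", window, n_classes)
    return int(np.argmax(counts))


def classify_by_first_spike(raster, t_min: float, n_classes: int) -> int:
    """Index of the prediction neuron spiking earliest at time >= t_min.

    The first spike after two synaptic time constants from onset is the
    low-latency readout; ties at the identical earliest time resolve to the
    lowest index, and a raster with no qualifying spike falls back to the
    counts decoder over [t_min, inf).
    """
    if t_min < 0:
        raise ValueError("t_min must be >= 0")
    arr = raster.layer_array("prediction")
    if arr.shape[0]:
        sel = arr[arr[:, 0] >= t_min]
        if sel.shape[0]:
            earliest = sel[:, 0].min()
            winners = sel[sel[:, 0] == earliest, 1].astype(int)
            return int(winners.min())
    return classify_by_counts(raster, (t_min, np.inf), n_classes)


def count_synops(net, raster, include_error: bool = True) -> int:
    """Synaptic operations implied by a raster at unit transmission.

    Every recorded spike counts once per outgoing synapse of its emitter
    (data and hidden spikes fan out through the next feed-forward block;
    error spikes reach every hidden dendrite they wire to plus their
    prediction neuron).  Blank-out is not replayed here: with transmission
    failures the network's own delivered-SynOp counter is binomially
    thinned relative to this count.
    """
    sizes = net.spec.layer_sizes
    names = ["data"] + [f"hidden{h}" for h in range(net.spec.n_hidden_layers)]
    total = 0
    for b, name in enumerate(names):
        if name not in raster.events and raster.layer_array(name).shape[0] == 0:
            continue
        n_spikes = raster.layer_array(name).shape[0]
        total += n_spikes * sizes[b + 1]
    if include_error:
        fan = sum(g.G.shape[0] for g in net.feedback) + 1
        for name in ("error_pos", "error_neg"):
            total += raster.layer_array(name).shape[0] * fan
    return int(total)


def alignment_angle(g1: np.ndarray, g2: np.ndarray) -> float:
    """Angle between two flattened directions, in degrees [0, 180]."""
    g1 = np.asarray(g1, dtype=np.float64).ravel()
    g2 = np.asarray(g2, dtype=np.float64).ravel()
    if g1.shape != g2.shape:
        raise ValueError("directions must have equal length")
    n1, n2 = np.linalg.norm(g1), np.linalg.norm(g2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero vector has no direction")
    c = np.clip(np.dot(g1, g2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


# ------------------------------------------------- spiking-to-rate bridging


def encoder_rate_activity(intensities: np.ndarray, encoder, tau_norm: float) -> np.ndarray:
    """Normalized steady-state data-layer activity for a sample.

    A hazard ``h`` with absolute refractory period fires at ``1/(tau_refr +
    1/h)``; activity is that rate times ``tau_norm`` (the network refractory
    period), giving the [0, 1] activity scale of the rate model.
    """
    from .datasets import scale_for_encoder

    h = scale_for_encoder(intensities, encoder.beta, encoder.gamma, encoder.tau_refr)
    rate = 1.0 / (encoder.tau_refr + 1.0 / h)
    return rate * tau_norm


def rate_image(weights: list[np.ndarray], net_spec, sigma_c: float = 0.3) -> RateNet:
    """Rate-model image of a spiking network at matched weights.

    Mean input current to a spiking neuron is ``mu = sum_j w_ij q nu_j``
    (nA); with normalized activities ``y = nu tau_refr`` this is
    ``sum_j (w_ij q / tau_refr) y_j``, thresholded at ``V_T g_V`` and
    smoothed over ``sigma_c`` (nA, the current-scale image of the membrane
    noise SD).  Used to evaluate true backpropagated gradients at the
    spiking network's weights.
    """
    p = net_spec.params
    scale = Q_SPIKE / p.tau_refr
    ws = [W * scale for W in weights]
    n_cls = net_spec.n_classes
    gs = [np.zeros((W.shape[0], n_cls)) for W in ws[:-1]]
    return RateNet(
        weights=ws,
        feedback=gs,
        activation="erf",
        derivative="exact",
        sigma=sigma_c,
        theta=p.V_T * p.g_V * 1e-3,  # nA
    )


def erbp_alignment_series(
    snapshots: list[list[np.ndarray]],
    dataset,
    net_spec,
    block: int = 0,
    sigma_c: float = 0.3,
) -> pd.DataFrame:
    """Angle between per-epoch eRBP update directions and true BP gradients.

    For consecutive weight snapshots the realized update direction of one
    block is ``W[k+1] - W[k]``; the reference direction is the negative
    batch gradient of the squared-error loss in the rate image of the
    network at ``W[k]``.  Angles below 90 degrees mean the event-driven
    random-feedback updates descend the true cost.
    """
    rows = []
    for k in range(len(snapshots) - 1):
        img = rate_image(snapshots[k], net_spec, sigma_c)
        grad = [np.zeros_like(W) for W in img.weights]
        for x, y in dataset:
            inp = encoder_rate_activity(x, net_spec.encoder, net_spec.params.tau_refr)
            ys, pre = forward(img, inp)
            target = np.zeros(net_spec.n_classes)
            target[int(y)] = 1.0
            g = backward_bp(img, ys, pre, ys[-1] - target)
            for gi, gg in zip(grad, g):
                gi += gg
        delta = snapshots[k + 1][block] - snapshots[k][block]
        if np.linalg.norm(delta) == 0.0 or np.linalg.norm(grad[block]) == 0.0:
            angle = np.nan
        else:
            angle = alignment_angle(delta, -grad[block])
        rows.append({"epoch": k + 1, "angle_deg": angle})
    return pd.DataFrame(rows)


def ops_error_curves(
    spiking_log: pd.DataFrame, rate_log: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """(operations, test-error) curves for matched spiking and rate runs.

    Expects per-epoch logs with cumulative operation columns (``synops`` /
    ``macs``) and a ``test_err`` column; rows without a test error are
    dropped.
    """
    out = {}
    for name, log, col in (("spiking", spiking_log, "synops"),
                           ("rate", rate_log, "macs")):
        if col not in log.columns or "test_err" not in log.columns:
            raise ValueError(f"{name} log must have '{col}' and 'test_err'")
        cur = log.dropna(subset=["test_err"])[[col, "test_err"]]
        out[name] = cur.rename(columns={col: "operations"}).reset_index(drop=True)
    return out
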