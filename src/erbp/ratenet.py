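"""Non-spiking reference network: BP, feedback-alignment RBP, and the
boxcar-surrogate variants, with an I&F-matched activation.

This model is the package's gradient oracle.  Its exact backward pass is
validated against finite differences, and its random-feedback variant is the
desk-scale stand-in for the batch-trained artificial-network baselines that
the spiking network is compared against.

Activities are scalar rates normalized to [0, 1] (a spiking-layer rate times
its refractory period), targets are one-hot vectors, and the cost is the
squared error ``L = 1/2 sum_i (y_i - l_i)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = ["RateNet", "LossState", "forward", "backward_bp", "backward_rbp",
           "sgd_step", "loss_and_error"]


@dataclass
class RateNet:
    """Layered rate network with fixed random direct feedback.

    ``weights[l]`` maps layer ``l`` activity to layer ``l+1`` pre-activation
    (shape post x pre); ``feedback[h]`` (hidden x outputs) carries the output
    error straight to hidden layer ``h`` with no layer-to-layer recursion.
    ``activation`` is ``"erf"`` (normalized, ``phi(0) = 1/2``) or
    ``"relu_sat"`` (linear threshold with saturation at 1); ``derivative``
    selects the exact ``phi'`` or the boxcar surrogate evaluated on the
    total input.
    """

    weights: list[np.ndarray]
    feedback: list[np.ndarray]
    activation: str = "erf"
    derivative: str = "exact"
    sigma: float = 1.0
    theta: float = 0.0
    boxcar: tuple[float, float] = (-1.15, 1.15)
    #: include phi' at the output layer; when False only the raw error is
    #: used there, mirroring the spiking rule's output update
    output_derivative: bool = True

    def __post_init__(self) -> None:
        for l in range(len(self.weights) - 1):
            if self.weights[l + 1].shape[1] != self.weights[l].shape[0]:
                raise ValueError("weight shapes do not chain")
        if len(self.feedback) != len(self.weights) - 1:
            raise ValueError("need one feedback matrix per hidden layer")
        n_out = self.weights[-1].shape[0]
        for h, G in enumerate(self.feedback):
            if G.shape != (self.weights[h].shape[0], n_out):
                raise ValueError(f"feedback matrix {h} has wrong shape")
        if self.activation not in ("erf", "relu_sat"):
            raise ValueError("activation must be 'erf' or 'relu_sat'")
        if self.derivative not in ("exact", "boxcar"):
            raise ValueError("derivative must be 'exact' or 'boxcar'")

    @classmethod
    def glorot(
        cls,
        layer_sizes: list[int],
        rng: np.random.Generator,
        numerator: float = 6.0,
        **kwargs,
    ) -> "RateNet":
        """Uniform Glorot-style init for forward and feedback matrices."""
        ws, gs = [], []
        for b in range(len(layer_sizes) - 1):
            n_in, n_out = layer_sizes[b], layer_sizes[b + 1]
            bound = np.sqrt(numerator / (n_in + n_out))
            ws.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
        n_cls = layer_sizes[-1]
        for h in range(len(layer_sizes) - 2):
            n_h = layer_sizes[h + 1]
            bound = np.sqrt(numerator / (2 * n_cls + n_h))
            gs.append(rng.uniform(-bound, bound, size=(n_h, n_cls)))
        return cls(weights=ws, feedback=gs, **kwargs)

    def copy(self) -> "RateNet":
        return RateNet(
            weights=[W.copy() for W in self.weights],
            feedback=[G.copy() for G in self.feedback],
            activation=self.activation,
            derivative=self.derivative,
            sigma=self.sigma,
            theta=self.theta,
            boxcar=self.boxcar,
            output_derivative=self.output_derivative,
        )

    # ----------------------------------------------------------- activation

    def phi(self, a: np.ndarray) -> np.ndarray:
        if self.activation == "erf":
            return 0.5 * (1.0 + erf((a - self.theta) / (self.sigma * np.sqrt(2.0))))
        return np.clip(a - self.theta, 0.0, 1.0)

    def phi_prime(self, a: np.ndarray) -> np.ndarray:
        """Derivative factor: exact phi' or the boxcar on the total input."""
        if self.derivative == "boxcar":
            lo, hi = self.boxcar
            return ((a > lo) & (a < hi)).astype(np.float64)
        if self.activation == "erf":
            z = (a - self.theta) / self.sigma
            return np.exp(-0.5 * z * z) / (self.sigma * np.sqrt(2.0 * np.pi))
        return ((a - self.theta > 0.0) & (a - self.theta < 1.0)).astype(np.float64)


@dataclass
class LossState:
    """Squared-error loss bookkeeping for one sample."""

    predictions: np.ndarray
    targets: np.ndarray

    @property
    def errors(self) -> np.ndarray:
        return self.predictions - self.targets

    @property
    def L(self) -> float:
        e = self.errors
        return float(0.5 * np.dot(e, e))


def forward(net: RateNet, x: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Layered composition; returns (activities incl. input, pre-activations)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != net.weights[0].shape[1]:
        raise ValueError("input does not match the first weight matrix")
    ys, pre = [x], []
    for W in net.weights:
        a = W @ ys[-1]
        pre.append(a)
        ys.append(net.phi(a))
    return ys, pre


def _deltas_to_grads(
    net: RateNet, ys: list[np.ndarray], deltas: list[np.ndarray]
) -> list[np.ndarray]:
    return [np.outer(d, y) for d, y in zip(deltas, ys[:-1])]


def backward_bp(
    net: RateNet,
    ys: list[np.ndarray],
    pre: list[np.ndarray],
    e: np.ndarray,
) -> list[np.ndarray]:
    """Exact chain-rule gradients of the squared error w.r.t. every weight."""
    L = len(net.weights)
    out_fac = net.phi_prime(pre[-1]) if net.output_derivative else 1.0
    deltas = [None] * L
    deltas[-1] = e * out_fac
    for l in range(L - 2, -1, -1):
        deltas[l] = net.phi_prime(pre[l]) * (net.weights[l + 1].T @ deltas[l + 1])
    return _deltas_to_grads(net, ys, deltas)


def backward_rbp(
    net: RateNet,
    ys: list[np.ndarray],
    pre: list[np.ndarray],
    e: np.ndarray,
) -> list[np.ndarray]:
    """Direct random-feedback pseudo-gradients.

    The output layer is identical to BP; each hidden layer receives the
    output error through its fixed random matrix, with no recursion through
    the layers above.
    """
    L = len(net.weights)
    out_fac = net.phi_prime(pre[-1]) if net.output_derivative else 1.0
    deltas = [None] * L
    deltas[-1] = e * out_fac
    for l in range(L - 2, -1, -1):
        deltas[l] = net.phi_prime(pre[l]) * (net.feedback[l] @ e)
    return _deltas_to_grads(net, ys, deltas)


def sgd_step(
    net: RateNet, grads: list[np.ndarray], eta: float, batch: int = 1
) -> RateNet:
    """In-place descent step with the learning rate scaled by 1/batch."""
    if len(grads) != len(net.weights):
        raise ValueError("one gradient per weight matrix required")
    scale = eta / batch
    for W, g in zip(net.weights, grads):
        W -= scale * g
    return net


def loss_and_error(net: RateNet, x: np.ndarray, target: np.ndarray) -> LossState:
    ys, _ = forward(net, x)
    return LossState(predictions=ys[-1], targets=np.asarray(target, dtype=np.float64))


def finite_difference_grads(
    net: RateNet, x: np.ndarray, target: np.ndarray, h: float = 1e-6
) -> list[np.ndarray]:
    """Central-difference gradient of the loss; the independent oracle for
    :func:`backward_bp`."""
    grads = []
    for W in net.weights:
        g = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            ij = it.multi_index
            orig = W[ij]
            W[ij] = orig + h
            lp = loss_and_error(net, x, target).L
            W[ij] = orig - h
            lm = loss_and_error(net, x, target).L
            W[ij] = orig
            g[ij] = (lp - lm) / (2.0 * h)
        grads.append(g)
    return grads
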