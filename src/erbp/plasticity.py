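"""The event-driven plasticity rule and its supporting pieces.

A weight update happens only when a presynaptic neuron spikes.  For every
such spike the postsynaptic neuron contributes an update iff its total
synaptic current lies inside the boxcar window ``(b_min, b_max)`` -- a binary
surrogate for the derivative of the refractory-bounded activation function.
The update magnitude is the dendritically stored error:

    dw[i, j] = -eta * U[i]        (descent sign; eta in nS, U in mV, w in nA)

so a single update costs one addition and two comparisons per synapse.
Optional fixed-point quantization with randomized rounding keeps every
weight on an equally spaced grid at all times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantSpec",
    "SynapseBlock",
    "FeedbackWiring",
    "boxcar_gate",
    "erbp_apply",
    "randomized_round",
    "init_weights",
    "blankout_mask",
]

#: nS * mV = pA; weight increments convert to nA with this factor.
_NA_PER_NS_MV = 1e-3


@dataclass(frozen=True)
class QuantSpec:
    """Fixed-point weight grid: ``n_levels`` equally spaced values in [lo, hi]."""

    n_levels: int = 256
    lo: float = -0.5
    hi: float = 0.5

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / (self.n_levels - 1)

    def on_grid(self, w: np.ndarray, atol: float = 1e-12) -> np.ndarray:
        """Boolean mask of entries lying on the grid (within atol)."""
        k = np.round((np.asarray(w) - self.lo) / self.step)
        ok = (k >= 0) & (k <= self.n_levels - 1)
        return ok & (np.abs(self.lo + k * self.step - w) <= atol)


def randomized_round(
    w: np.ndarray | float, spec: QuantSpec, rng: np.random.Generator
) -> np.ndarray | float:
    """Stochastically round values onto the quantization grid.

    Values are clipped to ``[lo, hi]``; a value between adjacent grid points
    ``a < b`` becomes ``b`` with probability ``(w - a)/(b - a)`` and ``a``
    otherwise, so rounding is unbiased in expectation.  Values already on a
    grid point are returned unchanged.
    """
    scalar = np.ndim(w) == 0
    w = np.atleast_1d(np.asarray(w, dtype=np.float64))
    x = np.clip(w, spec.lo, spec.hi)
    pos = (x - spec.lo) / spec.step
    lower = np.floor(pos)
    frac = pos - lower
    up = rng.random(x.shape) < frac
    k = lower + up
    out = spec.lo + k * spec.step
    if scalar:
        return float(out[0])
    return out


def boxcar_gate(I_post: np.ndarray | float, b_min: float, b_max: float) -> np.ndarray | float:
    """Binary derivative surrogate: 1 iff ``b_min < I < b_max`` (strict)."""
    if not b_min < b_max:
        raise ValueError("b_min must be < b_max")
    gate = (np.asarray(I_post) > b_min) & (np.asarray(I_post) < b_max)
    if np.ndim(I_post) == 0:
        return int(gate)
    return gate.astype(np.int8)


def init_weights(
    n_rows: int, n_cols: int, numerator: float, rng: np.random.Generator
) -> np.ndarray:
    """Glorot-style uniform initialization in nA.

    Entries are i.i.d. uniform on ``+/- sqrt(numerator / (n_rows + n_cols))``.
    The additive-noise and reference configurations use numerator 6; the
    blank-out (multiplicative-noise) configuration uses 7 to compensate for
    the expected transmission failures.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("weight matrix dimensions must be positive")
    bound = np.sqrt(numerator / (n_rows + n_cols))
    return rng.uniform(-bound, bound, size=(n_rows, n_cols))


def blankout_mask(
    presyn_spike_idx: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices surviving stochastic transmission failure with probability p."""
    if not 0.0 <= p < 1.0:
        raise ValueError("blank-out probability must lie in [0, 1)")
    idx = np.asarray(presyn_spike_idx)
    if p == 0.0 or idx.size == 0:
        return idx
    keep = rng.random(idx.shape[0]) >= p
    return idx[keep]


@dataclass
class SynapseBlock:
    """A dense weight matrix with its plasticity configuration.

    ``W`` has shape (post, pre) in nA.  ``eta`` is the learning rate in nS;
    ``b_min``/``b_max`` bound the postsynaptic total synaptic current (nA)
    inside which updates are enabled; ``blankout_p`` is the per-spike,
    per-synapse transmission-failure probability.  If ``quantizer`` is set
    every entry of ``W`` lies on its grid at all times.
    """

    W: np.ndarray
    plastic: bool = True
    eta: float = 1e-3
    b_min: float = -1.15
    b_max: float = 1.15
    blankout_p: float = 0.0
    quantizer: QuantSpec | None = None

    def __post_init__(self) -> None:
        if not self.b_min < self.b_max:
            raise ValueError("b_min must be < b_max")
        if not 0.0 <= self.blankout_p < 1.0:
            raise ValueError("blankout_p must lie in [0, 1)")
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValueError("W must be a 2-D (post x pre) matrix")

    @property
    def n_post(self) -> int:
        return self.W.shape[0]

    @property
    def n_pre(self) -> int:
        return self.W.shape[1]

    def quantize_all(self, rng: np.random.Generator) -> None:
        """Project the full matrix onto the quantization grid (randomized)."""
        if self.quantizer is not None:
            self.W = randomized_round(self.W.ravel(), self.quantizer, rng).reshape(
                self.W.shape
            )


def erbp_apply(
    block: SynapseBlock,
    presyn_spike_idx: np.ndarray,
    U_post: np.ndarray,
    I_post: np.ndarray,
    rng: np.random.Generator,
) -> tuple[SynapseBlock, int]:
    """Apply the event-driven update for one timestep.

    For each postsynaptic neuron ``i`` whose total synaptic current passes
    the boxcar gate and each presynaptic neuron ``j`` that fired this step::

        W[i, j] <- W[i, j] - eta * U_post[i] * 1e-3     (nA)

    followed by randomized rounding when a quantizer is configured.  Returns
    the block and the number of candidate update events,
    ``|gated posts| * |spiking pres|``.
    """
    if not block.plastic:
        raise ValueError("erbp_apply called on a non-plastic SynapseBlock")
    idx = np.asarray(presyn_spike_idx, dtype=np.intp)
    if idx.size == 0:
        return block, 0
    I_post = np.asarray(I_post)
    gated = ((I_post > block.b_min) & (I_post < block.b_max)).nonzero()[0]
    n_events = int(gated.size * idx.size)
    if gated.size == 0:
        return block, 0
    dw = (-block.eta * _NA_PER_NS_MV) * np.asarray(U_post)[gated]
    rows = gated[:, None]
    sub = block.W[rows, idx] + dw[:, None]
    if block.quantizer is not None:
        sub = randomized_round(sub.ravel(), block.quantizer, rng).reshape(sub.shape)
    block.W[rows, idx] = sub
    return block, n_events


@dataclass
class FeedbackWiring:
    """Fixed random error-feedback coefficients with paired-sign structure.

    ``G`` has shape (hidden, error pairs) in nA.  Pair ``k``'s positive
    error neuron projects ``+G[i, k]`` onto hidden dendrite ``i`` and its
    negative counterpart ``-G[i, k]``, so the summed feedback over each pair
    is exactly zero and spontaneous error activity cannot bias learning.
    """

    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.float64)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-D (hidden x error pairs)")

    @property
    def pair_sum(self) -> np.ndarray:
        """Summed feedback weight over each (E+, E-) pair: identically zero."""
        return self.G + (-self.G)

    @classmethod
    def glorot(
        cls,
        n_hidden: int,
        n_pairs: int,
        rng: np.random.Generator,
        numerator: float = 6.0,
    ) -> "FeedbackWiring":
        """Sample G ~ U(+/- sqrt(numerator / (N_E + N_H))), N_E = 2 * pairs."""
        bound = np.sqrt(numerator / (2 * n_pairs + n_hidden))
        return cls(G=rng.uniform(-bound, bound, size=(n_hidden, n_pairs)))
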