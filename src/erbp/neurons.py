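"""Discrete-time dynamics of the four neuron types.

The simulator is clock-driven (forward Euler, default ``dt = 0.1`` ms) and
carries physical units exactly as configured: capacitance in pF, conductances
in nS, membrane potentials in mV, synaptic currents in nA, time in ms.  With
these units a current of ``I`` nA must be converted to pA before it enters the
voltage equation, since ``pF * mV / ms = pA`` and ``nS * mV = pA``::

    C dV/dt = -g_V * V + 1000 * I          (all symbols in the units above)

A spike is a unit-area impulse carrying one time-unit of charge,
``Q_SPIKE = 1`` ms.  A presynaptic spike through weight ``w`` (nA) therefore
increments a current-integrating target by ``w * Q_SPIKE / tau_syn`` (exact
integration of ``tau_syn dI/dt = -I + w q delta``) and a direct voltage target
(error-neuron inputs, dendritic error synapses) by ``1000 * w * Q_SPIKE / C``
millivolts.

Four neuron types share these conventions:

* input encoders -- stochastic spike-response units with an exponential
  hazard of the pixel intensity and an absolute refractory period;
* hidden and prediction neurons -- leaky two-compartment current-based
  integrate-and-fire units: a somatic potential ``V`` drives spiking, a
  decoupled dendritic potential ``U`` integrates error feedback and is read
  only by the plasticity rule;
* error-coding neurons -- non-leaky integrate-and-fire pairs with a
  subtractive reset and a symmetric lower bound on the membrane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = [
    "Q_SPIKE",
    "PA_PER_NA",
    "NeuronParams",
    "EncoderParams",
    "ActivationParams",
    "LayerState",
    "step_two_compartment_layer",
    "step_error_layer",
    "encode_input",
    "activation_rate",
]

#: Charge carried by one spike, in ms (unit-area impulse convention).
Q_SPIKE: float = 1.0

#: Conversion factor so nA currents balance the pF/nS/mV/ms voltage equation.
PA_PER_NA: float = 1000.0


@dataclass(frozen=True)
class NeuronParams:
    """Physical constants of a hidden/prediction neuron population.

    Parameters
    ----------
    C : float
        Membrane capacitance in pF (shared by soma and dendrite).
    g_V : float
        Somatic leak conductance in nS; ``tau_m = C / g_V``.
    g_U : float
        Dendritic leak conductance in nS.
    V_T : float
        Somatic firing threshold in mV (strict: spike iff ``V > V_T``).
    V_T_E : float
        Error-neuron firing threshold in mV.
    tau_refr : float
        Absolute refractory period in ms.  The soma is held at the reset
        value 0 while refractory.
    tau_syn : float
        Synaptic current time constant in ms.  The analytic rate formula
        assumes ``tau_m << tau_syn``; we require ``tau_m <= tau_syn / 2``.
    sigma_w : float
        Synaptic weight of the background Poisson noise source in nA
        (0 disables the additive noise; the multiplicative blank-out
        configuration uses 0 here).
    nu_bg : float
        Background Poisson rate in kHz (events per ms and neuron).
    noise_scheme : str
        ``"poisson"`` for a single excitatory background stream (carries a
        mean of ``sigma_w * nu_bg * Q_SPIKE`` nA), ``"balanced"`` for paired
        +/- streams with zero mean, matching the zero-mean white noise of the
        diffusion analysis.
    """

    C: float = 1.0
    g_V: float = 1.0
    g_U: float = 5.0
    V_T: float = 100.0
    V_T_E: float = 100.0
    tau_refr: float = 3.9
    tau_syn: float = 4.0
    sigma_w: float = 0.0
    nu_bg: float = 1.0
    noise_scheme: str = "poisson"

    def __post_init__(self) -> None:
        for name in ("C", "g_V", "g_U", "V_T", "V_T_E", "tau_refr", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NeuronParams.{name} must be positive")
        if self.sigma_w < 0 or self.nu_bg < 0:
            raise ValueError("sigma_w and nu_bg must be non-negative")
        if self.tau_m > self.tau_syn / 2.0:
            raise ValueError(
                f"tau_m = C/g_V = {self.tau_m:g} ms violates the slow-synapse "
                f"regime tau_m <= tau_syn/2 = {self.tau_syn / 2.0:g} ms"
            )
        if self.noise_scheme not in ("poisson", "balanced"):
            raise ValueError("noise_scheme must be 'poisson' or 'balanced'")

    @property
    def tau_m(self) -> float:
        """Somatic membrane time constant C/g_V in ms."""
        return self.C / self.g_V

    @property
    def noise_mean_current(self) -> float:
        """Mean current (nA) carried by the background stream.

        Zero for the balanced scheme; ``sigma_w * nu_bg * Q_SPIKE`` for the
        single-signed Poisson stream.
        """
        if self.noise_scheme == "balanced":
            return 0.0
        return self.sigma_w * self.nu_bg * Q_SPIKE

    @property
    def noise_sigma_current(self) -> float:
        """Stationary standard deviation (nA) of the filtered noise current.

        Campbell's theorem for shot noise through the ``tau_syn`` filter:
        each event jumps the current by ``sigma_w * Q_SPIKE / tau_syn`` and
        decays exponentially, so ``var = rate * jump^2 * tau_syn / 2`` with
        ``rate = nu_bg`` (single stream) or ``2 nu_bg`` (balanced pair).
        """
        jump = self.sigma_w * Q_SPIKE / self.tau_syn
        rate = self.nu_bg * (2.0 if self.noise_scheme == "balanced" else 1.0)
        return jump * np.sqrt(rate * self.tau_syn / 2.0)


@dataclass(frozen=True)
class EncoderParams:
    """Input (data) neuron constants: exponential hazard of intensity."""

    beta: float = 0.5
    gamma: float = -0.215
    tau_refr: float = 4.0

    def __post_init__(self) -> None:
        if self.tau_refr <= 0:
            raise ValueError("EncoderParams.tau_refr must be positive")


@dataclass(frozen=True)
class ActivationParams:
    """Constants of the analytic erf firing-rate curve.

    ``sigma_OU`` is the stationary standard deviation of the free membrane
    potential in mV.  It is a free parameter of the analytic oracle: the
    dynamics realize the noise as filtered shot noise, whose membrane-level
    variance has no exact closed form once threshold, reset and the finite
    membrane time constant enter.
    """

    sigma_OU: float
    tau_refr: float = 3.9

    def __post_init__(self) -> None:
        if self.sigma_OU <= 0:
            raise ValueError("sigma_OU must be positive")
        if self.tau_refr <= 0:
            raise ValueError("tau_refr must be positive")


@dataclass
class LayerState:
    """Per-neuron dynamical variables of one layer.

    ``V`` somatic potential (mV), ``U`` dendritic potential (mV), ``I`` total
    synaptic current (nA), ``refr_until`` end of the current refractory
    window (ms), ``last_spike`` most recent spike time (ms).
    """

    V: np.ndarray
    U: np.ndarray
    I: np.ndarray
    refr_until: np.ndarray
    last_spike: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "LayerState":
        return cls(
            V=np.zeros(n),
            U=np.zeros(n),
            I=np.zeros(n),
            refr_until=np.zeros(n),
            last_spike=np.full(n, -np.inf),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def copy(self) -> "LayerState":
        return LayerState(*(a.copy() for a in
                            (self.V, self.U, self.I, self.refr_until, self.last_spike)))


def _background_noise_current(params: NeuronParams, n: int, dt: float,
                              rng: np.random.Generator) -> np.ndarray | float:
    """Synaptic-current increments (nA) from the background Poisson source.

    Events are delivered through the standard ``tau_syn`` filter like any
    other spike, each contributing ``sigma_w * Q_SPIKE / tau_syn`` to I.
    """
    if params.sigma_w == 0.0 or params.nu_bg == 0.0:
        return 0.0
    lam = params.nu_bg * dt
    jump = params.sigma_w * Q_SPIKE / params.tau_syn
    if params.noise_scheme == "balanced":
        events = rng.poisson(lam, n).astype(np.float64) - rng.poisson(lam, n)
    else:
        events = rng.poisson(lam, n).astype(np.float64)
    return jump * events


def step_two_compartment_layer(
    state: LayerState,
    ff_charge: np.ndarray | float,
    err_charge: np.ndarray | float,
    params: NeuronParams,
    t: float,
    dt: float,
    noise_stream: np.random.Generator | None = None,
) -> tuple[LayerState, np.ndarray]:
    """Advance a layer of two-compartment I&F neurons by one step.

    Parameters
    ----------
    state : LayerState
        Layer state at time ``t``; updated in place and returned.
    ff_charge : array or scalar
        Per-neuron increments to the synaptic current this step, in nA
        (already divided by ``tau_syn`` by the caller for spike inputs).
    err_charge : array or scalar
        Per-neuron increments to the dendritic potential this step, in mV.
    params, t, dt
        Population constants, step start time (ms) and step size (ms).
    noise_stream : numpy Generator, optional
        Source for the background Poisson noise; required if
        ``params.sigma_w > 0``.

    Returns
    -------
    (state, spikes)
        Updated state and a boolean spike-flag array.  Spiking neurons are
        reset to 0 and held there for ``tau_refr``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.n
    for name, arr in (("ff_charge", ff_charge), ("err_charge", err_charge)):
        if np.ndim(arr) > 0 and np.shape(arr) != (n,):
            raise ValueError(f"{name} not conformable with layer of size {n}")

    I, V, U = state.I, state.V, state.U
    if params.sigma_w > 0.0:
        if noise_stream is None:
            raise ValueError("noise_stream required when sigma_w > 0")
        ff_charge = ff_charge + _background_noise_current(
            params, n, dt, noise_stream
        )

    I *= 1.0 - dt / params.tau_syn
    I += ff_charge
    refractory = state.refr_until > t
    V += (dt / params.C) * (PA_PER_NA * I - params.g_V * V)
    if refractory.any():
        V[refractory] = 0.0
    U *= 1.0 - dt * params.g_U / params.C
    if np.ndim(err_charge) > 0 or err_charge != 0.0:
        U += err_charge

    spikes = V > params.V_T
    if spikes.any():
        t_spike = t + dt
        V[spikes] = 0.0
        state.refr_until[spikes] = t_spike + params.tau_refr
        state.last_spike[spikes] = t_spike
    return state, spikes


def step_error_layer(
    state: LayerState,
    pred_spikes: np.ndarray,
    label_spikes: np.ndarray,
    w_L: float,
    params: NeuronParams,
    dt: float,
) -> tuple[LayerState, np.ndarray, np.ndarray]:
    """Advance one layer of error-coding neuron pairs by one step.

    Pair ``i`` integrates the prediction/label spike difference without leak:
    ``V+ <- V+ + (1000 w_L Q/C) (pred_i - label_i)`` and the mirror neuron
    with the opposite sign (``w_L- = -w_L+``).  Crossing ``V_T_E`` emits a
    spike with a subtractive reset; the membrane is floored at ``-V_T_E`` so
    negative error cannot accumulate across samples.

    ``state.V`` holds the positive-error membranes, ``state.U`` the
    negative-error membranes (the pair shares one LayerState).
    """
    pred_spikes = np.asarray(pred_spikes)
    label_spikes = np.asarray(label_spikes)
    if pred_spikes.shape != (state.n,) or label_spikes.shape != (state.n,):
        raise ValueError("pred/label spike arrays must match error-layer size")

    diff = pred_spikes.astype(np.float64)
    diff -= label_spikes
    dv = (PA_PER_NA * w_L * Q_SPIKE / params.C) * diff
    state.V += dv
    state.U -= dv

    pos = state.V > params.V_T_E
    neg = state.U > params.V_T_E
    if pos.any():
        state.V[pos] -= params.V_T_E
    if neg.any():
        state.U[neg] -= params.V_T_E
    np.maximum(state.V, -params.V_T_E, out=state.V)
    np.maximum(state.U, -params.V_T_E, out=state.U)
    return state, pos, neg


def encode_input(
    intensities: np.ndarray,
    last_spike: np.ndarray,
    params: EncoderParams,
    t: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One step of the stochastic spike-response input encoder.

    Neuron ``j`` spikes with probability ``min(1, nu_d(d_j) dt)`` where
    ``nu_d = tau_refr^-1 exp(beta d_j + gamma)`` (rate in kHz for d in
    [0, 1]), provided at least ``tau_refr`` has elapsed since its last spike.
    ``last_spike`` is updated in place on spiking.
    """
    intensities = np.asarray(intensities, dtype=np.float64)
    if intensities.min() < 0.0 or intensities.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    hazard = np.exp(params.beta * intensities + params.gamma) / params.tau_refr
    p = np.minimum(1.0, hazard * dt)
    eligible = (t - last_spike) >= params.tau_refr
    spikes = eligible & (rng.random(intensities.shape[0]) < p)
    last_spike[spikes] = t
    return spikes


def activation_rate(mu: np.ndarray | float, params: ActivationParams) -> np.ndarray | float:
    """Analytic firing rate (Hz) of a noisy I&F neuron with refractoriness.

    ``rate = tau_refr^-1 * (1 + erf(mu / (sigma_OU sqrt(2)))) / 2`` with
    ``mu`` the mean input measured in membrane units (mV) relative to
    threshold.  Derived from the diffusion approximation: the free membrane
    is Gaussian with SD ``sigma_OU``; the neuron fires at its refractory-
    bounded maximum with the probability that the membrane is suprathreshold.
    """
    mu = np.asarray(mu, dtype=np.float64)
    rate = (1000.0 / params.tau_refr) * 0.5 * (
        1.0 + erf(mu / (params.sigma_OU * np.sqrt(2.0)))
    )
    if rate.ndim == 0:
        return float(rate)
    return rate
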