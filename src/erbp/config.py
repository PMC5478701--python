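"""Flat experiment configuration keyed by the simulation symbol names.

Defaults reproduce the published spiking-simulation constants verbatim for
the blank-out (multiplicative-noise) configuration; the additive-noise
configuration is selected with ``noise_mode: additive`` which switches
``sigma``, ``p``, ``eta`` and the initialization numerator together unless
overridden explicitly.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .network import NetworkSpec, PresentationProtocol
from .neurons import EncoderParams, NeuronParams
from .plasticity import QuantSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # architecture
    N_d: int = 64
    N_h: list[int] = field(default_factory=lambda: [32])
    N_p: int = 3
    # neuron constants
    C: float = 1.0            # pF
    g_V: float = 1.0          # nS
    g_U: float = 5.0          # nS
    V_T: float = 100.0        # mV
    V_T_E: float = 100.0      # mV
    tau_refr: float = 3.9     # ms, prediction/hidden
    tau_refr_data: float = 4.0  # ms, data neurons
    tau_syn: float = 4.0      # ms
    # noise
    noise_mode: str = "blankout"   # "blankout" (eRBP_x) or "additive" (eRBP_+)
    sigma: float | None = None     # nA; default per noise_mode (0 / 0.05)
    nu_bg: float = 1.0             # kHz
    p: float | None = None         # blank-out probability; default per mode
    # synapses / plasticity
    w_E: float = 0.09         # nA
    w_L_plus: float = 0.09    # nA
    w_L_minus: float = -0.09  # nA
    b_min: float = -1.15      # nA, first (and output) blocks
    b_max: float = 1.15
    b_min2: float = -25.0     # nA, block into a second hidden layer
    b_max2: float = 25.0
    eta: float | None = None  # nS; default per noise_mode (1e-3 / 6e-4)
    eta_output: float | None = None  # nS; None -> same as eta
    init_numerator: float | None = None  # default per mode (7 / 6)
    quantize: bool = False
    quant_levels: int = 256
    quant_lo: float = -0.5
    quant_hi: float = 0.5
    # encoder
    beta: float = 0.5
    gamma: float = -0.215
    # protocol
    T_train: float = 250.0    # ms per training sample
    T_test: float = 250.0     # ms per test sample
    learn_gate_delay: float = 50.0  # ms
    dt: float = 0.1           # ms
    epochs: int = 20
    seed: int = 0
    decoder: str = "counts"
    # dataset
    dataset: str = "prototype"     # "prototype" or "idx"
    task_classes: int = 3
    task_features: int = 64
    task_density: float = 0.5
    task_noise: float = 0.1
    task_train: int = 90
    task_test: int = 60
    task_seed: int = 0
    idx_images: str | None = None
    idx_labels: str | None = None
    idx_test_images: str | None = None
    idx_test_labels: str | None = None

    def __post_init__(self) -> None:
        if self.noise_mode not in ("blankout", "additive"):
            raise ValueError("noise_mode must be 'blankout' or 'additive'")
        blank = self.noise_mode == "blankout"
        if self.sigma is None:
            self.sigma = 0.0 if blank else 0.05
        if self.p is None:
            self.p = 0.45 if blank else 0.0
        if self.eta is None:
            self.eta = 1e-3 if blank else 6e-4
        if self.init_numerator is None:
            self.init_numerator = 7.0 if blank else 6.0
        if not self.b_min < self.b_max:
            raise ValueError("b_min must be < b_max")
        if not self.b_min2 < self.b_max2:
            raise ValueError("b_min2 must be < b_max2")
        if self.w_L_minus != -self.w_L_plus:
            raise ValueError("w_L_minus must equal -w_L_plus")
        if self.task_features != self.N_d and self.dataset == "prototype":
            raise ValueError("task_features must equal N_d")

    # ------------------------------------------------------------- builders

    def neuron_params(self) -> NeuronParams:
        return NeuronParams(
            C=self.C, g_V=self.g_V, g_U=self.g_U, V_T=self.V_T,
            V_T_E=self.V_T_E, tau_refr=self.tau_refr, tau_syn=self.tau_syn,
            sigma_w=self.sigma, nu_bg=self.nu_bg,
        )

    def encoder_params(self) -> EncoderParams:
        return EncoderParams(beta=self.beta, gamma=self.gamma,
                             tau_refr=self.tau_refr_data)

    def network_spec(self) -> NetworkSpec:
        sizes = [self.N_d, *self.N_h, self.N_p]
        n_blocks = len(sizes) - 1
        bounds = []
        for b in range(n_blocks):
            wide = n_blocks >= 3 and b == 1
            bounds.append((self.b_min2, self.b_max2) if wide
                          else (self.b_min, self.b_max))
        quant = (QuantSpec(self.quant_levels, self.quant_lo, self.quant_hi)
                 if self.quantize else None)
        eta_out = self.eta if self.eta_output is None else self.eta_output
        etas = [self.eta] * (n_blocks - 1) + [eta_out]
        return NetworkSpec(
            layer_sizes=sizes,
            params=self.neuron_params(),
            encoder=self.encoder_params(),
            eta=etas,
            init_numerator=self.init_numerator,
            gate_bounds=bounds,
            w_E=self.w_E,
            w_L=self.w_L_plus,
            blankout_p=self.p,
            quantizer=quant,
        )

    def protocol(self) -> PresentationProtocol:
        return PresentationProtocol(
            sample_duration=self.T_train,
            learn_gate_delay=self.learn_gate_delay,
            test_duration=self.T_test,
            dt=self.dt,
        )

    def datasets(self):
        from .datasets import (LabeledDataset, PrototypeTaskSpec,
                               make_prototype_task, read_idx)

        if self.dataset == "prototype":
            spec = PrototypeTaskSpec(
                n_classes=self.task_classes, n_features=self.task_features,
                prototype_density=self.task_density, noise=self.task_noise,
                n_train=self.task_train, n_test=self.task_test,
                seed=self.task_seed,
            )
            return make_prototype_task(spec)
        if self.dataset == "idx":
            if not (self.idx_images and self.idx_labels):
                raise ValueError("idx dataset needs idx_images and idx_labels")
            X = read_idx(self.idx_images).reshape(-1, self.N_d) / 255.0
            y = read_idx(self.idx_labels).astype(int)
            train = LabeledDataset(X, y, self.N_p)
            test = train
            if self.idx_test_images and self.idx_test_labels:
                Xt = read_idx(self.idx_test_images).reshape(-1, self.N_d) / 255.0
                yt = read_idx(self.idx_test_labels).astype(int)
                test = LabeledDataset(Xt, yt, self.N_p)
            return train, test
        raise ValueError(f"unknown dataset kind {self.dataset!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str) -> RunConfig:
    """Load a flat YAML config; unknown keys raise."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
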