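"""Model/Results interface over the spiking and rate networks.

``ErbpClassifier`` wraps the spiking simulator: construct it from a labeled
dataset, call :meth:`~ErbpClassifier.fit`, and receive an ``ErbpResults``
carrying the trained network, the per-epoch training log, operation counts
and alignment diagnostics, with a ``summary()`` table.  ``RateClassifier``
is the analogous interface over the non-spiking BP/RBP reference model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .metrics import erbp_alignment_series
from .network import Network, NetworkSpec, PresentationProtocol, build_network
from .neurons import EncoderParams, NeuronParams
from .plasticity import QuantSpec
from .ratenet import RateNet, backward_bp, backward_rbp, forward, sgd_step

__all__ = ["ErbpClassifier", "ErbpResults", "RateClassifier", "RateResults"]


class ErbpClassifier:
    """Spiking classifier trained with event-driven random backpropagation.

    Parameters
    ----------
    data : LabeledDataset
        Training samples (intensities in [0, 1] with integer labels).
    hidden : sequence of int
        Hidden layer sizes, e.g. ``(32,)`` or ``(200, 200)``.
    noise_mode : str
        ``"blankout"`` (multiplicative: transmission failures with
        probability 0.45, no background noise -- the preferred
        configuration) or ``"additive"`` (background Poisson noise, no
        blank-out).
    quantize : bool
        Constrain all plastic weights to 256 equally spaced values in
        [-0.5, 0.5] nA with randomized rounding.
    protocol : PresentationProtocol, optional
        Presentation timing; defaults to 250 ms per sample with a 50 ms
        plasticity gate after each onset.
    eta : float, optional
        Hidden-block learning rate (nS); defaults to the per-noise-mode
        value (1e-3 blank-out, 6e-4 additive).
    eta_output : float, optional
        Learning rate of the block into the prediction layer (nS), default
        3e-2.  At small layer sizes the random feedback weights onto hidden
        dendrites are several times larger than the one-to-one error weight
        onto prediction dendrites, so the readout needs a faster rate than
        the hidden blocks for feedback alignment to track the hidden code.
    encoder : EncoderParams, optional
        Input hazard scaling.  Defaults to ``beta=4, gamma=-3`` so that
        zero-intensity features are nearly silent and full-intensity
        features drive the encoder close to its refractory bound --
        intensities are scaled per task, as for the image benchmarks.
    """

    def __init__(
        self,
        data: LabeledDataset,
        hidden: tuple[int, ...] = (32,),
        noise_mode: str = "blankout",
        quantize: bool = False,
        protocol: PresentationProtocol | None = None,
        eta: float | None = None,
        eta_output: float = 3e-2,
        params: NeuronParams | None = None,
        encoder: EncoderParams | None = None,
        gate_bounds: list[tuple[float, float]] | None = None,
    ):
        if noise_mode not in ("blankout", "additive"):
            raise ValueError("noise_mode must be 'blankout' or 'additive'")
        self.data = data
        self.noise_mode = noise_mode
        if params is None:
            params = NeuronParams(
                sigma_w=0.0 if noise_mode == "blankout" else 0.05
            )
        blankout_p = 0.45 if noise_mode == "blankout" else 0.0
        numerator = 7.0 if noise_mode == "blankout" else 6.0
        if eta is None:
            eta = 1e-3 if noise_mode == "blankout" else 6e-4
        n_blocks = len(hidden) + 1
        etas = [eta] * (n_blocks - 1) + [eta_output]
        self.spec = NetworkSpec(
            layer_sizes=[data.n_features, *hidden, data.n_classes],
            params=params,
            encoder=encoder or EncoderParams(beta=4.0, gamma=-3.0),
            eta=etas,
            init_numerator=numerator,
            gate_bounds=gate_bounds,
            blankout_p=blankout_p,
            quantizer=QuantSpec() if quantize else None,
        )
        self.protocol = protocol or PresentationProtocol()

    def fit(
        self,
        epochs: int = 20,
        seed: int = 0,
        test_data: LabeledDataset | None = None,
        snapshot_every: int | None = None,
        eval_every: int | None = None,
        decoder: str = "counts",
        verbose: bool = False,
    ) -> "ErbpResults":
        """Train for ``epochs`` passes over the data and evaluate."""
        net = build_network(self.spec, seed)
        log = net.train(
            self.data,
            epochs,
            self.protocol,
            snapshot_every=snapshot_every,
            test_dataset=test_data,
            eval_every=eval_every,
            decoder=decoder,
            verbose=verbose,
        )
        train_err = net.evaluate(self.data, self.protocol, decoder)
        test_err = (
            net.evaluate(test_data, self.protocol, decoder)
            if test_data is not None
            else np.nan
        )
        return ErbpResults(
            model=self,
            network=net,
            log=log,
            train_err=train_err,
            test_err=test_err,
            decoder=decoder,
            epochs=epochs,
            seed=seed,
        )


@dataclass
class ErbpResults:
    """Fit results of the spiking classifier."""

    model: ErbpClassifier
    network: Network
    log: pd.DataFrame
    train_err: float
    test_err: float
    decoder: str
    epochs: int
    seed: int

    @property
    def train_accuracy(self) -> float:
        return 1.0 - self.train_err

    @property
    def test_accuracy(self) -> float:
        return 1.0 - self.test_err

    def predict(self, x: np.ndarray) -> int:
        return self.network.predict(x, self.model.protocol, self.decoder)

    def alignment(self, block: int = 0) -> pd.DataFrame:
        """Per-epoch angles between realized updates and true BP gradients.

        Requires the fit to have stored weight snapshots
        (``snapshot_every=1``).
        """
        snaps = getattr(self.network, "snapshots", [])
        if len(snaps) < 2:
            raise ValueError("fit with snapshot_every=1 to enable alignment")
        return erbp_alignment_series(snaps, self.model.data, self.model.spec, block)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Event-driven RBP spiking classifier",
            "=" * 45,
            f"architecture      {'-'.join(str(n) for n in spec.layer_sizes)}",
            f"noise mode        {self.model.noise_mode}"
            + (f" (p={spec.blankout_p})" if spec.blankout_p else
               f" (sigma_w={spec.params.sigma_w} nA)"),
            "learning rate     "
            + (
                "/".join(f"{e:g}" for e in spec.eta)
                if isinstance(spec.eta, (list, tuple))
                else f"{spec.eta:g}"
            )
            + " nS",
            f"quantized         {spec.quantizer is not None}",
            f"epochs / seed     {self.epochs} / {self.seed}",
            f"decoder           {self.decoder}",
            "-" * 45,
            f"train error       {self.train_err:.4f}",
            f"test error        {self.test_err:.4f}"
            if np.isfinite(self.test_err) else "test error        n/a",
            f"SynOps            {self.network.synops + self.network.synops_error:,}",
            f"update events     {self.network.update_events:,}",
            "=" * 45,
        ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Online training accuracy per epoch (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["epoch"], 1.0 - self.log["train_acc_online"], "o-")
        ax.set_xlabel("epoch")
        ax.set_ylabel("online training error")
        ax.set_yscale("log")
        return ax


class RateClassifier:
    """Non-spiking reference classifier trained with BP or direct RBP."""

    def __init__(
        self,
        data: LabeledDataset,
        hidden: tuple[int, ...] = (32,),
        rule: str = "rbp",
        activation: str = "erf",
        derivative: str = "exact",
        eta: float = 0.4,
        n_batch: int = 1,
    ):
        if rule not in ("bp", "rbp"):
            raise ValueError("rule must be 'bp' or 'rbp'")
        self.data = data
        self.rule = rule
        self.eta = eta
        self.n_batch = n_batch
        self.layer_sizes = [data.n_features, *hidden, data.n_classes]
        self.activation = activation
        self.derivative = derivative

    def fit(self, epochs: int = 20, seed: int = 0,
            test_data: LabeledDataset | None = None) -> "RateResults":
        rng = np.random.default_rng(seed)
        net = RateNet.glorot(
            self.layer_sizes, rng,
            activation=self.activation, derivative=self.derivative,
        )
        backward = backward_bp if self.rule == "bp" else backward_rbp
        T = self.data.one_hot()
        macs = 0
        mac_fwd = sum(W.size for W in net.weights)
        if self.rule == "bp":
            mac_bwd = sum(W.size for W in net.weights[1:])
        else:
            mac_bwd = sum(G.size for G in net.feedback)
        rows = []
        for epoch in range(epochs):
            order = rng.permutation(len(self.data))
            # accumulate minibatch gradients, step every n_batch samples
            acc = [np.zeros_like(W) for W in net.weights]
            n_acc = 0
            losses = []
            for i in order:
                x, _ = self.data[int(i)]
                ys, pre = forward(net, x)
                e = ys[-1] - T[int(i)]
                losses.append(0.5 * float(e @ e))
                g = backward(net, ys, pre, e)
                for a, gi in zip(acc, g):
                    a += gi
                n_acc += 1
                macs += mac_fwd + mac_bwd
                if n_acc == self.n_batch:
                    sgd_step(net, acc, self.eta, self.n_batch)
                    acc = [np.zeros_like(W) for W in net.weights]
                    n_acc = 0
            if n_acc:
                sgd_step(net, acc, self.eta, n_acc)
            wrong = 0
            for i in range(len(self.data)):
                x, y = self.data[i]
                ys, _ = forward(net, x)
                wrong += int(np.argmax(ys[-1])) != y
            rows.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                         "macs": macs,
                         "train_err": wrong / len(self.data)})
        log = pd.DataFrame(rows)
        res = RateResults(model=self, net=net, log=log, epochs=epochs, seed=seed)
        res.train_err = res.error_rate(self.data)
        res.test_err = (
            res.error_rate(test_data) if test_data is not None else np.nan
        )
        return res


@dataclass
class RateResults:
    """Fit results of the rate-model classifier."""

    model: RateClassifier
    net: RateNet
    log: pd.DataFrame
    epochs: int
    seed: int
    train_err: float = np.nan
    test_err: float = np.nan

    def predict(self, x: np.ndarray) -> int:
        ys, _ = forward(self.net, x)
        return int(np.argmax(ys[-1]))

    def error_rate(self, data: LabeledDataset) -> float:
        wrong = sum(self.predict(x) != y for x, y in data)
        return wrong / len(data)

    def summary(self) -> str:
        lines = [
            f"Rate-model classifier ({self.model.rule.upper()})",
            "=" * 45,
            f"architecture      {'-'.join(str(n) for n in self.model.layer_sizes)}",
            f"activation        {self.model.activation} "
            f"(derivative: {self.model.derivative})",
            f"eta / batch       {self.model.eta:g} / {self.model.n_batch}",
            f"epochs / seed     {self.epochs} / {self.seed}",
            "-" * 45,
            f"train error       {self.train_err:.4f}",
            f"test error        {self.test_err:.4f}"
            if np.isfinite(self.test_err) else "test error        n/a",
            f"MACs              {int(self.log['macs'].iloc[-1]):,}",
            "=" * 45,
        ]
        return "\n".join(lines)
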