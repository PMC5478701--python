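"""Synthetic classification tasks and IDX image-file support.

The prototype task is the package's desk-scale stand-in for intensity-coded
image data: each class is a random binary prototype over the feature set and
each sample is its prototype with independent per-feature flip noise, scaled
to [0, 1] -- exactly what the spiking encoder assumes (per-sample intensity
vectors in [0, 1] with an integer class label).  The IDX reader/writer
handles the standard big-endian MNIST/EMNIST ubyte container so generated
datasets and real image files flow through the same pipeline.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledDataset",
    "PrototypeTaskSpec",
    "make_prototype_task",
    "nearest_prototype_error",
    "bayes_error_estimate",
    "read_idx",
    "write_idx",
    "scale_for_encoder",
]


class LabeledDataset:
    """Samples as (intensity vector in [0, 1], class index) pairs."""

    def __init__(self, X: np.ndarray, y: np.ndarray, n_classes: int | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if self.X.size and (self.X.min() < 0.0 or self.X.max() > 1.0):
            raise ValueError("intensities must lie in [0, 1]")
        self.n_classes = int(n_classes if n_classes is not None else self.y.max() + 1)
        if self.y.size and (self.y.min() < 0 or self.y.max() >= self.n_classes):
            raise ValueError("labels out of range")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i: int) -> tuple[np.ndarray, int]:
        return self.X[i], int(self.y[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def one_hot(self) -> np.ndarray:
        T = np.zeros((len(self), self.n_classes))
        T[np.arange(len(self)), self.y] = 1.0
        return T


@dataclass(frozen=True)
class PrototypeTaskSpec:
    """Generative model of the synthetic task.

    ``prototype_density`` is the fraction of active features per class
    prototype; ``noise`` the independent per-feature flip probability.
    Train/test splits are balanced (per-class counts differ by at most 1).
    """

    n_classes: int = 3
    n_features: int = 64
    prototype_density: float = 0.5
    noise: float = 0.1
    n_train: int = 60
    n_test: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prototype_density", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_classes < 2 or self.n_features < 1:
            raise ValueError("need >= 2 classes and >= 1 feature")


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Labels 0..k-1 repeated so per-class counts differ by <= 1."""
    return np.arange(n) % k


def _sample_split(
    prototypes: np.ndarray, n: int, noise: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    k = prototypes.shape[0]
    y = _balanced_labels(n, k)
    flips = rng.random((n, prototypes.shape[1])) < noise
    X = np.where(flips, 1 - prototypes[y], prototypes[y]).astype(np.float64)
    return X, y


def make_prototype_task(
    spec: PrototypeTaskSpec,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw prototypes and the train/test splits; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    prototypes = (
        rng.random((spec.n_classes, spec.n_features)) < spec.prototype_density
    ).astype(np.int64)
    Xtr, ytr = _sample_split(prototypes, spec.n_train, spec.noise, rng)
    Xte, yte = _sample_split(prototypes, spec.n_test, spec.noise, rng)
    train = LabeledDataset(Xtr, ytr, spec.n_classes)
    test = LabeledDataset(Xte, yte, spec.n_classes)
    train.prototypes = prototypes  # type: ignore[attr-defined]
    test.prototypes = prototypes  # type: ignore[attr-defined]
    return train, test


def nearest_prototype_error(ds: LabeledDataset, prototypes: np.ndarray) -> float:
    """Error rate of the minimum-Hamming-distance classifier.

    For symmetric flip noise below 1/2 this is the Bayes rule of the
    generative model.
    """
    d = np.abs(ds.X[:, None, :] - prototypes[None, :, :]).sum(axis=2)
    pred = np.argmin(d, axis=1)
    return float(np.mean(pred != ds.y))


def bayes_error_estimate(
    spec: PrototypeTaskSpec, n_mc: int = 20000, seed: int = 12345
) -> float:
    """Monte-Carlo estimate of the Bayes error of the generative model.

    Draws fresh samples from the model and scores the exact Bayes rule
    (nearest prototype in Hamming distance, ties at random).  Serves as the
    brute-force oracle the generated-task accuracy is checked against.
    """
    rng = np.random.default_rng(spec.seed)
    prototypes = (
        rng.random((spec.n_classes, spec.n_features)) < spec.prototype_density
    ).astype(np.int64)
    mc = np.random.default_rng(seed)
    y = mc.integers(0, spec.n_classes, n_mc)
    flips = mc.random((n_mc, spec.n_features)) < spec.noise
    X = np.where(flips, 1 - prototypes[y], prototypes[y])
    d = np.abs(X[:, None, :] - prototypes[None, :, :]).sum(axis=2)
    # random tie-break, as the Bayes rule prescribes for equal posteriors
    jitter = mc.random(d.shape) * 1e-9
    pred = np.argmin(d + jitter, axis=1)
    return float(np.mean(pred != y))


# ----------------------------------------------------------------- IDX format

_IDX_DTYPES = {
    0x08: np.dtype(">u1"),
    0x09: np.dtype(">i1"),
    0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"),
    0x0D: np.dtype(">f4"),
    0x0E: np.dtype(">f8"),
}


def read_idx(path: str) -> np.ndarray:
    """Parse a big-endian IDX (MNIST ubyte style) file into an array.

    uint8 image payloads are returned as raw counts; scale with ``/255`` for
    encoder intensities.
    """
    with open(path, "rb") as f:
        magic = f.read(4)
        if len(magic) != 4 or magic[0] != 0 or magic[1] != 0:
            raise ValueError(f"{path}: bad IDX magic number")
        type_code, n_dims = magic[2], magic[3]
        if type_code not in _IDX_DTYPES:
            raise ValueError(f"{path}: unknown IDX type code 0x{type_code:02x}")
        dims = struct.unpack(f">{n_dims}I", f.read(4 * n_dims))
        dtype = _IDX_DTYPES[type_code]
        count = int(np.prod(dims)) if dims else 0
        payload = f.read()
    expected = count * dtype.itemsize
    if len(payload) < expected:
        raise ValueError(f"{path}: truncated IDX payload")
    arr = np.frombuffer(payload[:expected], dtype=dtype).reshape(dims)
    return arr.astype(dtype.newbyteorder("="))


def write_idx(path: str, arr: np.ndarray) -> None:
    """Write an array (up to 4 dims) in the IDX container."""
    arr = np.asarray(arr)
    if arr.ndim > 4:
        raise ValueError("IDX supports at most 4 dimensions")
    codes = {v.base.str.lstrip(">|=<"): k for k, v in _IDX_DTYPES.items()}
    key = arr.dtype.str.lstrip(">|=<")
    if key not in codes:
        raise ValueError(f"dtype {arr.dtype} not representable in IDX")
    code = codes[key]
    with open(path, "wb") as f:
        f.write(bytes([0, 0, code, arr.ndim]))
        f.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        f.write(arr.astype(_IDX_DTYPES[code]).tobytes())


def scale_for_encoder(
    intensities: np.ndarray, beta: float, gamma: float, tau_refr: float = 4.0
) -> np.ndarray:
    """Effective hazard rates (kHz) the encoder assigns to intensities."""
    d = np.asarray(intensities, dtype=np.float64)
    if d.size and (d.min() < 0.0 or d.max() > 1.0):
        raise ValueError("intensities must lie in [0, 1]")
    return np.exp(beta * d + gamma) / tau_refr
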