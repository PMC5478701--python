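"""Serialization: HDF5 weight containers, TSV rasters, CSV logs."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

__all__ = ["save_weights", "load_weights", "save_raster", "load_raster",
           "save_log"]


def save_weights(path: str, weights: list[np.ndarray],
                 names: list[str] | None = None,
                 quantizer=None, units: str = "nA") -> None:
    """Write weight matrices with names, shapes and quantizer metadata."""
    names = names or [f"block{i}" for i in range(len(weights))]
    if len(names) != len(weights):
        raise ValueError("one name per weight matrix")
    with h5py.File(path, "w") as f:
        f.attrs["units"] = units
        f.attrs["n_blocks"] = len(weights)
        f.attrs["names"] = json.dumps(names)
        if quantizer is not None:
            f.attrs["quantizer"] = json.dumps(
                {"n_levels": quantizer.n_levels, "lo": quantizer.lo,
                 "hi": quantizer.hi}
            )
        for name, W in zip(names, weights):
            f.create_dataset(name, data=np.asarray(W))


def load_weights(path: str) -> tuple[list[np.ndarray], dict]:
    """Read a weight container; returns (matrices, metadata)."""
    with h5py.File(path, "r") as f:
        names = json.loads(f.attrs["names"])
        meta = {"units": f.attrs.get("units", "nA"), "names": names}
        if "quantizer" in f.attrs:
            meta["quantizer"] = json.loads(f.attrs["quantizer"])
        weights = [f[name][...] for name in names]
    return weights, meta


def save_raster(path: str, raster, layer: str) -> None:
    """One layer's events as tab-separated (time_ms, neuron_id)."""
    raster.to_frame(layer).to_csv(path, sep="\t", index=False)


def load_raster(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_log(path: str, log: pd.DataFrame) -> None:
    log.to_csv(path, index=False)
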