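"""Serialization: networks and configs as YAML, signals and rasters as
columnar text tables, dense arrays as an npz container."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import EINetwork, Network
from .plasticity import LearnConfig
from .signals import SignalBundle

__all__ = [
    "save_network",
    "load_network",
    "save_signals",
    "load_signals",
    "save_raster",
    "load_raster",
    "save_arrays",
    "load_config",
]

_ARRAY_FIELDS = {
    "network": ["F", "Omega", "T", "delay_kernel", "mask"],
    "ei_network": ["F", "W_IE", "W_EI", "W_II", "W_EE", "T_E", "T_I", "delay_kernel", "mask"],
}
_SCALAR_FIELDS = {
    "network": ["dt", "noise_sigma", "v_floor", "guard"],
    "ei_network": ["dt", "noise_sigma", "v_floor", "guard", "dale_rectify"],
}


def _arr_to_yaml(a):
    if a is None:
        return None
    return np.asarray(a).tolist()


def save_network(net: Network | EINetwork, path) -> None:
    """Write a network to YAML (floats round-trip bit-exactly through their
    repr)."""
    kind = "ei_network" if isinstance(net, EINetwork) else "network"
    doc = {"kind": kind}
    for f in _ARRAY_FIELDS[kind]:
        doc[f] = _arr_to_yaml(getattr(net, f))
    for f in _SCALAR_FIELDS[kind]:
        v = getattr(net, f)
        doc[f] = float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v
    Path(path).write_text(yaml.safe_dump(doc, default_flow_style=None))


def load_network(path) -> Network | EINetwork:
    doc = yaml.safe_load(Path(path).read_text())
    kind = doc.pop("kind")
    cls = EINetwork if kind == "ei_network" else Network
    kwargs = {}
    for f in _ARRAY_FIELDS[kind]:
        v = doc[f]
        if f == "mask":
            kwargs[f] = None if v is None else np.asarray(v, dtype=bool)
        elif f == "delay_kernel":
            kwargs[f] = np.asarray(v if v is not None else [], dtype=float)
        else:
            kwargs[f] = np.asarray(v, dtype=float)
    for f in _SCALAR_FIELDS[kind]:
        kwargs[f] = doc[f]
    return cls(**kwargs)


def save_signals(sig: SignalBundle, path) -> None:
    """Columnar text table: time column plus c/x columns per channel."""
    sig.to_frame().to_csv(path, index=False)


def load_signals(path, dt: float | None = None) -> SignalBundle:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    if dt is None:
        dt = float(t[1] - t[0])
    M = sum(1 for col in df.columns if col.startswith("c"))
    c = np.vstack([df[f"c{j}"].to_numpy() for j in range(M)])
    x = np.vstack([df[f"x{j}"].to_numpy() for j in range(M)])
    return SignalBundle(c=c, x=x, dt=dt, meta={"source": str(path)})


def save_raster(spikes: np.ndarray, dt: float, path) -> None:
    """Two-column event list (time, neuron id)."""
    df = pd.DataFrame({"time": spikes[:, 0] * dt, "neuron": spikes[:, 1]})
    df.to_csv(path, index=False)


def load_raster(path, dt: float) -> np.ndarray:
    df = pd.read_csv(path)
    steps = np.round(df["time"].to_numpy() / dt).astype(np.int64)
    return np.column_stack([steps, df["neuron"].to_numpy(dtype=np.int64)])


def save_arrays(path, **arrays) -> None:
    """Dense arrays (voltage traces, filtered trains) in the npz container."""
    np.savez_compressed(path, **arrays)


def load_config(path) -> dict:
    """Declarative experiment/learning config from YAML."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "learn" in doc and isinstance(doc["learn"], dict):
        doc["learn"] = LearnConfig(**doc["learn"])
    return doc
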