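"""Serialization helpers: YAML parameter files, spike-train CSV."""

from __future__ import annotations

import dataclasses
from typing import Tuple, Type, TypeVar

import numpy as np
import pandas as pd
import yaml

from .circuit import CircuitBiases, DeviceParams
from .protocols import ProtocolSpec, SpikeTrain
from .rules import PairParams, TripletParams

__all__ = [
    "params_to_yaml",
    "params_from_yaml",
    "save_trains_csv",
    "load_trains_csv",
]

T = TypeVar("T")

_TYPES = {
    "TripletParams": TripletParams,
    "PairParams": PairParams,
    "CircuitBiases": CircuitBiases,
    "DeviceParams": DeviceParams,
    "ProtocolSpec": ProtocolSpec,
}


def params_to_yaml(obj, path) -> None:
    """Write a parameter dataclass as a YAML mapping (field names as keys)."""
    d = {"type": type(obj).__name__, **dataclasses.asdict(obj)}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def params_from_yaml(path, expected: Type[T] | None = None) -> T:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    tname = d.pop("type", None)
    cls = _TYPES.get(tname) if tname else expected
    if cls is None:
        raise ValueError(f"unknown parameter type {tname!r}")
    if expected is not None and cls is not expected:
        raise ValueError(f"expected {expected.__name__}, found {tname}")
    return cls(**d)


def save_trains_csv(pre: SpikeTrain, post: SpikeTrain, path) -> None:
    """Two-column interchange format: train in {pre, post}, time_s."""
    df = pd.DataFrame(
        {
            "train": ["pre"] * len(pre) + ["post"] * len(post),
            "time_s": np.concatenate([pre.times, post.times]),
        }
    )
    df.to_csv(path, index=False)


def load_trains_csv(path, pulse_width: float = 1e-3) -> Tuple[SpikeTrain, SpikeTrain]:
    df = pd.read_csv(path)
    if not {"train", "time_s"} <= set(df.columns):
        raise ValueError("spike-train CSV needs columns: train, time_s")
    pre = np.sort(df.loc[df["train"] == "pre", "time_s"].to_numpy(float))
    post = np.sort(df.loc[df["train"] == "post", "time_s"].to_numpy(float))
    return SpikeTrain(pre, pulse_width), SpikeTrain(post, pulse_width)
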