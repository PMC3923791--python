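"""Shared fixtures: parameter presets, random-train factories, and an
explicit nearest-predecessor-search oracle for the triplet rule."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tstdpsim.presets import (
    DEFAULT_DEVICE,
    HIPPOCAMPAL_PARAMS,
    VISUAL_CORTEX_PARAMS,
    hippocampal_biases,
    visual_cortex_biases,
)
from tstdpsim.protocols import SpikeTrain
from tstdpsim.rules import TripletParams


@pytest.fixture
def hippo_params() -> TripletParams:
    return HIPPOCAMPAL_PARAMS


@pytest.fixture
def vc_params() -> TripletParams:
    return VISUAL_CORTEX_PARAMS


@pytest.fixture
def device():
    return DEFAULT_DEVICE


@pytest.fixture
def hippo_biases():
    return hippocampal_biases()


@pytest.fixture
def vc_biases():
    return visual_cortex_biases()


def oracle_tstdp(pre_times, post_times, p: TripletParams) -> float:
    """Brute-force nearest-spike triplet rule: for every spike, explicitly
    search the full opposite train for the nearest predecessor (pre spikes
    at equal times processed before post spikes)."""
    total = 0.0
    for t in post_times:
        earlier_pre = [s for s in pre_times if s <= t]
        if not earlier_pre:
            continue
        dt1 = t - max(earlier_pre)
        bracket = p.A2_plus
        earlier_post = [s for s in post_times if s < t]
        if earlier_post:
            dt2 = t - max(earlier_post) - p.epsilon
            bracket += p.A3_plus * math.exp(-dt2 / p.tau_y)
        total += math.exp(-dt1 / p.tau_plus) * bracket
    for t in pre_times:
        earlier_post = [s for s in post_times if s < t]
        if not earlier_post:
            continue
        dt1 = t - max(earlier_post)
        bracket = p.A2_minus
        earlier_pre = [s for s in pre_times if s < t]
        if earlier_pre:
            dt2 = t - max(earlier_pre) - p.epsilon
            bracket += p.A3_minus * math.exp(-dt2 / p.tau_x)
        total -= math.exp(-dt1 / p.tau_minus) * bracket
    return total


@pytest.fixture
def oracle():
    return oracle_tstdp


def random_train_pair(rng: np.random.Generator, pulse_width: float = 1e-3):
    """A pair of random valid spike trains with gaps >= pulse width."""
    n_pre = int(rng.integers(0, 25))
    n_post = int(rng.integers(0, 25))

    def train(n):
        gaps = rng.uniform(pulse_width, 60e-3, size=n)
        return SpikeTrain(np.cumsum(gaps) + rng.uniform(0, 10e-3), pulse_width)

    return train(n_pre), train(n_post)


@pytest.fixture
def train_factory():
    return random_train_pair
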