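"""Stimulation-protocol spike-train generators.

Every electrophysiological stimulation paradigm used to characterise
spike-timing-dependent plasticity (STDP) boils down to a pair of spike trains
— one pre-synaptic, one post-synaptic — with carefully controlled relative
timing.  This module generates those trains on the *biological* timescale
(seconds, 1 ms pulses).  The 1000x accelerated timescale of the hardware
model is applied only inside :mod:`tstdpsim.circuit`.

Sign convention used throughout the package: ``dt = t_post - t_pre``, so a
positive ``dt`` is a causal pre-before-post pairing (the one that produces
long-term potentiation at low repetition rates).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "BIO_PULSE_WIDTH",
    "SpikeTrain",
    "ProtocolSpec",
    "make_pairing",
    "make_triplet",
    "make_extra_triplet",
    "make_quadruplet",
    "make_poisson_pair",
    "delay_train",
    "TRIPLET_COMBOS",
    "EXTRA_TRIPLET_COMBOS",
]

#: Biological spike-pulse width in seconds (1 ms; maps to 1 us at the
#: accelerated circuit timescale).
BIO_PULSE_WIDTH = 1e-3


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered sequence of spike (pulse-onset) times.

    Parameters
    ----------
    times
        Strictly increasing, non-negative onset times in seconds.
    pulse_width
        Pulse duration in seconds.  Consecutive onsets must be separated by
        at least one pulse width so pulses within a train never overlap.
    """

    times: np.ndarray
    pulse_width: float = BIO_PULSE_WIDTH

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).ravel()
        object.__setattr__(self, "times", t)
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if t.size:
            if t[0] < 0:
                raise ValueError("spike times must be non-negative")
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise ValueError("spike times must be strictly increasing")
            # 1e-12 slack absorbs float round-off in k/rho + dt constructions
            if np.any(gaps < self.pulse_width - 1e-12):
                raise ValueError(
                    "consecutive onsets closer than one pulse width"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, delay: float) -> "SpikeTrain":
        """Return a copy with all times shifted by ``+delay`` (>= 0)."""
        if delay < 0:
            raise ValueError("delay must be non-negative")
        return SpikeTrain(self.times + delay, self.pulse_width)


TRIPLET_COMBOS = ("pre_post_pre", "post_pre_post")

#: Extra-triplet combos: the label lists the identity of the three spikes in
#: temporal order.
EXTRA_TRIPLET_COMBOS = (
    "pre_pre_post",
    "pre_post_pre",
    "pre_post_post",
    "post_pre_pre",
    "post_pre_post",
    "post_post_pre",
)


def _pair_trains(
    pre_times, post_times, pulse_width: float
) -> Tuple[SpikeTrain, SpikeTrain]:
    return (
        SpikeTrain(np.sort(np.asarray(pre_times, float)), pulse_width),
        SpikeTrain(np.sort(np.asarray(post_times, float)), pulse_width),
    )


def make_pairing(
    dt: float,
    n_reps: int = 60,
    rho: float = 1.0,
    pulse_width: float = BIO_PULSE_WIDTH,
) -> Tuple[SpikeTrain, SpikeTrain]:
    """Pairing (STDP window) protocol: ``n_reps`` pre/post pairs at ``rho`` Hz.

    Pre spikes sit at ``k / rho`` and post spikes at ``k / rho + dt``; for
    negative ``dt`` the whole set is shifted so all times are non-negative.

    Raises
    ------
    ValueError
        If ``dt`` is zero (coincident pulses) or ``|dt| >= 1/rho`` (pairs
        from consecutive repetitions would interleave ambiguously).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dt == 0:
        raise ValueError("dt must be nonzero (coincident pulses)")
    if abs(dt) >= 1.0 / rho:
        raise ValueError("|dt| must be smaller than the pair period 1/rho")
    base = np.arange(n_reps) / rho
    pre = base.copy()
    post = base + dt
    if dt < 0:
        pre -= dt
        post -= dt
    return _pair_trains(pre, post, pulse_width)


def make_triplet(
    dt1: float,
    dt2: float,
    combo: str,
    n_reps: int = 60,
    rho: float = 1.0,
    pulse_width: float = BIO_PULSE_WIDTH,
) -> Tuple[SpikeTrain, SpikeTrain]:
    """Hippocampal-style triplet protocol (pre-post-pre or post-pre-post).

    Within repetition ``k`` (base time ``k/rho``) the three spikes sit at
    ``base``, ``base + dt1`` and ``base + dt1 + dt2``; the combo label says
    which train each belongs to.
    """
    if combo not in TRIPLET_COMBOS:
        raise ValueError(f"combo must be one of {TRIPLET_COMBOS}")
    if dt1 <= 0 or dt2 <= 0:
        raise ValueError("dt1 and dt2 must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dt1 + dt2 >= 1.0 / rho:
        raise ValueError("triplet span must be shorter than 1/rho")
    base = np.arange(n_reps) / rho
    outer = np.concatenate([base, base + dt1 + dt2])
    inner = base + dt1
    if combo == "pre_post_pre":
        return _pair_trains(outer, inner, pulse_width)
    return _pair_trains(inner, outer, pulse_width)


def make_extra_triplet(
    dt1: float,
    dt2: float,
    combo: str,
    n_reps: int = 60,
    rho: float = 0.2,
    pulse_width: float = BIO_PULSE_WIDTH,
) -> Tuple[SpikeTrain, SpikeTrain]:
    """All-combination triplet protocol (60 reps at 0.2 Hz by default).

    ``dt1`` and ``dt2`` are the two consecutive inter-spike gaps (leftmost
    and rightmost adjacent pair, respectively); the combo label is
    authoritative for the temporal ordering of pre and post spikes, and gap
    values are taken in absolute value.  Zero gaps are rejected.
    """
    if combo not in EXTRA_TRIPLET_COMBOS:
        raise ValueError(f"combo must be one of {EXTRA_TRIPLET_COMBOS}")
    if dt1 == 0 or dt2 == 0:
        raise ValueError("dt1 and dt2 must be nonzero")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    g1, g2 = abs(dt1), abs(dt2)
    if g1 + g2 >= 1.0 / rho:
        raise ValueError("triplet span must be shorter than 1/rho")
    offsets = np.array([0.0, g1, g1 + g2])
    kinds = combo.split("_")
    base = np.arange(n_reps) / rho
    pre_t = np.concatenate(
        [base + off for off, kind in zip(offsets, kinds) if kind == "pre"]
    )
    post_t = np.concatenate(
        [base + off for off, kind in zip(offsets, kinds) if kind == "post"]
    )
    return _pair_trains(pre_t, post_t, pulse_width)


def make_quadruplet(
    T: float,
    dt: float = 5e-3,
    n_reps: int = 60,
    rho: float = 1.0,
    pulse_width: float = BIO_PULSE_WIDTH,
) -> Tuple[SpikeTrain, SpikeTrain]:
    """Quadruplet protocol: a post-pre and a pre-post pair separated by ``T``.

    For ``T > 0`` the post-pre pair comes first (post, pre, pre, post at
    offsets 0, dt, dt+T, 2 dt+T); for ``T < 0`` the order is mirrored
    (pre-post precedes post-pre).  ``T`` is measured between the two inner
    (pre for T>0, post for T<0) spikes; total span is ``2 dt + |T|``.
    """
    if T == 0:
        raise ValueError("T must be nonzero (coincident inner spikes)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    span = 2 * dt + abs(T)
    if span >= 1.0 / rho:
        raise ValueError("quadruplet span must be shorter than 1/rho")
    base = np.arange(n_reps) / rho
    inner = np.concatenate([base + dt, base + dt + abs(T)])
    outer = np.concatenate([base, base + span])
    if T > 0:
        return _pair_trains(inner, outer, pulse_width)  # post,pre,pre,post
    return _pair_trains(outer, inner, pulse_width)  # pre,post,post,pre


def _poisson_train(
    rate: float, duration: float, rng: np.random.Generator, pulse_width: float
) -> np.ndarray:
    if rate == 0:
        return np.empty(0)
    # draw exponential inter-arrivals in blocks until past `duration`
    chunks = []
    t_last = 0.0
    n_block = max(int(rate * duration * 1.2) + 16, 64)
    while t_last <= duration:
        block = t_last + np.cumsum(rng.exponential(1.0 / rate, size=n_block))
        chunks.append(block)
        t_last = block[-1]
        n_block = 64
    times = np.concatenate(chunks)
    times = times[times <= duration]
    # sequential refractory thinning (drop any spike closer than one pulse
    # width to the last *kept* spike); collisions are sparse, so resolve the
    # first offender of each run per pass and re-check
    while times.size > 1:
        bad = np.flatnonzero(np.diff(times) < pulse_width) + 1
        if bad.size == 0:
            break
        first_of_run = np.ones(bad.size, bool)
        first_of_run[1:] = np.diff(bad) > 1
        keep = np.ones(times.size, bool)
        keep[bad[first_of_run]] = False
        times = times[keep]
    return times


def make_poisson_pair(
    rho_pre: float,
    rho_post: float,
    duration: float,
    seed: int,
    pulse_width: float = BIO_PULSE_WIDTH,
) -> Tuple[SpikeTrain, SpikeTrain]:
    """Two independent homogeneous Poisson trains, thinned so that no two
    spikes of the same train fall within one pulse width (overlapping pulses
    are physically meaningless for the hardware).  Deterministic for a fixed
    ``seed``."""
    if rho_pre < 0 or rho_post < 0:
        raise ValueError("rates must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    ss_pre, ss_post = np.random.SeedSequence(seed).spawn(2)
    pre = _poisson_train(
        rho_pre, duration, np.random.default_rng(ss_pre), pulse_width
    )
    post = _poisson_train(
        rho_post, duration, np.random.default_rng(ss_post), pulse_width
    )
    return SpikeTrain(pre, pulse_width), SpikeTrain(post, pulse_width)


def delay_train(train: SpikeTrain, delay: float) -> SpikeTrain:
    """Shift a train by ``+delay`` seconds (used to derive the previous-spike
    circuit inputs pre(n-1) / post(n-1))."""
    return train.shifted(delay)


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one stimulation protocol.

    Only the fields relevant to ``kind`` need to be set; :meth:`build`
    validates and dispatches to the generator functions.  Timing fields are
    in seconds, rates in Hz.
    """

    kind: str
    dt: Optional[float] = None
    dt1: Optional[float] = None
    dt2: Optional[float] = None
    T: Optional[float] = None
    combo: Optional[str] = None
    n_reps: int = 60
    rho: float = 1.0
    rho_pre: Optional[float] = None
    rho_post: Optional[float] = None
    duration: Optional[float] = None
    seed: int = 0
    pulse_width: float = BIO_PULSE_WIDTH

    KINDS = ("pairing", "triplet", "extra_triplet", "quadruplet", "poisson_pair")

    def build(self) -> Tuple[SpikeTrain, SpikeTrain]:
        """Generate the (pre, post) spike trains for this protocol."""
        k = self.kind
        if k == "pairing":
            if self.dt is None:
                raise ValueError("pairing requires dt")
            return make_pairing(self.dt, self.n_reps, self.rho, self.pulse_width)
        if k == "triplet":
            if self.dt1 is None or self.dt2 is None or self.combo is None:
                raise ValueError("triplet requires dt1, dt2 and combo")
            return make_triplet(
                self.dt1, self.dt2, self.combo, self.n_reps, self.rho,
                self.pulse_width,
            )
        if k == "extra_triplet":
            if self.dt1 is None or self.dt2 is None or self.combo is None:
                raise ValueError("extra_triplet requires dt1, dt2 and combo")
            return make_extra_triplet(
                self.dt1, self.dt2, self.combo, self.n_reps, self.rho,
                self.pulse_width,
            )
        if k == "quadruplet":
            if self.T is None:
                raise ValueError("quadruplet requires T")
            dt = 5e-3 if self.dt is None else self.dt
            return make_quadruplet(
                self.T, dt, self.n_reps, self.rho, self.pulse_width
            )
        if k == "poisson_pair":
            if self.rho_pre is None or self.rho_post is None or self.duration is None:
                raise ValueError(
                    "poisson_pair requires rho_pre, rho_post and duration"
                )
            return make_poisson_pair(
                self.rho_pre, self.rho_post, self.duration, self.seed,
                self.pulse_width,
            )
        raise ValueError(f"unknown protocol kind {k!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)
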