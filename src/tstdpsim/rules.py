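"""Pair- and triplet-based STDP rules with nearest-spike interaction.

The pair-based rule (PSTDP) changes the synaptic weight by
``+A_plus * exp(-dt/tau_plus)`` at each post-synaptic spike (``dt`` to the
nearest earlier pre-synaptic spike) and ``-A_minus * exp(-dt'/tau_minus)``
at each pre-synaptic spike.  The triplet rule (TSTDP) multiplies each of
these pair terms by a bracket that also senses the previous spike of the
*same* train:

    at a post spike t:  dw += exp(-(t - t_pre)/tau_plus)
                              * [A2+ + A3+ * exp(-(t - t_prevpost - eps)/tau_y)]
    at a pre  spike t:  dw -= exp(-(t - t_post)/tau_minus)
                              * [A2- + A3- * exp(-(t - t_prevpre  - eps)/tau_x)]

with nearest-spike interaction throughout: each spike interacts only with
the most recent spike of the opposite train, and the triplet term is present
only when a previous same-train spike exists.  ``eps`` is a small positive
offset ensuring the same-train trace is read just *before* the current
spike resets it.

Two algebraically identical organisations of the potentiation/depression
update are provided (the expanded sum-of-products form and the factorised
form natural to the hardware realisation); their equivalence is a package
invariant.  Weights are unbounded here — supply-rail saturation lives in
:mod:`tstdpsim.circuit`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence, Tuple, Union

import numpy as np

from .protocols import ProtocolSpec, SpikeTrain

__all__ = [
    "PairParams",
    "TripletParams",
    "RULE_VARIANTS",
    "WeightChangeLog",
    "check_variant",
    "pstdp_apply",
    "tstdp_apply",
    "run_protocol",
    "bcm_sweep",
    "bcm_sweep_pre_driven",
    "crossing_rate",
]

RULE_VARIANTS = (
    "pstdp",
    "tstdp_full",
    "tstdp_minimal_hippocampal",
    "tstdp_minimal_visual_cortex",
)


@dataclass(frozen=True)
class PairParams:
    """PSTDP amplitudes (dimensionless) and time constants (seconds)."""

    A_plus: float
    A_minus: float
    tau_plus: float
    tau_minus: float

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class TripletParams:
    """TSTDP amplitudes (dimensionless) and time constants (seconds).

    ``epsilon`` is the small positive read-out offset of the same-train
    trace (default 1e-6 s, far below every plasticity time constant).
    """

    A2_plus: float
    A2_minus: float
    A3_plus: float
    A3_minus: float
    tau_plus: float
    tau_minus: float
    tau_x: float
    tau_y: float
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        amps = (self.A2_plus, self.A2_minus, self.A3_plus, self.A3_minus)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be non-negative")
        taus = (self.tau_plus, self.tau_minus, self.tau_x, self.tau_y)
        if any(t <= 0 for t in taus):
            raise ValueError("time constants must be positive")
        if not 0 < self.epsilon < min(taus):
            raise ValueError("epsilon must be positive and << min(tau)")


def check_variant(params: TripletParams, variant: str) -> None:
    """Enforce the zero-amplitude constraints implied by a rule variant."""
    if variant not in RULE_VARIANTS:
        raise ValueError(f"variant must be one of {RULE_VARIANTS}")
    if variant in ("tstdp_minimal_hippocampal", "tstdp_minimal_visual_cortex"):
        if params.A3_minus != 0:
            raise ValueError(f"{variant} requires A3_minus = 0")
    if variant == "tstdp_minimal_visual_cortex" and params.A2_plus != 0:
        raise ValueError("tstdp_minimal_visual_cortex requires A2_plus = 0")
    if variant == "pstdp" and (params.A3_plus != 0 or params.A3_minus != 0):
        raise ValueError("pstdp requires A3_plus = A3_minus = 0")


@dataclass(frozen=True)
class WeightChangeLog:
    """Per-event weight-change contributions and their total.

    ``times``/``contributions`` are chronologically ordered (simultaneous
    pre and post events ordered pre-first); ``total_dw`` equals their sum.
    """

    total_dw: float
    times: np.ndarray
    contributions: np.ndarray

    @property
    def events(self) -> Sequence[Tuple[float, float]]:
        return list(zip(self.times.tolist(), self.contributions.tolist()))


class EventTable(NamedTuple):
    """Nearest-spike event geometry shared by the rule and circuit engines.

    Potentiation events are indexed by post spikes, depression events by pre
    spikes.  ``*_dt`` is the lag to the nearest opposite-train predecessor,
    ``*_trip_dt`` the lag to the previous same-train spike; the ``*_has``
    masks flag whether those predecessors exist.  Ties (equal pre and post
    times) resolve pre-first, so a coincident pair potentiates with dt = 0.
    """

    pot_t: np.ndarray
    pot_dt: np.ndarray
    pot_has: np.ndarray
    pot_trip_dt: np.ndarray
    pot_trip_has: np.ndarray
    dep_t: np.ndarray
    dep_dt: np.ndarray
    dep_has: np.ndarray
    dep_trip_dt: np.ndarray
    dep_trip_has: np.ndarray


def event_table(pre: SpikeTrain, post: SpikeTrain) -> EventTable:
    """Compute nearest-predecessor lags for every spike of both trains."""
    pre_t = np.asarray(pre.times, float)
    post_t = np.asarray(post.times, float)

    def lags(own: np.ndarray, other: np.ndarray, side: str):
        if other.size == 0:
            dt = np.full(own.size, np.inf)
            has = np.zeros(own.size, bool)
        else:
            idx = np.searchsorted(other, own, side=side) - 1
            has = idx >= 0
            dt = np.where(has, own - other[np.clip(idx, 0, None)], np.inf)
        trip_has = np.arange(own.size) >= 1
        trip_dt = np.empty(own.size)
        trip_dt[:] = np.inf
        if own.size > 1:
            trip_dt[1:] = np.diff(own)
        return dt, has, trip_dt, trip_has

    # post spikes see pre spikes at <= t (pre processed first on ties)
    pot_dt, pot_has, pot_trip_dt, pot_trip_has = lags(post_t, pre_t, "right")
    # pre spikes see post spikes strictly earlier
    dep_dt, dep_has, dep_trip_dt, dep_trip_has = lags(pre_t, post_t, "left")
    return EventTable(
        post_t, pot_dt, pot_has, pot_trip_dt, pot_trip_has,
        pre_t, dep_dt, dep_has, dep_trip_dt, dep_trip_has,
    )


def _triplet_increments(
    tab: EventTable, p: TripletParams, form: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-event signed contributions in either algebraic organisation."""
    pot_pair = np.where(tab.pot_has, np.exp(-tab.pot_dt / p.tau_plus), 0.0)
    pot_trip = np.where(
        tab.pot_trip_has & tab.pot_has,
        np.exp(-(tab.pot_trip_dt - p.epsilon) / p.tau_y),
        0.0,
    )
    dep_pair = np.where(tab.dep_has, np.exp(-tab.dep_dt / p.tau_minus), 0.0)
    dep_trip = np.where(
        tab.dep_trip_has & tab.dep_has,
        np.exp(-(tab.dep_trip_dt - p.epsilon) / p.tau_x),
        0.0,
    )
    if form == "factored":
        pot = pot_pair * (p.A2_plus + p.A3_plus * pot_trip)
        dep = dep_pair * (p.A2_minus + p.A3_minus * dep_trip)
    elif form == "expanded":
        pot = p.A2_plus * pot_pair + p.A3_plus * pot_pair * pot_trip
        dep = p.A2_minus * dep_pair + p.A3_minus * dep_pair * dep_trip
    else:
        raise ValueError("form must be 'factored' or 'expanded'")
    return pot, -dep


def _merge_log(
    tab: EventTable, pot: np.ndarray, dep: np.ndarray
) -> WeightChangeLog:
    times = np.concatenate([tab.dep_t, tab.pot_t])
    contrib = np.concatenate([dep, pot])
    # stable sort keeps pre (listed first) ahead of post on equal times
    order = np.argsort(times, kind="stable")
    times, contrib = times[order], contrib[order]
    return WeightChangeLog(float(contrib.sum()), times, contrib)


def tstdp_apply(
    pre: SpikeTrain,
    post: SpikeTrain,
    params: TripletParams,
    variant: str = "tstdp_full",
    form: str = "factored",
) -> WeightChangeLog:
    """Apply the nearest-spike triplet STDP rule to a pair of trains.

    ``form`` selects the algebraic organisation of the update ("factored"
    is the hardware-style factorisation, "expanded" the plain sum); the two
    agree to floating-point round-off on any input.
    """
    check_variant(params, variant)
    tab = event_table(pre, post)
    pot, dep = _triplet_increments(tab, params, form)
    return _merge_log(tab, pot, dep)


def pstdp_apply(
    pre: SpikeTrain, post: SpikeTrain, params: PairParams
) -> WeightChangeLog:
    """Apply the nearest-spike pair-based STDP rule."""
    tab = event_table(pre, post)
    pot = np.where(
        tab.pot_has, params.A_plus * np.exp(-tab.pot_dt / params.tau_plus), 0.0
    )
    dep = np.where(
        tab.dep_has, params.A_minus * np.exp(-tab.dep_dt / params.tau_minus), 0.0
    )
    return _merge_log(tab, pot, -dep)


def run_protocol(
    spec: ProtocolSpec,
    params: Union[PairParams, TripletParams],
    variant: str = "tstdp_full",
) -> float:
    """Generate a protocol's trains, apply the rule, return total dw."""
    pre, post = spec.build()
    if isinstance(params, PairParams):
        return pstdp_apply(pre, post, params).total_dw
    return tstdp_apply(pre, post, params, variant).total_dw


def _sweep(
    params: TripletParams,
    variant: str,
    pre_rates: np.ndarray,
    post_rates: np.ndarray,
    duration: float,
    trials: int,
    seed: int,
    pulse_width: float,
) -> Tuple[np.ndarray, np.ndarray]:
    from .protocols import make_poisson_pair

    check_variant(params, variant)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if np.any(pre_rates < 0) or np.any(post_rates < 0):
        raise ValueError("rates must be non-negative")
    children = np.random.SeedSequence(seed).spawn(len(post_rates))
    means = np.empty(len(post_rates))
    sds = np.empty(len(post_rates))
    for i, (rp, rq) in enumerate(zip(pre_rates, post_rates)):
        trial_seeds = children[i].generate_state(trials) % (2**31)
        dws = np.empty(trials)
        for j in range(trials):
            pre, post = make_poisson_pair(
                rp, rq, duration, int(trial_seeds[j]), pulse_width
            )
            dws[j] = tstdp_apply(pre, post, params, variant).total_dw
        means[i] = dws.mean()
        sds[i] = dws.std()
    return means, sds


def bcm_sweep(
    params: TripletParams,
    variant: str = "tstdp_minimal_visual_cortex",
    rho_pre: float = 10.0,
    rho_post_grid: Sequence[float] = tuple(np.arange(0.0, 50.1, 2.5)),
    duration: float = 200.0,
    trials: int = 10,
    seed: int = 0,
    pulse_width: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rate-based (BCM-style) sweep: Poisson pre at fixed ``rho_pre``, post
    rate swept over ``rho_post_grid``; returns (grid, mean dw, SD dw) over
    ``trials`` independent train draws per grid point.

    At zero post rate the weight change is exactly zero: both the
    potentiation trigger (a post spike) and the depression pair term (a
    preceding post spike) are absent.
    """
    grid = np.asarray(rho_post_grid, float)
    means, sds = _sweep(
        params, variant, np.full(grid.size, float(rho_pre)), grid,
        duration, trials, seed, pulse_width,
    )
    return grid, means, sds


def bcm_sweep_pre_driven(
    params: TripletParams,
    variant: str = "tstdp_minimal_visual_cortex",
    rho_grid: Sequence[float] = tuple(np.arange(0.0, 50.1, 2.5)),
    duration: float = 200.0,
    trials: int = 10,
    seed: int = 0,
    pulse_width: float = 1e-3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-synaptically driven BCM sweep with a linear neuron assumption
    (post rate equal to pre rate at every grid point)."""
    grid = np.asarray(rho_grid, float)
    means, sds = _sweep(
        params, variant, grid, grid, duration, trials, seed, pulse_width
    )
    return grid, means, sds


def crossing_rate(grid: np.ndarray, means: np.ndarray) -> float:
    """Linearly interpolated rate at which mean dw crosses from LTD (<0) to
    LTP (>0); the sliding modification threshold of the BCM analogy.

    Returns NaN when no negative-to-positive crossing exists.  The scan
    starts above zero rate (dw is identically 0 there).
    """
    grid = np.asarray(grid, float)
    means = np.asarray(means, float)
    for i in range(1, len(grid) - 1):
        if means[i] < 0 and means[i + 1] >= 0:
            x0, x1, y0, y1 = grid[i], grid[i + 1], means[i], means[i + 1]
            return float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return float("nan")


def pair_params_from_triplet(params: TripletParams) -> PairParams:
    """The PSTDP rule obtained by zeroing both triplet amplitudes."""
    return PairParams(
        A_plus=params.A2_plus,
        A_minus=params.A2_minus,
        tau_plus=params.tau_plus,
        tau_minus=params.tau_minus,
    )


def zeroed_triplet(params: TripletParams) -> TripletParams:
    """Copy of ``params`` with the triplet amplitudes set to zero."""
    return replace(params, A3_plus=0.0, A3_minus=0.0)
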