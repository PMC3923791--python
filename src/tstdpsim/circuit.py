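"""Behavioral model of the accelerated-time subthreshold TSTDP synapse.

The hardware realises the triplet rule with a handful of transistors biased
in the subthreshold (weak-inversion) region, where the drain current depends
exponentially on the gate voltage, ``I = I0 * exp(kappa * Vg / UT)``.  Each
plasticity time constant is produced by a node capacitor that is pulled to
ground by its triggering spike pulse and then recharged linearly toward the
supply by a bias-controlled ramp current; the instantaneous node voltage
gates an exponential branch current onto (potentiation) or off (depression)
a weight capacitor ``Cw``.  The circuit runs 1000x faster than biology
(1 us pulses model 1 ms spikes); trains enter on the biological timescale
and are rescaled internally.

Three variants are modelled: the full 18-transistor circuit, the
14-transistor minimal circuit that drops the triplet-depression branch
(M1-M4), and the 13-transistor minimal circuit that additionally drops the
pair-potentiation amplitude device (M7).

Two simulators are provided and cross-validated against each other:

* :func:`simulate_event` — event-driven closed-form update per spike, the
  direct hardware analogue of the triplet rule (each post spike adds
  ``(pulse_width/Cw) * exp(-dt/tau+) * [I_A2p + I_A3p * exp(-dt2/tau_y)]``
  volts to the weight node, and symmetrically for depression), with each
  branch cut off once its node ramp has saturated at the supply rail;
* :func:`simulate_ramp_ode` — a time-stepped simulation of the triangular
  node voltages and the gated branch currents, integrated on ``Cw``.

The weight voltage is clamped to the supply rails in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np

from .protocols import SpikeTrain
from .rules import EventTable, TripletParams, event_table

__all__ = [
    "DeviceParams",
    "CircuitBiases",
    "CIRCUIT_VARIANTS",
    "EffectiveParams",
    "biases_to_effective",
    "bias_for_amplitude",
    "bias_for_tau",
    "simulate_event",
    "simulate_ramp_ode",
    "apply_mismatch",
    "active_transistors",
    "draw_mismatch",
    "triplet_params_from_effective",
    "CircuitResult",
    "RampResult",
]

CIRCUIT_VARIANTS = ("full18", "minimal14", "minimal13")


@dataclass(frozen=True)
class DeviceParams:
    """Process/device constants of the behavioral model.

    ``I0``, ``kappa`` and ``UT`` are representative subthreshold constants
    (the pre-exponential leakage current, the gate coupling ("slope")
    factor, and the thermal voltage); all are configurable since the model
    is not tied to one process.  ``Cw`` is the weight capacitor, the
    ``Cp_*`` are the small node capacitors that set the four plasticity
    time constants together with their ramp currents.  ``time_accel`` is
    the acceleration factor between biological and circuit time and
    ``pulse_width_accel`` the spike pulse width on the circuit timescale.
    """

    I0: float = 1e-15
    kappa: float = 0.7
    UT: float = 0.02585
    Vdd: float = 3.3
    Cw: float = 1e-12
    Cp_pot: float = 5e-15
    Cp_dep: float = 5e-15
    Cp_y: float = 5e-15
    Cp_x: float = 5e-15
    pulse_width_accel: float = 1e-6
    time_accel: float = 1000.0

    def __post_init__(self) -> None:
        vals = (
            self.I0, self.kappa, self.UT, self.Vdd, self.Cw, self.Cp_pot,
            self.Cp_dep, self.Cp_y, self.Cp_x, self.pulse_width_accel,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all device parameters must be positive")
        if self.time_accel < 1:
            raise ValueError("time_accel must be >= 1")


@dataclass(frozen=True)
class CircuitBiases:
    """Gate bias voltages (volts, within the supply rails).

    Amplitude biases ``V_A2p`` (M7), ``V_A2m`` (M12), ``V_A3p`` (M16) and
    ``V_A3m`` (M3, full circuit only) set the branch currents; ramp biases
    ``V_tp`` (M5), ``V_td`` (M14), ``V_ty`` (M17) and ``V_tx`` (M2, full
    circuit only) set the recharge currents and hence the time constants.
    """

    V_A2p: float
    V_A2m: float
    V_A3p: float
    V_tp: float
    V_td: float
    V_ty: float
    V_tx: float = 3.0
    V_A3m: float = 0.0


class EffectiveParams(NamedTuple):
    """Bias-independent summary of the circuit: branch amplitude currents
    (amps), realised time constants and ramp-saturation windows (seconds,
    circuit timescale).  A branch contributes nothing once the lag exceeds
    its window (the node ramp has reached the rail)."""

    I_A2p: float
    I_A2m: float
    I_A3p: float
    I_A3m: float
    tau_plus: float
    tau_minus: float
    tau_x: float
    tau_y: float
    window_plus: float
    window_minus: float
    window_x: float
    window_y: float


def _amp_current(V: float, dev: DeviceParams) -> float:
    return dev.I0 * math.exp(dev.kappa * V / dev.UT)


def _ramp_current(V_bias: float, dev: DeviceParams) -> float:
    # PMOS convention: the ramp device sources from Vdd; a higher bias means
    # a smaller recharge current and therefore a slower ramp / larger tau.
    return dev.I0 * math.exp(dev.kappa * (dev.Vdd - V_bias) / dev.UT)


def bias_for_amplitude(I: float, dev: DeviceParams) -> float:
    """Gate voltage of a series amplitude transistor carrying current ``I``."""
    if I <= 0:
        raise ValueError("amplitude current must be positive")
    return dev.UT / dev.kappa * math.log(I / dev.I0)


def bias_for_tau(tau: float, C_node: float, dev: DeviceParams) -> float:
    """Ramp-control gate voltage realising time constant ``tau`` (circuit
    timescale) on a node of capacitance ``C_node``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    I_ramp = C_node * dev.UT / (dev.kappa * tau)
    return dev.Vdd - dev.UT / dev.kappa * math.log(I_ramp / dev.I0)


def _check_variant(variant: str) -> None:
    if variant not in CIRCUIT_VARIANTS:
        raise ValueError(f"variant must be one of {CIRCUIT_VARIANTS}")


def biases_to_effective(
    biases: CircuitBiases,
    device: DeviceParams = DeviceParams(),
    variant: str = "minimal14",
) -> EffectiveParams:
    """Map gate biases to amplitude currents, time constants and windows.

    Time constants follow ``tau = C_node * UT / (kappa * I_ramp)`` — the
    exponential decay seen by a branch whose gating node ramps linearly at
    ``I_ramp / C_node`` volts per second — and each window is the time for
    that ramp to traverse the rails, ``C_node * Vdd / I_ramp``.
    """
    _check_variant(variant)
    for name in ("V_A2p", "V_A2m", "V_A3p", "V_tp", "V_td", "V_ty", "V_tx",
                 "V_A3m"):
        v = getattr(biases, name)
        if not 0 <= v <= device.Vdd:
            raise ValueError(f"{name}={v} outside supply rails [0, {device.Vdd}]")

    def ramp(bias: float, C: float) -> Tuple[float, float]:
        I = _ramp_current(bias, device)
        tau = C * device.UT / (device.kappa * I)
        window = C * device.Vdd / I
        return tau, window

    tau_p, win_p = ramp(biases.V_tp, device.Cp_pot)
    tau_m, win_m = ramp(biases.V_td, device.Cp_dep)
    tau_y, win_y = ramp(biases.V_ty, device.Cp_y)
    tau_x, win_x = ramp(biases.V_tx, device.Cp_x)
    I_A2p = 0.0 if variant == "minimal13" else _amp_current(biases.V_A2p, device)
    I_A3m = _amp_current(biases.V_A3m, device) if variant == "full18" else 0.0
    return EffectiveParams(
        I_A2p=I_A2p,
        I_A2m=_amp_current(biases.V_A2m, device),
        I_A3p=_amp_current(biases.V_A3p, device),
        I_A3m=I_A3m,
        tau_plus=tau_p, tau_minus=tau_m, tau_x=tau_x, tau_y=tau_y,
        window_plus=win_p, window_minus=win_m, window_x=win_x, window_y=win_y,
    )


def triplet_params_from_effective(
    eff: EffectiveParams, device: DeviceParams, epsilon: float = 1e-12
) -> TripletParams:
    """The mathematical triplet rule this circuit realises: amplitudes are
    the per-event weight-voltage steps ``I * pulse_width / Cw`` and time
    constants are rescaled back to biological time."""
    s = device.pulse_width_accel / device.Cw
    a = device.time_accel
    return TripletParams(
        A2_plus=eff.I_A2p * s, A2_minus=eff.I_A2m * s,
        A3_plus=eff.I_A3p * s, A3_minus=eff.I_A3m * s,
        tau_plus=eff.tau_plus * a, tau_minus=eff.tau_minus * a,
        tau_x=eff.tau_x * a, tau_y=eff.tau_y * a,
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# event-driven simulator


class CircuitResult(NamedTuple):
    """Weight-voltage trajectory sampled after every spike event."""

    times: np.ndarray  # circuit-timescale event times (s)
    v_w: np.ndarray    # weight voltage after each event (V)
    total_dv: float    # final minus initial weight voltage (V)


def _accelerate(
    pre: SpikeTrain, post: SpikeTrain, device: DeviceParams
) -> Tuple[SpikeTrain, SpikeTrain]:
    pw = device.pulse_width_accel
    a = device.time_accel
    p = SpikeTrain(pre.times / a, pw)
    q = SpikeTrain(post.times / a, pw)
    # cross-train pulses must not overlap on the accelerated timescale
    if p.times.size and q.times.size:
        idx = np.searchsorted(q.times, p.times)
        for nbr in (np.clip(idx - 1, 0, q.times.size - 1),
                    np.clip(idx, 0, q.times.size - 1)):
            gap = np.abs(p.times - q.times[nbr])
            if np.any(gap < pw - 1e-18):
                raise ValueError(
                    "pre and post pulses overlap on the accelerated timescale"
                )
    return p, q


def _event_increments(
    tab: EventTable, eff: EffectiveParams, device: DeviceParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Signed weight-voltage steps for every potentiation/depression event."""
    scale = device.pulse_width_accel / device.Cw
    pot_gate = tab.pot_has & (tab.pot_dt <= eff.window_plus)
    pot_pair = np.where(pot_gate, np.exp(-tab.pot_dt / eff.tau_plus), 0.0)
    pot_trip = np.where(
        tab.pot_trip_has & (tab.pot_trip_dt <= eff.window_y),
        np.exp(-tab.pot_trip_dt / eff.tau_y),
        0.0,
    )
    dep_gate = tab.dep_has & (tab.dep_dt <= eff.window_minus)
    dep_pair = np.where(dep_gate, np.exp(-tab.dep_dt / eff.tau_minus), 0.0)
    dep_trip = np.where(
        tab.dep_trip_has & (tab.dep_trip_dt <= eff.window_x),
        np.exp(-tab.dep_trip_dt / eff.tau_x),
        0.0,
    )
    pot = scale * pot_pair * (eff.I_A2p + eff.I_A3p * pot_trip)
    dep = -scale * dep_pair * (eff.I_A2m + eff.I_A3m * dep_trip)
    return pot, dep


def _clamped_trajectory(
    times: np.ndarray, steps: np.ndarray, w_init: float, Vdd: float
) -> Tuple[np.ndarray, float]:
    """Accumulate per-event steps with rail clamping; returns (v_w, final)."""
    free = w_init + np.cumsum(steps)
    if free.size == 0:
        return free, w_init
    if free.min() >= 0.0 and free.max() <= Vdd:
        return free, float(free[-1])
    v = np.empty_like(free)
    w = w_init
    for i, dv in enumerate(steps):
        w = min(max(w + dv, 0.0), Vdd)
        v[i] = w
    return v, float(w)


def prepare_event_tables(
    pre: SpikeTrain, post: SpikeTrain, device: DeviceParams
) -> EventTable:
    """Precompute the accelerated-timescale event geometry of a protocol so
    that many parameter sets (e.g. Monte-Carlo mismatch draws) can be
    evaluated on it cheaply."""
    p, q = _accelerate(pre, post, device)
    return event_table(p, q)


def total_dv_from_table(
    tab: EventTable,
    eff: EffectiveParams,
    device: DeviceParams,
    w_init: Optional[float] = None,
) -> float:
    """Total weight-voltage change for a precomputed event table."""
    if w_init is None:
        w_init = device.Vdd / 2
    pot, dep = _event_increments(tab, eff, device)
    times = np.concatenate([tab.dep_t, tab.pot_t])
    steps = np.concatenate([dep, pot])
    order = np.argsort(times, kind="stable")
    _, final = _clamped_trajectory(times[order], steps[order], w_init, device.Vdd)
    return final - w_init


def _resolve_effective(
    params: Union[CircuitBiases, EffectiveParams],
    device: DeviceParams,
    variant: str,
) -> EffectiveParams:
    if isinstance(params, EffectiveParams):
        return params
    return biases_to_effective(params, device, variant)


def simulate_event(
    pre: SpikeTrain,
    post: SpikeTrain,
    biases: Union[CircuitBiases, EffectiveParams],
    device: DeviceParams = DeviceParams(),
    variant: str = "minimal14",
    w_init: Optional[float] = None,
) -> CircuitResult:
    """Event-driven weight update on the accelerated timescale.

    At each post spike the weight node charges by
    ``(pulse_width/Cw) * exp(-dt1/tau+) * [I_A2p + I_A3p * exp(-dt2/tau_y)]``
    (pair lag ``dt1`` to the nearest pre spike, triplet lag ``dt2`` to the
    previous post spike, each branch active only within its ramp window);
    each pre spike discharges it symmetrically.  The weight voltage is
    clamped to ``[0, Vdd]`` after every event.
    """
    _check_variant(variant)
    eff = _resolve_effective(biases, device, variant)
    if w_init is None:
        w_init = device.Vdd / 2
    if not 0 <= w_init <= device.Vdd:
        raise ValueError("w_init outside supply rails")
    tab = prepare_event_tables(pre, post, device)
    pot, dep = _event_increments(tab, eff, device)
    times = np.concatenate([tab.dep_t, tab.pot_t])
    steps = np.concatenate([dep, pot])
    order = np.argsort(times, kind="stable")
    times, steps = times[order], steps[order]
    v_w, final = _clamped_trajectory(times, steps, w_init, device.Vdd)
    return CircuitResult(times, v_w, final - w_init)


# ---------------------------------------------------------------------------
# ramp (time-stepped) simulator


class RampResult(NamedTuple):
    """Sampled node-voltage and weight trajectories of the ramp simulator."""

    times: np.ndarray
    v_w: np.ndarray
    v_pot: np.ndarray
    v_dep: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    total_dv: float


def _node_voltage(
    t: np.ndarray, triggers: np.ndarray, slope: float, pw: float, Vdd: float
) -> np.ndarray:
    """Triangular node voltage: at rest the node sits at the rail; each
    trigger pulse holds it at ground for one pulse width, after which it
    ramps linearly back toward the rail."""
    t = np.asarray(t, float)
    if triggers.size == 0:
        return np.full(t.shape, Vdd)
    idx = np.searchsorted(triggers, t, side="right") - 1
    has = idx >= 0
    since = np.where(has, t - triggers[np.clip(idx, 0, None)], np.inf)
    v = np.where(since < pw, 0.0, np.minimum((since - pw) * slope, Vdd))
    return np.where(has, v, Vdd)


def simulate_ramp_ode(
    pre: SpikeTrain,
    post: SpikeTrain,
    biases: Union[CircuitBiases, EffectiveParams],
    device: DeviceParams = DeviceParams(),
    variant: str = "minimal14",
    step: Optional[float] = None,
    w_init: Optional[float] = None,
) -> RampResult:
    """Time-stepped simulation of the node ramps and gated branch currents.

    Node dynamics: the potentiation node is triggered by pre spikes, the
    depression node by post spikes, and the two triplet nodes by the
    internally delayed copies of the trains (delayed by one pulse width, the
    previous-spike inputs of the hardware).  Branch currents follow the
    subthreshold exponential of the instantaneous node voltage and flow only
    while the gating pulse of the opposite train is high; the weight
    capacitor integrates them, clamped to the rails.  ``step`` must not
    exceed a tenth of the pulse width.
    """
    _check_variant(variant)
    eff = _resolve_effective(biases, device, variant)
    pw = device.pulse_width_accel
    if step is None:
        step = pw / 20
    if step > pw / 10:
        raise ValueError("step must be <= pulse_width_accel / 10")
    if w_init is None:
        w_init = device.Vdd / 2
    if not 0 <= w_init <= device.Vdd:
        raise ValueError("w_init outside supply rails")
    p, q = _accelerate(pre, post, device)
    kUT = device.kappa / device.UT
    Vdd = device.Vdd

    pot_trig = p.times
    dep_trig = q.times
    y_trig = q.times + pw  # delayed post: previous-spike input
    x_trig = p.times + pw  # delayed pre

    slope_pot = Vdd / eff.window_plus
    slope_dep = Vdd / eff.window_minus
    slope_y = Vdd / eff.window_y
    slope_x = Vdd / eff.window_x

    # gating pulses in chronological order; +1 -> potentiation (post pulse)
    pulses = sorted(
        [(t, +1) for t in q.times] + [(t, -1) for t in p.times]
    )
    n_sub = max(int(math.ceil(pw / step)), 10)
    h = pw / n_sub
    offsets = (np.arange(n_sub) + 0.5) * h

    t_out = [np.array([0.0])]
    w_out = [np.array([w_init])]
    w = w_init
    for t0, sign in pulses:
        ts = t0 + offsets
        vp = _node_voltage(ts, pot_trig, slope_pot, pw, Vdd)
        vy = _node_voltage(ts, y_trig, slope_y, pw, Vdd)
        vd = _node_voltage(ts, dep_trig, slope_dep, pw, Vdd)
        vx = _node_voltage(ts, x_trig, slope_x, pw, Vdd)
        if sign > 0:
            cur = np.exp(-kUT * vp) * (eff.I_A2p + eff.I_A3p * np.exp(-kUT * vy))
        else:
            cur = -np.exp(-kUT * vd) * (eff.I_A2m + eff.I_A3m * np.exp(-kUT * vx))
        dvs = cur * h / device.Cw
        free = w + np.cumsum(dvs)
        if free.min() >= 0.0 and free.max() <= Vdd:
            traj = free
            w = float(free[-1])
        else:
            traj = np.empty(n_sub)
            for i, dv in enumerate(dvs):
                w = min(max(w + dv, 0.0), Vdd)
                traj[i] = w
        t_out.append(ts)
        w_out.append(traj)

    times = np.concatenate(t_out)
    v_w = np.concatenate(w_out)
    v_pot = _node_voltage(times, pot_trig, slope_pot, pw, Vdd)
    v_dep = _node_voltage(times, dep_trig, slope_dep, pw, Vdd)
    v_x = _node_voltage(times, x_trig, slope_x, pw, Vdd)
    v_y = _node_voltage(times, y_trig, slope_y, pw, Vdd)
    return RampResult(times, v_w, v_pot, v_dep, v_x, v_y, w - w_init)


# ---------------------------------------------------------------------------
# transistor mismatch

#: Fixed mapping from transistor label to the EffectiveParams entries its
#: threshold deviation rescales.  Series devices of a branch multiply that
#: branch's amplitude current; shared series devices (M8/M9, M10/M11) touch
#: both branches they carry.  Ramp devices rescale their tau and window.
#: Switch transistors are ideal and have no effect.
_AMP_MAP: Dict[str, Tuple[str, ...]] = {
    "M7": ("I_A2p",),
    "M8": ("I_A2p", "I_A3p"),
    "M9": ("I_A2p", "I_A3p"),
    "M15": ("I_A3p",),
    "M16": ("I_A3p",),
    "M10": ("I_A2m", "I_A3m"),
    "M11": ("I_A2m", "I_A3m"),
    "M12": ("I_A2m",),
    "M3": ("I_A3m",),
    "M4": ("I_A3m",),
}
_RAMP_MAP: Dict[str, Tuple[str, str]] = {
    "M5": ("tau_plus", "window_plus"),
    "M14": ("tau_minus", "window_minus"),
    "M17": ("tau_y", "window_y"),
    "M2": ("tau_x", "window_x"),
}
_SWITCHES = ("M1", "M6", "M13", "M18")


def active_transistors(variant: str) -> Tuple[str, ...]:
    """Transistor labels present in a circuit variant."""
    _check_variant(variant)
    labels = [f"M{i}" for i in range(1, 19)]
    if variant in ("minimal14", "minimal13"):
        labels = [m for m in labels if m not in ("M1", "M2", "M3", "M4")]
    if variant == "minimal13":
        labels.remove("M7")
    return tuple(labels)


def apply_mismatch(
    effective: EffectiveParams,
    sample: Mapping[str, float],
    device: DeviceParams = DeviceParams(),
    variant: str = "minimal14",
) -> EffectiveParams:
    """Perturb the effective parameters by per-transistor threshold-voltage
    deviations.

    A deviation ``dVth`` rescales the current through its device by
    ``exp(-kappa * dVth / UT)`` (a positive deviation of the threshold
    magnitude always weakens conduction, for either polarity).  Amplitude
    devices rescale their branch currents; ramp devices rescale the ramp
    current and hence divide tau and window by the same factor; switch
    devices (M1, M6, M13, M18) are ideal and ignored.
    """
    allowed = set(active_transistors(variant))
    values = effective._asdict()
    for label, dvth in sample.items():
        if label not in allowed:
            raise ValueError(
                f"transistor {label!r} not present in variant {variant!r}"
            )
        f = math.exp(-device.kappa * dvth / device.UT)
        if label in _AMP_MAP:
            for field in _AMP_MAP[label]:
                values[field] *= f
        elif label in _RAMP_MAP:
            tau_field, win_field = _RAMP_MAP[label]
            values[tau_field] /= f
            values[win_field] /= f
        elif label in _SWITCHES:
            continue
        else:  # pragma: no cover - labels are validated against the variant
            raise ValueError(f"unknown transistor label {label!r}")
    return EffectiveParams(**values)


def draw_mismatch(
    rng: np.random.Generator, sigma_vth: float, variant: str = "minimal14"
) -> Dict[str, float]:
    """I.i.d. Normal(0, sigma_vth) threshold deviation per active transistor."""
    if sigma_vth < 0:
        raise ValueError("sigma_vth must be non-negative")
    labels = active_transistors(variant)
    dv = rng.normal(0.0, sigma_vth, size=len(labels)) if sigma_vth > 0 else (
        np.zeros(len(labels))
    )
    return dict(zip(labels, dv.tolist()))


def unbounded_windows(eff: EffectiveParams) -> EffectiveParams:
    """Copy of ``eff`` with all ramp windows set to infinity (ideal,
    unbounded-memory limit in which the circuit realises the triplet rule
    exactly)."""
    return eff._replace(
        window_plus=math.inf, window_minus=math.inf,
        window_x=math.inf, window_y=math.inf,
    )
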