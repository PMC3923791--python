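"""NMSE goodness-of-fit, dataset handling and simplex parameter fitting.

The error measure is the normalized mean square error

    NMSE = (1/N) * sum_i ((dw_exp_i - dw_sim_i) / sem_i)^2

over a dataset of protocol/weight-change points, each residual scaled by
that point's standard error of the mean.  A perfect fit gives 0; a fit
within one SEM per point gives ~1.  Parameters (rule amplitudes/time
constants, or circuit bias voltages plus a global volts-to-fraction scale)
are adjusted by a derivative-free Nelder-Mead simplex search.

The experimental 13-point hippocampal and 10-point visual-cortex tables are
external to this package; :func:`make_synthetic_dataset` generates
datasets of the same composition from known ground-truth parameters, and
:func:`load_dataset_csv` accepts user-transcribed tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from . import circuit as circ
from .protocols import ProtocolSpec
from .rules import TripletParams, check_variant, run_protocol

__all__ = [
    "DataPoint",
    "Dataset",
    "FitResult",
    "nmse",
    "simulate_dataset",
    "make_objective",
    "optimize",
    "fit_rule_params",
    "make_synthetic_dataset",
    "default_hippocampal_grid",
    "default_frequency_pairing_grid",
    "load_dataset_csv",
    "save_dataset_csv",
]

#: Fittable TripletParams fields, in the vector order used by objectives.
RULE_AMPLITUDES = ("A2_plus", "A2_minus", "A3_plus", "A3_minus")


@dataclass(frozen=True)
class DataPoint:
    """One protocol with its measured mean weight change and SEM."""

    spec: ProtocolSpec
    dw_exp: float
    sem: float

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")


@dataclass(frozen=True)
class Dataset:
    name: str
    points: Tuple[DataPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if not self.points:
            raise ValueError("dataset must be nonempty")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dw_exp(self) -> np.ndarray:
        return np.array([p.dw_exp for p in self.points])

    @property
    def sem(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])


def nmse(dw_sim: Sequence[float], dataset: Dataset) -> float:
    """Normalized mean square error of simulated vs measured weight changes."""
    sim = np.asarray(dw_sim, float)
    if sim.shape != (len(dataset),):
        raise ValueError("dw_sim length must match the dataset")
    sems = dataset.sem
    if np.any(sems <= 0):
        raise ValueError("sem values must be positive")
    r = (dataset.dw_exp - sim) / sems
    return float(np.mean(r * r))


def simulate_dataset(
    dataset: Dataset,
    params: Union[TripletParams, circ.CircuitBiases, circ.EffectiveParams],
    engine: str = "rule",
    variant: str = "tstdp_minimal_hippocampal",
    device: Optional[circ.DeviceParams] = None,
    scale: Optional[float] = None,
    w_init: Optional[float] = None,
) -> np.ndarray:
    """Simulate every point's protocol; returns the dw_sim vector.

    The circuit engine converts its weight-voltage change to fractional
    weight change through the mandatory global ``scale`` factor (units:
    fraction per volt).
    """
    out = np.empty(len(dataset))
    if engine == "rule":
        for i, p in enumerate(dataset.points):
            try:
                out[i] = run_protocol(p.spec, params, variant)
            except Exception as e:  # surface the offending point
                raise RuntimeError(f"simulation failed at point {i}: {e}") from e
        return out
    if engine == "circuit":
        if scale is None:
            raise ValueError(
                "circuit engine requires the volts-to-fraction scale factor"
            )
        dev = device or circ.DeviceParams()
        for i, p in enumerate(dataset.points):
            try:
                pre, post = p.spec.build()
                res = circ.simulate_event(
                    pre, post, params, dev, variant, w_init=w_init
                )
                out[i] = res.total_dv * scale
            except Exception as e:
                raise RuntimeError(f"simulation failed at point {i}: {e}") from e
        return out
    raise ValueError("engine must be 'rule' or 'circuit'")


def make_objective(
    dataset: Dataset,
    engine: str = "rule",
    variant: str = "tstdp_minimal_hippocampal",
    template: Optional[TripletParams] = None,
    free_params: Sequence[str] = RULE_AMPLITUDES[:3],
    biases_template: Optional[circ.CircuitBiases] = None,
    free_biases: Sequence[str] = (),
    fit_scale: bool = True,
    device: Optional[circ.DeviceParams] = None,
    scale: Optional[float] = None,
    w_init: Optional[float] = None,
) -> Callable[[np.ndarray], float]:
    """Bind a dataset and a parameterisation into an NMSE objective.

    Rule engine: the vector holds the ``free_params`` fields of a
    :class:`TripletParams` template.  Circuit engine: the vector holds the
    ``free_biases`` fields of a :class:`CircuitBiases` template, followed by
    the global volts-to-fraction scale when ``fit_scale`` is true.
    Deterministic protocols give a deterministic objective; Poisson points
    use their spec's fixed seed.
    """
    if engine == "rule":
        if template is None:
            raise ValueError("rule engine requires a TripletParams template")
        check_variant(template, variant)
        # the trains do not depend on the rule parameters, so the event
        # geometry of every protocol is computed once up front
        from .rules import _triplet_increments, event_table

        tables = [event_table(*p.spec.build()) for p in dataset.points]

        def fun(x: np.ndarray) -> float:
            p = dataclasses.replace(
                template, **dict(zip(free_params, np.asarray(x, float)))
            )
            sim = np.array(
                [
                    pot.sum() + dep.sum()
                    for pot, dep in (
                        _triplet_increments(tab, p, "factored")
                        for tab in tables
                    )
                ]
            )
            return nmse(sim, dataset)

        return fun
    if engine == "circuit":
        if biases_template is None:
            raise ValueError("circuit engine requires a CircuitBiases template")
        if not fit_scale and scale is None:
            raise ValueError(
                "circuit engine requires the volts-to-fraction scale factor"
            )
        dev = device or circ.DeviceParams()
        nb = len(free_biases)

        def fun(x: np.ndarray) -> float:
            x = np.asarray(x, float)
            b = dataclasses.replace(
                biases_template, **dict(zip(free_biases, x[:nb]))
            )
            s = float(x[nb]) if fit_scale else float(scale)
            sim = simulate_dataset(
                dataset, b, "circuit", variant, dev, s, w_init
            )
            return nmse(sim, dataset)

        return fun
    raise ValueError("engine must be 'rule' or 'circuit'")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a simplex fit: best vector (named), NMSE, bookkeeping."""

    x: Dict[str, float]
    nmse: float
    n_evaluations: int
    converged: bool


def optimize(
    objective: Callable[[np.ndarray], float],
    initial: Sequence[float],
    bounds: Sequence[Tuple[float, float]],
    seed: int = 0,
    max_evals: int = 2000,
    n_restarts: int = 0,
    names: Optional[Sequence[str]] = None,
    jitter: float = 0.25,
) -> FitResult:
    """Bounded Nelder-Mead simplex descent with optional seeded multi-start.

    Restart initial points jitter the user's ``initial`` by a seeded
    relative perturbation within bounds.  The returned point is never worse
    than the initial point.
    """
    x0 = np.asarray(initial, float)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial point outside bounds")
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_restarts):
        span = hi - lo
        cand = x0 + jitter * span * rng.standard_normal(x0.size)
        starts.append(np.clip(cand, lo, hi))

    f0 = float(objective(x0))
    best_x, best_f = x0, f0
    total_evals = 1
    converged = False
    for start in starts:
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            bounds=Bounds(lo, hi),
            options={
                "maxfev": max_evals,
                "xatol": 1e-10,
                "fatol": 1e-12,
            },
        )
        total_evals += int(res.nfev)
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
        converged = converged or bool(res.success)
    if names is None:
        names = [f"x{i}" for i in range(x0.size)]
    return FitResult(
        x=dict(zip(names, np.asarray(best_x, float).tolist())),
        nmse=best_f,
        n_evaluations=total_evals,
        converged=converged,
    )


def fit_rule_params(
    dataset: Dataset,
    variant: str = "tstdp_minimal_hippocampal",
    template: Optional[TripletParams] = None,
    free_params: Sequence[str] = ("A2_plus", "A2_minus", "A3_plus"),
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    initial: Optional[Sequence[float]] = None,
    seed: int = 0,
    max_evals: int = 2000,
    n_restarts: int = 0,
) -> FitResult:
    """Convenience wrapper: fit selected rule fields to a dataset.

    Default bounds: amplitudes in [0, 0.1], time constants in [1, 200] ms
    (typical STDP ranges).
    """
    if template is None:
        from .presets import HIPPOCAMPAL_PARAMS

        template = HIPPOCAMPAL_PARAMS
    if bounds is None:
        bounds = [
            (0.0, 0.1) if name.startswith("A") else (1e-3, 0.2)
            for name in free_params
        ]
    if initial is None:
        initial = [
            min(max(getattr(template, n), b[0]), b[1])
            for n, b in zip(free_params, bounds)
        ]
    fun = make_objective(
        dataset, "rule", variant, template=template, free_params=free_params
    )
    return optimize(
        fun, initial, bounds, seed=seed, max_evals=max_evals,
        n_restarts=n_restarts, names=list(free_params),
    )


def default_hippocampal_grid(
    n_reps: int = 60, rho: float = 1.0
) -> List[ProtocolSpec]:
    """The 13-point hippocampal-style composition: 2 pairing points
    (dt = +/-10 ms), 3 quadruplet points and 8 triplet points."""
    specs = [
        ProtocolSpec("pairing", dt=10e-3, n_reps=n_reps, rho=rho),
        ProtocolSpec("pairing", dt=-10e-3, n_reps=n_reps, rho=rho),
        ProtocolSpec("quadruplet", T=-20e-3, n_reps=n_reps, rho=rho),
        ProtocolSpec("quadruplet", T=20e-3, n_reps=n_reps, rho=rho),
        ProtocolSpec("quadruplet", T=100e-3, n_reps=n_reps, rho=rho),
    ]
    for combo in ("pre_post_pre", "post_pre_post"):
        for dt1, dt2 in ((5e-3, 5e-3), (10e-3, 10e-3), (5e-3, 15e-3),
                         (15e-3, 5e-3)):
            specs.append(
                ProtocolSpec(
                    "triplet", dt1=dt1, dt2=dt2, combo=combo,
                    n_reps=n_reps, rho=rho,
                )
            )
    return specs


def default_frequency_pairing_grid(n_reps: int = 60) -> List[ProtocolSpec]:
    """The 10-point visual-cortex-style composition: two pairing offsets
    (dt = +/-10 ms) across five pairing repetition frequencies."""
    specs = []
    for dt in (10e-3, -10e-3):
        for rho in (0.1, 10.0, 20.0, 40.0, 50.0):
            specs.append(ProtocolSpec("pairing", dt=dt, n_reps=n_reps, rho=rho))
    return specs


def make_synthetic_dataset(
    true_params: Union[TripletParams, circ.CircuitBiases],
    variant: str = "tstdp_minimal_hippocampal",
    protocol_grid: Optional[Sequence[ProtocolSpec]] = None,
    noise_scale: float = 1.0,
    seed: int = 0,
    sem_frac: float = 0.1,
    sem_floor: float = 1e-3,
    engine: str = "rule",
    device: Optional[circ.DeviceParams] = None,
    scale: float = 1.0,
    name: str = "synthetic",
) -> Dataset:
    """Generate a dataset from known ground-truth parameters.

    Each grid protocol is simulated with ``true_params``; the SEM is
    ``max(sem_frac * |dw|, sem_floor)`` and the recorded mean is perturbed
    by Gaussian noise of SD ``noise_scale * sem``.  With ``noise_scale = 1``
    the expected NMSE at the true parameters is 1 (a chi-square mean); with
    0 it is exactly 0.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if protocol_grid is None:
        protocol_grid = default_hippocampal_grid()
    base = Dataset(
        name,
        tuple(DataPoint(spec, 0.0, 1.0) for spec in protocol_grid),
    )
    dw = simulate_dataset(base, true_params, engine, variant, device, scale)
    rng = np.random.default_rng(seed)
    sems = np.maximum(sem_frac * np.abs(dw), sem_floor)
    noisy = dw + noise_scale * sems * rng.standard_normal(dw.size)
    points = tuple(
        DataPoint(spec, float(m), float(s))
        for spec, m, s in zip(protocol_grid, noisy, sems)
    )
    return Dataset(name, points)


_CSV_COLUMNS = [
    "protocol_kind", "dt_ms", "dt1_ms", "dt2_ms", "T_ms", "rho_Hz", "combo",
    "dw_exp", "sem",
]


def save_dataset_csv(dataset: Dataset, path) -> None:
    """Write a dataset in the interchange CSV layout (timings in ms)."""
    rows = []
    for p in dataset.points:
        s = p.spec
        rows.append(
            {
                "protocol_kind": s.kind,
                "dt_ms": None if s.dt is None else s.dt * 1e3,
                "dt1_ms": None if s.dt1 is None else s.dt1 * 1e3,
                "dt2_ms": None if s.dt2 is None else s.dt2 * 1e3,
                "T_ms": None if s.T is None else s.T * 1e3,
                "rho_Hz": s.rho,
                "combo": s.combo,
                "dw_exp": p.dw_exp,
                "sem": p.sem,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def load_dataset_csv(path, name: Optional[str] = None, n_reps: int = 60) -> Dataset:
    """Load a dataset from the interchange CSV layout."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing columns: {sorted(missing)}")

    def ms(v):
        return None if pd.isna(v) else float(v) * 1e-3

    points = []
    for _, row in df.iterrows():
        spec = ProtocolSpec(
            kind=str(row["protocol_kind"]),
            dt=ms(row["dt_ms"]),
            dt1=ms(row["dt1_ms"]),
            dt2=ms(row["dt2_ms"]),
            T=ms(row["T_ms"]),
            combo=None if pd.isna(row["combo"]) else str(row["combo"]),
            n_reps=n_reps,
            rho=float(row["rho_Hz"]),
        )
        points.append(
            DataPoint(spec, float(row["dw_exp"]), float(row["sem"]))
        )
    return Dataset(name or str(path), tuple(points))
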