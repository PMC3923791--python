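"""Monte-Carlo transistor-mismatch study.

Fabricated analog circuits deviate from their design: each transistor's
threshold voltage carries an independent random offset, which in the
subthreshold regime rescales its current exponentially.  This module draws
i.i.d. Normal(0, sigma_vth) threshold deviations per active transistor (the
default sigma of 10 mV puts the three-sigma point at 30 mV), perturbs the
circuit's effective parameters, re-evaluates every dataset protocol with
*fixed* bias voltages, and records the resulting NMSE per run.  The spread
of that distribution relative to the unperturbed baseline measures the
design's mismatch tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import circuit as circ
from .fitting import Dataset, nmse

__all__ = ["MCConfig", "MCResult", "run_mc", "summarize_mc"]


@dataclass(frozen=True)
class MCConfig:
    """Configuration of one mismatch Monte-Carlo experiment.

    ``scale`` converts the circuit's weight-voltage change to the dataset's
    fractional weight-change units (fraction per volt); ``w_init`` defaults
    to mid-rail.
    """

    dataset: Dataset
    biases: circ.CircuitBiases
    variant: str = "minimal14"
    n_runs: int = 1000
    sigma_vth: float = 0.010
    seed: int = 0
    device: circ.DeviceParams = field(default_factory=circ.DeviceParams)
    scale: float = 1.0
    w_init: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.sigma_vth < 0:
            raise ValueError("sigma_vth must be non-negative")


@dataclass(frozen=True)
class MCResult:
    nmse_values: np.ndarray
    baseline_nmse: float

    def __post_init__(self) -> None:
        v = np.asarray(self.nmse_values, float)
        object.__setattr__(self, "nmse_values", v)
        if np.any(v < 0) or self.baseline_nmse < 0:
            raise ValueError("NMSE values must be non-negative")


def run_mc(config: MCConfig) -> MCResult:
    """Run the mismatch Monte Carlo; reproducible for a fixed seed.

    The protocol event geometry is computed once (the biases, and hence the
    spike trains, are fixed across runs); each run only redraws the
    threshold deviations and re-evaluates the weight changes.
    """
    cfg = config
    eff0 = circ.biases_to_effective(cfg.biases, cfg.device, cfg.variant)
    tables = []
    for i, point in enumerate(cfg.dataset.points):
        try:
            pre, post = point.spec.build()
            tables.append(circ.prepare_event_tables(pre, post, cfg.device))
        except Exception as e:
            raise RuntimeError(f"protocol build failed at point {i}: {e}") from e

    def dataset_nmse(eff: circ.EffectiveParams) -> float:
        sim = np.array(
            [
                circ.total_dv_from_table(tab, eff, cfg.device, cfg.w_init)
                * cfg.scale
                for tab in tables
            ]
        )
        return nmse(sim, cfg.dataset)

    baseline = dataset_nmse(eff0)
    rng = np.random.default_rng(cfg.seed)
    values = np.empty(cfg.n_runs)
    for r in range(cfg.n_runs):
        sample = circ.draw_mismatch(rng, cfg.sigma_vth, cfg.variant)
        try:
            eff_r = circ.apply_mismatch(eff0, sample, cfg.device, cfg.variant)
            values[r] = dataset_nmse(eff_r)
        except Exception as e:
            raise RuntimeError(f"MC run {r} failed: {e}") from e
    return MCResult(values, baseline)


def summarize_mc(
    result: MCResult,
    closeness_factor: float = 2.0,
    n_bins: int = 30,
) -> Dict:
    """Deterministic summary: quantiles, spread, histogram with fixed edges,
    and the fraction of runs within ``closeness_factor`` of the baseline.

    For a strictly positive baseline "within" means
    ``nmse <= closeness_factor * baseline``; a degenerate (sigma = 0)
    result yields fraction 1.0 and zero spread.
    """
    if closeness_factor < 1:
        raise ValueError("closeness_factor must be >= 1")
    v = result.nmse_values
    if v.size == 0:
        raise ValueError("empty MC result")
    base = result.baseline_nmse
    threshold = closeness_factor * base if base > 0 else closeness_factor * 1e-12
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
    hi = max(float(v.max()), base, 1e-12)
    edges = np.linspace(0.0, hi, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return {
        "n_runs": int(v.size),
        "baseline_nmse": base,
        "mean": float(v.mean()),
        "quantiles": {
            "min": float(q[0]), "q25": float(q[1]), "median": float(q[2]),
            "q75": float(q[3]), "max": float(q[4]),
        },
        "iqr": float(q[3] - q[1]),
        "closeness_factor": float(closeness_factor),
        "fraction_within": float(np.mean(v <= threshold)),
        "histogram": {
            "edges": edges.tolist(),
            "counts": counts.tolist(),
        },
    }
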