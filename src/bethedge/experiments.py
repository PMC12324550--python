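"""Seeded, desk-scale computational experiments.

Four pipelines mirror the package's main analyses:

* a symmetric-model sweep — simulate parameter sets, estimate (Gamma, I)
  and measure their distance to the analytic master curve;
* a purely analytic region sweep tracing (Gamma, I) across the feasible
  joint laws at fixed marginals, with their upper bounds;
* the marginal-information-value profile dGamma/dI;
* a dormant-proliferating sweep over the stress death rate mu1.

Each pipeline returns a tidy pandas DataFrame (one row per grid point) and
is deterministic given its seed: point ``n`` of a sweep uses ``seed + n``.
Default trajectory lengths are desk scale (1e5 environmental transitions);
assertions downstream scale tolerances as 1/sqrt(n_transitions).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import integrate_fractions
from .environment import sample_environment
from .estimator import JointDistribution, estimate_joint_distribution
from .metrics import (
    compute_metrics,
    marginal_information_value,
    max_information,
    max_normalized_fitness,
    mutual_information,
    normalized_fitness,
    joint_from_parameters,
    symmetric_gamma_at_information,
)
from .model import ModelConfig, make_dormancy_model, make_symmetric_model

__all__ = [
    "SweepSpec",
    "CANONICAL_SYMMETRIC_POINTS",
    "simulate_point",
    "run_symmetric_experiment",
    "run_region_sweep",
    "run_marginal_value_profile",
    "run_dormancy_sweep",
]

logger = logging.getLogger("bethedge")

# The four canonical symmetric-model regimes (slow / fast environment,
# responsive at an intermediate timescale, non-responsive), all with the
# same relative growth rate mu - rho = 3.
CANONICAL_SYMMETRIC_POINTS: tuple[dict, ...] = (
    {"label": "slow_env", "mu": 4.0, "rho": 1.0, "ka": 0.1, "kb": 1.2, "lam": 0.1},
    {"label": "fast_env", "mu": 4.0, "rho": 1.0, "ka": 0.1, "kb": 1.2, "lam": 10.0},
    {"label": "responsive", "mu": 4.0, "rho": 1.0, "ka": 0.1, "kb": 1.2, "lam": 1.0},
    {"label": "nonresponsive", "mu": 4.0, "rho": 1.0, "ka": 0.5, "kb": 0.5, "lam": 0.1},
)


@dataclass
class SweepSpec:
    """Configuration of one sweep.

    ``grid`` maps parameter names to lists of values and is expanded as a
    full cross product; ``points`` gives explicit parameter dicts instead
    (exactly one of the two should be nonempty).
    """

    preset: str = "symmetric"
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    points: Sequence[Mapping] = field(default_factory=tuple)
    n_transitions: int = 100_000
    seed: int = 0
    burn_in_fraction: float = 0.01
    f0: float = 0.5
    output_resolution: int = 30
    out: str | None = None

    def __post_init__(self) -> None:
        if self.n_transitions < 100:
            raise ValueError("n_transitions must be >= 100")
        if bool(self.grid) == bool(self.points):
            if not self.grid and not self.points:
                raise ValueError("spec needs a parameter grid or explicit points")
            raise ValueError("give either grid or points, not both")

    def expand(self) -> list[dict]:
        if self.points:
            return [dict(p) for p in self.points]
        names = list(self.grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.grid[n] for n in names))
        ]


def simulate_point(
    config: ModelConfig,
    n_transitions: int,
    seed: int,
    f0: float = 0.5,
    burn_in_fraction: float = 0.01,
    output_resolution: int = 30,
) -> tuple[JointDistribution, "pd.Series"]:
    """Simulate one model: sample environment, integrate fractions,
    estimate the joint law and compute the metrics report (as a Series)."""
    env = sample_environment(config.env_rates, n_transitions, seed=seed)
    frac = integrate_fractions(
        env, config, f0=f0, output_resolution=output_resolution
    )
    joint = estimate_joint_distribution(env, frac, burn_in_fraction)
    report = compute_metrics(joint, config)
    row = pd.Series({**joint.to_json_dict(), **report.to_dict()})
    return joint, row


def run_symmetric_experiment(spec: SweepSpec | None = None) -> pd.DataFrame:
    """Simulate symmetric-model parameter sets and compare against the
    analytic master curve.

    Each record carries the input parameters, the estimated joint law, the
    metrics report, and ``curve_deviation``: the vertical distance from
    the simulated (I, Gamma) point to the analytic curve, Gamma minus
    Gamma_sym evaluated at the simulated information.
    """
    if spec is None:
        spec = SweepSpec(preset="symmetric", points=CANONICAL_SYMMETRIC_POINTS)
    if spec.preset != "symmetric":
        raise ValueError(f"expected the symmetric preset, got {spec.preset!r}")
    rows = []
    for n, params in enumerate(spec.expand()):
        label = params.pop("label", str(n))
        t0 = time.perf_counter()
        config = make_symmetric_model(**params)
        joint, row = simulate_point(
            config,
            spec.n_transitions,
            seed=spec.seed + n,
            f0=spec.f0,
            burn_in_fraction=spec.burn_in_fraction,
            output_resolution=spec.output_resolution,
        )
        info = min(row["I"], 1.0)
        row["curve_deviation"] = row["Gamma"] - symmetric_gamma_at_information(info)
        rows.append({"label": label, **params, "seed": spec.seed + n, **row})
        logger.info(
            "symmetric point %s %s done in %.2fs (Gamma=%.4f, I=%.4f)",
            label, params, time.perf_counter() - t0, row["Gamma"], row["I"],
        )
    table = pd.DataFrame(rows)
    if spec.out:
        table.to_csv(spec.out, index=False)
    return table


def run_region_sweep(
    Px1: float = 0.4,
    Py1_grid: Sequence[float] | None = None,
    Px1y1_resolution: int = 51,
    out: str | None = None,
) -> pd.DataFrame:
    """Trace (Gamma, I) through the feasible region at fixed marginals.

    Purely analytic.  For each phenotype marginal Py1, the corner
    probability runs from the independence point to the upper Frechet
    boundary; the bounds Gamma_max / I_max and the marginal information
    value are reported alongside.
    """
    if Py1_grid is None:
        Py1_grid = np.round(np.arange(0.05, 0.96, 0.05), 10)
    rows = []
    for Py1 in Py1_grid:
        Py1 = float(Py1)
        lo, hi = Px1 * Py1, min(Px1, Py1)
        gmax = max_normalized_fitness(Px1, Py1)
        imax = max_information(Px1, Py1)
        for p in np.linspace(lo, hi, Px1y1_resolution):
            p = float(p)
            try:
                joint = joint_from_parameters(Px1, Py1, p)
            except ValueError as err:  # pragma: no cover - grid is feasible
                logger.warning("skipping infeasible point (%s, %s, %s): %s",
                               Px1, Py1, p, err)
                continue
            rows.append(
                {
                    "Px1": Px1,
                    "Py1": Py1,
                    "Px1y1": p,
                    "Gamma": normalized_fitness(joint),
                    "I": mutual_information(joint),
                    "Gamma_max": gmax,
                    "I_max": imax,
                    "marginal_value": marginal_information_value(Px1, Py1, p),
                }
            )
    table = pd.DataFrame(rows)
    if out:
        table.to_csv(out, index=False)
    return table


def run_marginal_value_profile(
    Px1: float = 0.5,
    resolution: int = 200,
    Py1: float | None = None,
    out: str | None = None,
) -> pd.DataFrame:
    """Profile of the marginal information value dGamma/dI against I.

    Analytic and grid-free: each row evaluates closed forms at one corner
    probability strictly inside the feasibility interval.  The profile is
    strictly positive, strictly decreasing in I, and diverges as I -> 0.
    """
    if Py1 is None:
        Py1 = Px1
    lo, hi = Px1 * Py1, min(Px1, Py1)
    interior = np.linspace(lo, hi, resolution + 2)[1:-1]
    rows = []
    for p in interior:
        p = float(p)
        joint = joint_from_parameters(Px1, Py1, p)
        rows.append(
            {
                "Px1": Px1,
                "Py1": Py1,
                "Px1y1": p,
                "I": mutual_information(joint),
                "Gamma": normalized_fitness(joint),
                "dGamma_dI": marginal_information_value(Px1, Py1, p),
            }
        )
    table = pd.DataFrame(rows)
    if out:
        table.to_csv(out, index=False)
    return table


def default_mu1_grid(mu2: float = 1.0, n: int = 30) -> np.ndarray:
    """Log-spaced death-rate grid: 30 values in [0.01, 100] times the
    proliferation rate mu2, wide enough to bracket the interior Gamma
    maximum for every stress probability down to Px1 = 0.1 (the rarer the
    stress, the larger the death rate at which dormancy starts to pay)."""
    return np.geomspace(0.01 * mu2, 100.0 * mu2, n)


def run_dormancy_sweep(
    mu1_grid: Sequence[float] | None = None,
    Px1_list: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    spec: SweepSpec | None = None,
    mu2: float = 1.0,
    k: float = 0.01,
    lam21: float = 0.5,
    out: str | None = None,
) -> pd.DataFrame:
    """Sweep the dormant-proliferating model over the stress death rate.

    For each (mu1, Px1): build the preset, simulate, and record the
    phenotype marginal, mean and independent fitness, Gamma and I.  The
    sweep exhibits the characteristic contracts: the dormant fraction and
    the information rise monotonically with mu1 while Gamma peaks near
    Py1 = Px1 and then falls.
    """
    if mu1_grid is None:
        mu1_grid = default_mu1_grid(mu2)
    if spec is None:
        spec = SweepSpec(preset="dormancy", points=({},), out=out)
    rows = []
    n = 0
    for Px1 in Px1_list:
        for mu1 in mu1_grid:
            t0 = time.perf_counter()
            config = make_dormancy_model(
                mu1=float(mu1), mu2=mu2, k=k, lam21=lam21, Px1=float(Px1)
            )
            _, row = simulate_point(
                config,
                spec.n_transitions,
                seed=spec.seed + n,
                f0=spec.f0,
                burn_in_fraction=spec.burn_in_fraction,
                output_resolution=spec.output_resolution,
            )
            rows.append(
                {"mu1": float(mu1), "mu2": mu2, "k": k, "lam21": lam21,
                 "Px1_target": float(Px1), "seed": spec.seed + n, **row}
            )
            logger.info(
                "dormancy point mu1=%.4g Px1=%.2f done in %.2fs (Py1=%.3f)",
                mu1, Px1, time.perf_counter() - t0, row["Py1"],
            )
            n += 1
    table = pd.DataFrame(rows)
    dest = out or spec.out
    if dest:
        table.to_csv(dest, index=False)
    return table
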