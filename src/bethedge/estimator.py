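"""Time-average estimators: joint environment-phenotype law and fitness.

Treating the environment as the input of a noisy channel and the phenotype
as its output, the joint probability of observing environment x_i together
with phenotype y_j is defined as a long-run time average,

    P(x_i, y_j) = lim_{T->inf} (1/T) integral_0^T f_{y_j}(t) 1_{x_i}(x(t)) dt,

where f_{y_j}(t) is the phenotype fraction and 1_{x_i} the indicator of
the environment state.  The marginals P(x_i) (telegraph occupancy) and
P(y_j) (mean fraction) are its row and column sums.  Instantaneous
population fitness is the fraction-weighted mean growth rate

    gamma(t) = sum_j g(y_j | x(t)) f_{y_j}(t),

and its time average equals the growth-rate matrix contracted with the
joint law — both are computed and their agreement is asserted in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .model import ModelConfig

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import FractionTrajectory
    from .environment import EnvironmentTrajectory

__all__ = [
    "JointDistribution",
    "FitnessSeries",
    "estimate_joint_distribution",
    "instantaneous_fitness",
    "time_averaged_fitness",
]


@dataclass(frozen=True)
class JointDistribution:
    """2x2 joint law of (environment, phenotype).

    ``P[i, j] = P(x_{i+1}, y_{j+1})``; entries are nonnegative and sum to
    one (tolerance 1e-10).  Marginals are the row/column sums.  Negatively
    associated joints (P(x1,y1) < P(x1)P(y1)) are representable: the
    product lower bound characterizes responsive strategies and is a
    diagnostic property, not a constraint of the type.
    """

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float).reshape(2, 2)
        object.__setattr__(self, "P", P)
        if np.any(P < -1e-12):
            raise ValueError(f"joint probabilities must be nonnegative, got {P}")
        if abs(P.sum() - 1.0) > 1e-10:
            raise ValueError(f"joint probabilities must sum to 1, got {P.sum()!r}")

    @property
    def Px(self) -> np.ndarray:
        """Environment marginal (P_x1, P_x2)."""
        return self.P.sum(axis=1)

    @property
    def Py(self) -> np.ndarray:
        """Phenotype marginal (P_y1, P_y2)."""
        return self.P.sum(axis=0)

    @property
    def Px1(self) -> float:
        return float(self.P[0].sum())

    @property
    def Py1(self) -> float:
        return float(self.P[:, 0].sum())

    def to_json_dict(self) -> dict[str, float]:
        return {
            "Px1y1": float(self.P[0, 0]),
            "Px1y2": float(self.P[0, 1]),
            "Px2y1": float(self.P[1, 0]),
            "Px2y2": float(self.P[1, 1]),
            "Px1": self.Px1,
            "Py1": self.Py1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.P, index=["x1", "x2"], columns=["y1", "y2"]).to_csv(path)


@dataclass(frozen=True)
class FitnessSeries:
    """Instantaneous population fitness gamma(t) on the trajectory grid."""

    times: np.ndarray
    gamma: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "gamma": self.gamma})


def _check_alignment(env_traj: "EnvironmentTrajectory", frac_traj: "FractionTrajectory"):
    if frac_traj.epoch_f.shape[0] != env_traj.n_epochs:
        raise ValueError(
            "fraction trajectory is not aligned with the environment "
            f"trajectory ({frac_traj.epoch_f.shape[0]} vs {env_traj.n_epochs} epochs)"
        )
    if not np.array_equal(frac_traj.epoch_states, env_traj.states):
        raise ValueError("epoch states of the two trajectories disagree")


def estimate_joint_distribution(
    env_traj: "EnvironmentTrajectory",
    frac_traj: "FractionTrajectory",
    burn_in_fraction: float = 0.01,
) -> JointDistribution:
    """Estimate P(x_i, y_j) by time-averaging a simulated trajectory.

    The integral of f_{y1}(t) 1_{x_i}(x(t)) is evaluated epoch by epoch —
    epoch boundaries are integration breakpoints, so the indicator is
    never interpolated across a switch — and normalized by the window
    length.  Trajectories from the analytic integrator carry exact
    closed-form epoch means of f; otherwise the trapezoid rule on the
    per-epoch uniform sample grid is used.  Epochs starting within the
    first ``burn_in_fraction`` of total time are discarded to remove the
    transient from the arbitrary initial fraction.
    """
    _check_alignment(env_traj, frac_traj)
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    t_burn = burn_in_fraction * env_traj.total_time
    keep = env_traj.start_times >= t_burn
    if not np.any(keep):
        raise ValueError("burn-in discards the whole trajectory")
    durs = env_traj.durations[keep]
    states = env_traj.states[keep]
    if frac_traj.epoch_mean_f is not None:
        mean_f = frac_traj.epoch_mean_f[keep]
    else:
        F = frac_traj.epoch_f[keep]
        n_pts = F.shape[1]
        weights = np.full(n_pts, 1.0)
        weights[0] = weights[-1] = 0.5
        mean_f = F @ weights / (n_pts - 1)  # per-epoch time-mean of f_y1
    T = durs.sum()
    P = np.zeros((2, 2))
    for s in (1, 2):
        mask = states == s
        w = durs[mask]
        P[s - 1, 0] = (w * mean_f[mask]).sum() / T
        P[s - 1, 1] = (w * (1.0 - mean_f[mask])).sum() / T
    return JointDistribution(P=P)


def instantaneous_fitness(
    env_traj: "EnvironmentTrajectory",
    frac_traj: "FractionTrajectory",
    config: ModelConfig,
) -> FitnessSeries:
    """gamma(t) = g(y1|x(t)) f_y1(t) + g(y2|x(t)) (1 - f_y1(t)).

    Dips right after each environment switch (the population is still
    dominated by the previously fit phenotype) and recovers as the
    fraction relaxes toward the new fixed point.
    """
    _check_alignment(env_traj, frac_traj)
    g = config.growth
    idx = frac_traj.env_state_at_time - 1
    f = frac_traj.f_y1
    gamma = g[idx, 0] * f + g[idx, 1] * (1.0 - f)
    return FitnessSeries(times=frac_traj.times, gamma=gamma)


def time_averaged_fitness(joint: JointDistribution, config: ModelConfig) -> float:
    """Mean growth rate: the growth matrix contracted with the joint law."""
    return float(np.sum(config.growth * joint.P))
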