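"""Two-state telegraph environment: trajectory sampling and stationary laws.

The environment x(t) alternates between states 1 and 2 with constant
switching rates lambda12 (1 -> 2) and lambda21 (2 -> 1), so dwell times in
state i are Exponential with mean 1/lambda_ij and the stationary occupancy
is P(x_i) = lambda_ji / (lambda_ij + lambda_ji).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentTrajectory",
    "sample_environment",
    "stationary_environment_probability",
    "environment_entropy",
]


@dataclass(frozen=True)
class EnvironmentTrajectory:
    """An ordered sequence of environment epochs tiling [0, total_time].

    ``states[n]`` is the environment label (1 or 2) during epoch ``n``,
    which starts at ``start_times[n]`` and lasts ``durations[n]``.  States
    strictly alternate; epochs tile [0, total_time] with no gaps.  ``seed``
    records the RNG seed used to draw the dwell times (provenance).
    """

    states: np.ndarray
    start_times: np.ndarray
    durations: np.ndarray
    total_time: float
    seed: int | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if not (len(states) == len(starts) == len(durs)):
            raise ValueError("states, start_times, durations must have equal length")
        if np.any(durs <= 0):
            raise ValueError("epoch durations must be positive")
        if np.any(states[1:] == states[:-1]):
            raise ValueError("consecutive epochs must alternate states")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], rtol=0, atol=1e-9):
            raise ValueError("epochs must tile time with no gaps or overlaps")

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    def time_fraction(self, state: int) -> float:
        """Fraction of total time spent in ``state``."""
        return float(self.durations[self.states == state].sum() / self.total_time)

    def dwell_times(self, state: int) -> np.ndarray:
        """Complete dwell times observed in ``state`` (last epoch excluded,
        as its exponential draw is still representative but conventionally
        the trajectory is truncated there)."""
        return self.durations[self.states == state]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states.astype(int),
                "start_time": self.start_times,
                "duration": self.durations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_environment(
    env_rates: tuple[float, float],
    n_transitions: int,
    initial_state: int = 1,
    seed: int | None = None,
) -> EnvironmentTrajectory:
    """Sample a telegraph trajectory with ``n_transitions`` switches.

    The trajectory has ``n_transitions + 1`` epochs; the dwell time of an
    epoch in state i is Exponential with mean ``1/lambda_ij``.  Length is
    specified in transitions (not model time); ``total_time`` is derived.
    """
    lam12, lam21 = float(env_rates[0]), float(env_rates[1])
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    if initial_state not in (1, 2):
        raise ValueError("initial_state must be 1 or 2")
    n_epochs = n_transitions + 1
    states = np.empty(n_epochs, dtype=np.int8)
    states[0::2] = initial_state
    states[1::2] = 3 - initial_state
    rate_of = {1: lam12, 2: lam21}  # exit rate of each state
    for s in (1, 2):
        if np.any(states == s) and rate_of[s] <= 0:
            raise ValueError(
                f"exit rate of visited state {s} is zero (infinite dwell time)"
            )
    rng = np.random.default_rng(seed)
    rates = np.where(states == 1, lam12, lam21)
    durations = rng.exponential(1.0 / rates)
    start_times = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    total_time = float(start_times[-1] + durations[-1])
    return EnvironmentTrajectory(
        states=states,
        start_times=start_times,
        durations=durations,
        total_time=total_time,
        seed=seed,
    )


def stationary_environment_probability(
    env_rates: tuple[float, float]
) -> tuple[float, float]:
    """Stationary occupancy (P_x1, P_x2) = (l21, l12) / (l12 + l21)."""
    lam12, lam21 = float(env_rates[0]), float(env_rates[1])
    if lam12 < 0 or lam21 < 0:
        raise ValueError("environment rates must be nonnegative")
    if lam12 + lam21 <= 0:
        raise ValueError("at least one environment rate must be positive")
    px1 = lam21 / (lam12 + lam21)
    return px1, 1.0 - px1


def environment_entropy(Px1: float) -> float:
    """Shannon entropy of the two-state environment, in bits.

    H(x) = -Px1 log2 Px1 - (1-Px1) log2 (1-Px1), with 0 log 0 = 0.
    This is the ceiling for the environment-phenotype mutual information.
    """
    if not 0.0 <= Px1 <= 1.0:
        raise ValueError(f"Px1 must lie in [0, 1], got {Px1}")
    h = 0.0
    for p in (Px1, 1.0 - Px1):
        if p > 0.0:
            h -= p * np.log2(p)
    return float(h)
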