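"""Model configurations for two-state bet-hedging populations.

A model couples three rate structures:

* a growth-rate matrix ``g[i, j]`` giving the proliferation rate of
  phenotype ``y_{j+1}`` in environment ``x_{i+1}`` (rows are environments,
  columns are phenotypes),
* a phenotype-switching matrix ``k[i, 0] = k(y1 -> y2 | x_{i+1})`` and
  ``k[i, 1] = k(y2 -> y1 | x_{i+1})``,
* the environment switching rates ``lambda12`` (x1 -> x2) and ``lambda21``
  (x2 -> x1) of the two-state telegraph process.

Environments and phenotypes are labeled 1 and 2 throughout the package;
internal array index 0 corresponds to label 1.  All rates are in arbitrary
inverse-time units; no unit conversion is performed.

By the fittest-labeling convention, phenotype ``y_i`` is the fastest grower
in environment ``x_i`` (``g[i, i] >= g[i, j]``).  The convention fixes the
sign of the normalized-fitness measure downstream; violating it is legal
(a relabeling restores it) and only triggers a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "ModelConfig",
    "RelativeGrowthRates",
    "FittestLabelingWarning",
    "make_symmetric_model",
    "make_dormancy_model",
    "relative_growth_rates",
]


class FittestLabelingWarning(UserWarning):
    """The growth matrix violates g(y_i|x_i) >= g(y_j|x_i)."""


class RelativeGrowthRates(NamedTuple):
    """Fitness advantage of the fittest phenotype in each environment.

    ``gx1 = g(y1|x1) - g(y2|x1)`` and ``gx2 = g(y2|x2) - g(y1|x2)``; both
    are nonnegative under the fittest-labeling convention.
    """

    gx1: float
    gx2: float


# Flat serialization keys: gij = growth of phenotype yj in environment xi,
# kjk_xi = switching rate yj -> yk in environment xi.
_CONFIG_KEYS = (
    "g11", "g12", "g21", "g22",
    "k12_x1", "k21_x1", "k12_x2", "k21_x2",
    "lambda12", "lambda21",
)


@dataclass(frozen=True)
class ModelConfig:
    """Complete rate specification of the two-state model.

    Parameters
    ----------
    growth
        2x2 array, ``growth[i, j] = g(y_{j+1} | x_{i+1})`` (1/time).  Growth
        rates may be negative (death, as in the dormancy model).
    switching
        2x2 array, ``switching[i, 0] = k(y1 -> y2 | x_{i+1})`` and
        ``switching[i, 1] = k(y2 -> y1 | x_{i+1})`` (1/time, nonnegative).
    env_rates
        ``(lambda12, lambda21)`` environment switching rates (1/time,
        nonnegative, not both zero).
    """

    growth: np.ndarray
    switching: np.ndarray
    env_rates: tuple[float, float]

    def __post_init__(self) -> None:
        g = np.asarray(self.growth, dtype=float).reshape(2, 2)
        k = np.asarray(self.switching, dtype=float).reshape(2, 2)
        lam = (float(self.env_rates[0]), float(self.env_rates[1]))
        object.__setattr__(self, "growth", g)
        object.__setattr__(self, "switching", k)
        object.__setattr__(self, "env_rates", lam)
        if np.any(k < 0):
            raise ValueError("switching rates must be nonnegative")
        if lam[0] < 0 or lam[1] < 0:
            raise ValueError("environment rates must be nonnegative")
        if lam[0] == 0 and lam[1] == 0:
            raise ValueError("at least one environment rate must be positive")
        if g[0, 0] < g[0, 1] or g[1, 1] < g[1, 0]:
            warnings.warn(
                "growth matrix violates the fittest-labeling convention "
                "g(y_i|x_i) >= g(y_j|x_i); relabel states 1<->2 to restore it "
                "(the sign convention of normalized fitness assumes it)",
                FittestLabelingWarning,
                stacklevel=3,
            )

    # -- rate accessors (labels, not indices) --------------------------------

    def growth_rate(self, phenotype: int, env_state: int) -> float:
        """g(y_phenotype | x_env_state) with labels in {1, 2}."""
        return float(self.growth[env_state - 1, phenotype - 1])

    def switch_rate(self, from_phenotype: int, to_phenotype: int, env_state: int) -> float:
        """k(y_from -> y_to | x_env_state) with labels in {1, 2}."""
        if {from_phenotype, to_phenotype} != {1, 2}:
            raise ValueError("switch_rate requires the two distinct phenotype labels")
        return float(self.switching[env_state - 1, 0 if from_phenotype == 1 else 1])

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        g, k, (l12, l21) = self.growth, self.switching, self.env_rates
        return {
            "g11": g[0, 0], "g12": g[0, 1], "g21": g[1, 0], "g22": g[1, 1],
            "k12_x1": k[0, 0], "k21_x1": k[0, 1],
            "k12_x2": k[1, 0], "k21_x2": k[1, 1],
            "lambda12": l12, "lambda21": l21,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelConfig":
        missing = [key for key in _CONFIG_KEYS if key not in d]
        if missing:
            raise KeyError(f"config is missing keys: {missing}")
        return cls(
            growth=np.array([[d["g11"], d["g12"]], [d["g21"], d["g22"]]], dtype=float),
            switching=np.array(
                [[d["k12_x1"], d["k21_x1"]], [d["k12_x2"], d["k21_x2"]]], dtype=float
            ),
            env_rates=(float(d["lambda12"]), float(d["lambda21"])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({key: float(v) for key, v in self.to_dict().items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_symmetric_model(
    mu: float, rho: float, ka: float, kb: float, lam: float
) -> ModelConfig:
    """Symmetric bet-hedging preset.

    Growth and switching are invariant under the simultaneous relabeling
    1 <-> 2 of environments and phenotypes: the fittest phenotype grows at
    ``mu``, the unfit one at ``rho`` (``mu > rho``); switching toward the
    fittest phenotype runs at ``kb`` and away from it at ``ka``
    (``kb >= ka``, responsive when ``kb > ka``).  The environment is
    symmetric, ``lambda12 = lambda21 = lam``.
    """
    if not mu > rho:
        raise ValueError(f"symmetric model requires mu > rho, got mu={mu}, rho={rho}")
    if ka < 0 or kb < ka:
        raise ValueError(f"symmetric model requires kb >= ka >= 0, got ka={ka}, kb={kb}")
    if not lam > 0:
        raise ValueError(f"symmetric model requires lam > 0, got lam={lam}")
    return ModelConfig(
        growth=np.array([[mu, rho], [rho, mu]], dtype=float),
        # k(y1->y2|x1)=ka, k(y2->y1|x1)=kb; mirrored in x2
        switching=np.array([[ka, kb], [kb, ka]], dtype=float),
        env_rates=(lam, lam),
    )


def make_dormancy_model(
    mu1: float, mu2: float, k: float, lam21: float, Px1: float
) -> ModelConfig:
    """Dormant-proliferating preset.

    Environment ``x1`` is the stressful state (e.g. antibiotic), ``x2`` the
    growth state.  Phenotype ``y1`` is dormant with zero growth everywhere;
    phenotype ``y2`` proliferates at ``mu2`` under ``x2`` but dies at rate
    ``mu1`` under ``x1`` (growth ``-mu1``).  All four switching rates equal
    ``k``.  ``lambda12`` is set to ``lam21 * (1 - Px1) / Px1`` so the
    stationary probability of the stress environment equals ``Px1``.
    """
    if mu1 < 0:
        raise ValueError(f"mu1 must be >= 0, got {mu1}")
    if not mu2 > 0:
        raise ValueError(f"mu2 must be > 0, got {mu2}")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    if not lam21 > 0:
        raise ValueError(f"lam21 must be > 0, got {lam21}")
    if not 0 < Px1 < 1:
        raise ValueError(f"Px1 must lie strictly in (0, 1), got {Px1}")
    lam12 = lam21 * (1.0 - Px1) / Px1
    return ModelConfig(
        growth=np.array([[0.0, -mu1], [0.0, mu2]], dtype=float),
        switching=np.full((2, 2), float(k)),
        env_rates=(lam12, lam21),
    )


def relative_growth_rates(config: ModelConfig) -> RelativeGrowthRates:
    """Growth advantage of the fittest phenotype in each environment."""
    g = config.growth
    return RelativeGrowthRates(
        gx1=float(g[0, 0] - g[0, 1]), gx2=float(g[1, 1] - g[1, 0])
    )
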