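"""Information-fitness analytics for the two-state channel.

The environment-phenotype association is quantified two ways and the two
turn out to be monotonically linked at fixed marginals:

* mutual information  I = sum_ij P_ij log2[ P_ij / (P_i. P_.j) ]  in bits;
* normalized fitness  Gamma = (<gamma> - <gamma>_ind) / (<gamma>_max -
  <gamma>_ind),  the mean growth rate measured relative to a population
  whose phenotype is independent of the environment and scaled by the best
  achievable excess (all individuals in the locally fit phenotype).

Gamma admits a growth-rate-free form,

    Gamma = (P(x1,y1) - P(x1) P(y1)) / (P(x1) (1 - P(x1))),

so it depends on the joint law alone; both routes are computed and
cross-checked.  With marginals held fixed, the joint law is a one-parameter
family in p = P(x1,y1) on [P(x1)P(y1), min(P(x1), P(y1))]; Gamma and I both
increase with p, giving the bounds Gamma_max and I_max at the upper
endpoint and the marginal information value dGamma/dI in the interior.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .environment import environment_entropy
from .estimator import JointDistribution, time_averaged_fitness
from .model import ModelConfig, relative_growth_rates

__all__ = [
    "MetricsReport",
    "mutual_information",
    "mutual_information_matrix",
    "independent_fitness",
    "normalized_fitness",
    "symmetric_curve",
    "symmetric_gamma_at_information",
    "joint_from_parameters",
    "max_normalized_fitness",
    "max_information",
    "marginal_information_value",
    "compute_metrics",
]

_ZERO = 1e-15  # probabilities below this are treated as exact zeros in logs


def mutual_information_matrix(P: np.ndarray) -> float:
    """Mutual information (bits) of an arbitrary joint probability matrix.

    Terms with P_ij = 0 contribute zero (0 log 0 = 0 convention); a
    positive entry whose marginal product vanishes is inconsistent and
    raises.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < -1e-12) or abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("P must be a probability matrix (nonnegative, sum 1)")
    Px = P.sum(axis=1)
    Py = P.sum(axis=0)
    info = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            p = P[i, j]
            if p <= _ZERO:
                continue
            denom = Px[i] * Py[j]
            if denom <= _ZERO:
                raise ValueError(
                    f"entry ({i},{j}) is positive but its marginal product is zero"
                )
            info += p * math.log2(p / denom)
    return max(info, 0.0)


def mutual_information(joint: JointDistribution) -> float:
    """Mutual information between environment and phenotype, in bits."""
    return mutual_information_matrix(joint.P)


def independent_fitness(joint: JointDistribution, config: ModelConfig) -> float:
    """Mean growth rate of the decorrelated reference population.

    The fitness a population would have if its phenotype distribution kept
    the same marginal but were statistically independent of the
    environment: the growth matrix contracted with the product of the
    joint law's marginals.
    """
    product = np.outer(joint.Px, joint.Py)
    return time_averaged_fitness(JointDistribution(P=product), config)


def _gamma_joint_only(P11: float, Px1: float, Py1: float) -> float:
    return (P11 - Px1 * Py1) / (Px1 * (1.0 - Px1))


def normalized_fitness(joint: JointDistribution, config: ModelConfig | None = None) -> float:
    """Normalized fitness Gamma of a joint law.

    Computed from the growth-rate-free form; when a model config is given
    the growth-rate route (<gamma> - <gamma>_ind over the maximal excess)
    is evaluated too and the two must agree to 1e-10 — they are
    algebraically identical, so a discrepancy flags a broken joint.
    Undefined for a deterministic environment or when both relative growth
    rates vanish.
    """
    Px1, Py1 = joint.Px1, joint.Py1
    if not 0.0 < Px1 < 1.0:
        raise ValueError(
            f"normalized fitness is undefined for a deterministic environment (Px1={Px1})"
        )
    gamma_free = _gamma_joint_only(float(joint.P[0, 0]), Px1, Py1)
    if config is not None:
        gx1, gx2 = relative_growth_rates(config)
        if gx1 + gx2 <= 0.0:
            raise ValueError(
                "normalized fitness is undefined when both relative growth rates vanish"
            )
        excess = gx1 * (joint.P[0, 0] - Px1 * Py1) + gx2 * (
            joint.P[1, 1] - (1.0 - Px1) * (1.0 - Py1)
        )
        gamma_rates = excess / ((gx1 + gx2) * Px1 * (1.0 - Px1))
        if abs(gamma_rates - gamma_free) > 1e-10:
            raise AssertionError(
                f"growth-rate and joint-only forms of Gamma disagree: "
                f"{gamma_rates!r} vs {gamma_free!r}"
            )
    return gamma_free


def symmetric_curve(Px1y1: float) -> tuple[float, float]:
    """The (Gamma, I) master curve of the symmetric model.

    With symmetric environment and switching, P(x1) = P(y1) = 1/2 and the
    joint law is parameterized by p = P(x1,y1) in [1/4, 1/2]:

        Gamma_sym(p) = 4 p - 1,
        I_sym(p)     = 1 + (1 - 2p) log2(1 - 2p) + 2p log2(2p).

    Monotone in p, hence Gamma_sym is a monotonically increasing function
    of I_sym: more information means more fitness.
    """
    p = float(Px1y1)
    if not 0.25 <= p <= 0.5:
        raise ValueError(f"Px1y1 must lie in [0.25, 0.5], got {p}")
    gamma = 4.0 * p - 1.0
    info = 1.0
    for q in (1.0 - 2.0 * p, 2.0 * p):
        if q > _ZERO:
            info += q * math.log2(q)
    return gamma, max(info, 0.0)


def symmetric_gamma_at_information(info: float) -> float:
    """Invert the symmetric master curve: Gamma_sym at a given I (bits)."""
    if not 0.0 <= info <= 1.0 + 1e-12:
        raise ValueError(f"information must lie in [0, 1] bits, got {info}")
    info = min(info, 1.0)
    from scipy.optimize import brentq

    def residual(p: float) -> float:
        return symmetric_curve(p)[1] - info

    if info <= 0.0:
        return 0.0
    if info >= 1.0:
        return 1.0
    p = brentq(residual, 0.25, 0.5, xtol=1e-14)
    return symmetric_curve(p)[0]


def joint_from_parameters(Px1: float, Py1: float, Px1y1: float) -> JointDistribution:
    """Build the 2x2 joint law with given marginals and corner probability.

    The remaining entries follow from the marginal constraints:
    P(x2,y1) = Py1 - p, P(x1,y2) = Px1 - p, P(x2,y2) = 1 - Px1 - Py1 + p.
    Feasibility requires max(0, Px1+Py1-1) <= p <= min(Px1, Py1) (Frechet
    bounds).  Joints below the independence point p = Px1*Py1 describe
    anti-correlated (maladaptive) strategies; they are representable and
    only trigger a warning.
    """
    if not (0.0 < Px1 < 1.0 and 0.0 < Py1 < 1.0):
        raise ValueError("marginals must lie strictly in (0, 1)")
    lo = max(0.0, Px1 + Py1 - 1.0)
    hi = min(Px1, Py1)
    if not lo - 1e-12 <= Px1y1 <= hi + 1e-12:
        raise ValueError(
            f"Px1y1={Px1y1} infeasible for marginals ({Px1}, {Py1}): "
            f"must lie in [{lo}, {hi}]"
        )
    p = min(max(Px1y1, lo), hi)
    if p < Px1 * Py1 - 1e-12:
        warnings.warn(
            "Px1y1 below the independence point Px1*Py1: anti-correlated "
            "joint (negative normalized fitness)",
            stacklevel=2,
        )
    P = np.array(
        [[p, Px1 - p], [Py1 - p, 1.0 - Px1 - Py1 + p]], dtype=float
    )
    return JointDistribution(P=np.clip(P, 0.0, None))


def max_normalized_fitness(Px1: float, Py1: float) -> float:
    """Largest Gamma achievable at fixed marginals.

    Attained at P(x1,y1) = min(Px1, Py1):
    (1-Py1)/(1-Px1) for Px1 <= Py1, and Py1/Px1 otherwise.  Equals 1 (the
    global maximum) exactly when the phenotype marginal matches the
    environment marginal.
    """
    if not (0.0 < Px1 < 1.0 and 0.0 < Py1 < 1.0):
        raise ValueError("marginals must lie strictly in (0, 1)")
    if Px1 <= Py1:
        return (1.0 - Py1) / (1.0 - Px1)
    return Py1 / Px1


def max_information(Px1: float, Py1: float) -> float:
    """Largest mutual information (bits) achievable at fixed marginals.

    Evaluated as the mutual information of the joint law at the upper
    Frechet boundary P(x1,y1) = min(Px1, Py1).  When the marginals match,
    this equals the environment entropy — the channel ceiling.
    """
    joint = joint_from_parameters(Px1, Py1, min(Px1, Py1))
    return mutual_information(joint)


def marginal_information_value(Px1: float, Py1: float, Px1y1: float) -> float:
    """dGamma/dI at fixed marginals — the fitness gain per extra bit.

    Along the one-parameter family in p = P(x1,y1),

        dGamma/dp = 1 / (Px1 (1 - Px1)),
        dI/dp     = log2[ (P11 P22) / (P12 P21) ],

    so the value is their ratio.  At the independence point dI/dp = 0 and
    the value is +inf (the first bit is infinitely valuable); it decays
    monotonically with I but never reaches zero in the interior.
    """
    joint = joint_from_parameters(Px1, Py1, Px1y1)
    P = joint.P
    dgamma = 1.0 / (Px1 * (1.0 - Px1))
    if P[0, 1] <= _ZERO or P[1, 0] <= _ZERO:
        return 0.0  # upper Frechet boundary: dI/dp diverges
    if P[0, 0] <= _ZERO or P[1, 1] <= _ZERO:
        return math.inf  # lower Frechet corner
    ratio = (P[0, 0] * P[1, 1]) / (P[0, 1] * P[1, 0])
    if ratio <= 1.0:
        # at (or below) the independence point the information slope
        # vanishes (or turns negative): the first bit is infinitely valuable
        return math.inf
    return dgamma / math.log2(ratio)


@dataclass(frozen=True)
class MetricsReport:
    """All information-fitness summaries of one (joint law, model) pair."""

    gamma_mean: float
    gamma_ind: float
    gamma_max: float
    Gamma: float
    I: float
    H_env: float
    Gamma_max_bound: float
    I_max_bound: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def compute_metrics(joint: JointDistribution, config: ModelConfig) -> MetricsReport:
    """Assemble the full metrics report for an estimated joint law."""
    gx1, gx2 = relative_growth_rates(config)
    gamma_mean = time_averaged_fitness(joint, config)
    gamma_ind = independent_fitness(joint, config)
    Px1 = joint.Px1
    gamma_max = gamma_ind + (gx1 + gx2) * Px1 * (1.0 - Px1)
    return MetricsReport(
        gamma_mean=gamma_mean,
        gamma_ind=gamma_ind,
        gamma_max=gamma_max,
        Gamma=normalized_fitness(joint, config),
        I=mutual_information(joint),
        H_env=environment_entropy(Px1),
        Gamma_max_bound=max_normalized_fitness(Px1, joint.Py1),
        I_max_bound=max_information(Px1, joint.Py1),
    )
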