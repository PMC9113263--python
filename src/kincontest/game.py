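"""Inclusive-fitness contest game between two cannibalistic larvae.

Two tadpoles of relative sizes ``s1, s2`` choose aggressiveness levels
``a1, a2``.  Competitive strength is multiplicative, ``theta_i = s_i * a_i``,
and contestant 1 wins with probability ``omega_1 = theta_1 / (theta_1 +
theta_2)``.  Only the winner reproduces; its direct fitness ``upsilon``
depends on its own aggressiveness through one of three cost structures
(size-independent, size-proportional, or size-scaled cost).  Because the
loser is a relative with relatedness ``r``, the winner's inclusive payoff is
``upsilon_1 - r * upsilon_2``, and the expected inclusive fitness of
contestant 1 is ``F1 = omega_1 * (upsilon_1 - r * upsilon_2)``.

Everything here is a pure function of floats or numpy arrays; the
equilibrium solver and the synthetic-trial machinery build on top.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitnessFormulation",
    "ContestantState",
    "DyadGame",
    "competitive_strength",
    "win_probability",
    "direct_fitness",
    "max_aggressiveness",
    "expected_inclusive_fitness",
]


class FitnessFormulation(enum.Enum):
    """Cost structure of aggressiveness in the winner's direct fitness.

    SIZE_INDEPENDENT:  upsilon = 1 - a**2
    SIZE_PROPORTIONAL: upsilon = s - a**2
    SIZE_SCALED_COST:  upsilon = 1 - (a / s)**2
    """

    SIZE_INDEPENDENT = "size_independent"
    SIZE_PROPORTIONAL = "size_proportional"
    SIZE_SCALED_COST = "size_scaled_cost"


def _check_size(s: float) -> None:
    if not (s > 0) or not math.isfinite(s):
        raise ValueError(f"relative size must be positive and finite, got {s!r}")


@dataclass(frozen=True)
class ContestantState:
    """One contestant's relative size and its aggressiveness decision."""

    size: float
    aggressiveness: float

    def __post_init__(self) -> None:
        _check_size(self.size)
        if self.aggressiveness < 0:
            raise ValueError(
                f"aggressiveness must be non-negative, got {self.aggressiveness!r}"
            )


@dataclass(frozen=True)
class DyadGame:
    """A pairwise contest: two sizes, a relatedness coefficient, a formulation.

    ``relatedness`` is the coefficient of relatedness between the pair
    (0.5 full siblings, 0.25 paternal half siblings, 0 unrelated).
    """

    s1: float
    s2: float
    relatedness: float
    formulation: FitnessFormulation

    def __post_init__(self) -> None:
        _check_size(self.s1)
        _check_size(self.s2)
        if not 0.0 <= self.relatedness <= 1.0:
            raise ValueError(f"relatedness must be in [0, 1], got {self.relatedness!r}")

    def size(self, player: int) -> float:
        if player == 1:
            return self.s1
        if player == 2:
            return self.s2
        raise ValueError(f"player must be 1 or 2, got {player!r}")


def competitive_strength(s: float, a):
    """Competitive strength theta = s * a.

    ``a`` may be a scalar or numpy array; size must be a positive scalar.
    """
    _check_size(s)
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("aggressiveness must be non-negative")
    out = s * a
    return float(out) if out.ndim == 0 else out


def win_probability(theta1, theta2, s1: float = 1.0, s2: float = 1.0):
    """Probability that contestant 1 wins, theta1 / (theta1 + theta2).

    When both strengths are zero the ratio is undefined; we adopt the
    continuity convention s1 / (s1 + s2), the limit along a1 = a2 -> 0+.
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if np.any(theta1 < 0) or np.any(theta2 < 0):
        raise ValueError("competitive strengths must be non-negative")
    _check_size(s1)
    _check_size(s2)
    total = theta1 + theta2
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(total > 0, theta1 / np.where(total > 0, total, 1.0),
                         s1 / (s1 + s2))
    return float(omega) if omega.ndim == 0 else omega


def max_aggressiveness(s: float, formulation: FitnessFormulation) -> float:
    """Upper bound of the admissible aggressiveness range.

    Defined as the level at which the winner's direct fitness hits zero:
    1 for the size-independent cost, sqrt(s) for the size-proportional
    fitness, and s for the size-scaled cost.
    """
    _check_size(s)
    if formulation is FitnessFormulation.SIZE_INDEPENDENT:
        return 1.0
    if formulation is FitnessFormulation.SIZE_PROPORTIONAL:
        return math.sqrt(s)
    if formulation is FitnessFormulation.SIZE_SCALED_COST:
        return s
    raise TypeError(f"unknown formulation {formulation!r}")


def direct_fitness(s: float, a, formulation: FitnessFormulation):
    """Winner's direct fitness upsilon under the given cost structure.

    Raises ValueError outside the admissible range [0, max_aggressiveness],
    where the expression would turn negative: a negative reproductive
    success for a winner is meaningless and would distort optimisation.
    """
    _check_size(s)
    a = np.asarray(a, dtype=float)
    bound = max_aggressiveness(s, formulation)
    if np.any(a < 0) or np.any(a > bound * (1 + 1e-12)):
        raise ValueError(
            f"aggressiveness must lie in [0, {bound}] for {formulation.name} "
            f"at size {s}"
        )
    if formulation is FitnessFormulation.SIZE_INDEPENDENT:
        out = 1.0 - a**2
    elif formulation is FitnessFormulation.SIZE_PROPORTIONAL:
        out = s - a**2
    else:
        out = 1.0 - (a / s) ** 2
    out = np.maximum(out, 0.0)  # clip the 1e-12 tolerance sliver, never sign flips
    return float(out) if out.ndim == 0 else out


def expected_inclusive_fitness(game: DyadGame, a1, a2, focal: int = 1):
    """Expected inclusive fitness of the focal contestant.

    F_focal = omega_focal * (upsilon_focal - r * upsilon_other), the
    win-probability-weighted inclusive payoff of surviving a contest in
    which the loser (a relative with relatedness r) dies.  Either
    aggressiveness argument may be a numpy array (broadcast).
    """
    if focal == 1:
        s_f, s_o, a_f, a_o = game.s1, game.s2, a1, a2
    elif focal == 2:
        s_f, s_o, a_f, a_o = game.s2, game.s1, a2, a1
    else:
        raise ValueError(f"focal must be 1 or 2, got {focal!r}")
    theta_f = competitive_strength(s_f, a_f)
    theta_o = competitive_strength(s_o, a_o)
    omega = win_probability(theta_f, theta_o, s_f, s_o)
    ups_f = direct_fitness(s_f, a_f, game.formulation)
    ups_o = direct_fitness(s_o, a_o, game.formulation)
    out = omega * (ups_f - game.relatedness * ups_o)
    return float(out) if np.ndim(out) == 0 else out
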