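"""Best responses and mutual-best-response (Nash) aggressiveness pairs.

The contest game has a one-dimensional strategy space per player (its
aggressiveness on ``[0, max_aggressiveness]``), so best responses are
computed by a coarse grid scan followed by bounded Brent refinement, and
equilibria by iterated (Gauss-Seidel) best response from several restarts.
Closed-form symmetric equilibria, derived from the first-order condition
``dF1/da1 = 0`` at ``a1 = a2``, serve as analytic oracles:

    size-independent cost:   a* = sqrt((1-r)/(5-r))
    size-proportional:       a* = sqrt(s (1-r)/(5-r))
    size-scaled cost:        a* = s sqrt((1-r)/(5-r))

A subtlety of the payoff structure: against a non-aggressive opponent
(``a2 = 0``), any positive ``a1`` wins outright, so ``F1`` is maximised in
the limit ``a1 -> 0+`` and the supremum is not attained.  Best responses in
that situation are reported as the limit point 0.0 together with a
``sup_not_attained`` flag rather than as a grid-resolution-dependent
epsilon, which keeps fixed points and their independent verification
consistent across grid resolutions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .game import (
    DyadGame,
    FitnessFormulation,
    direct_fitness,
    expected_inclusive_fitness,
    max_aggressiveness,
)

__all__ = [
    "SolverOptions",
    "BestResponse",
    "EquilibriumResult",
    "best_response",
    "nash_equilibrium",
    "symmetric_equilibrium_analytic",
    "verify_mutual_best_response",
    "sweep",
]

# internal stand-in for a supremum-type best response during iteration;
# small enough to be within any verification tolerance of the limit point 0
_SUP_PROBE = 1e-7


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for best-response and equilibrium computation."""

    grid_points: int = 1001
    refine_tol: float = 1e-9
    br_tol: float = 1e-8
    max_iterations: int = 500
    restarts: int = 8
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_points < 3:
            raise ValueError("grid_points must be >= 3")
        if self.refine_tol <= 0 or self.br_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iterations < 1 or self.restarts < 1:
            raise ValueError("max_iterations and restarts must be >= 1")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")


@dataclass(frozen=True)
class BestResponse:
    """A single-agent best response with attainability diagnostics."""

    value: float
    fitness: float
    sup_not_attained: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass
class EquilibriumResult:
    """A mutual-best-response pair with convergence diagnostics."""

    a1_star: float
    a2_star: float
    converged: bool
    iterations: int
    is_corner: bool
    sup_not_attained: bool = False
    oscillation_detected: bool = False
    multiplicity_note: list = field(default_factory=list)


def _payoff_grid(game: DyadGame, grid: np.ndarray, opponent_a: float, focal: int):
    if focal == 1:
        return expected_inclusive_fitness(game, grid, opponent_a, focal=1)
    return expected_inclusive_fitness(game, opponent_a, grid, focal=2)


def best_response(
    game: DyadGame,
    opponent_a: float,
    focal: int = 1,
    opts: SolverOptions | None = None,
) -> BestResponse:
    """Aggressiveness maximising the focal contestant's expected inclusive fitness.

    Coarse grid over the admissible range, bounded Brent refinement around
    the best grid point; both boundaries are always evaluated and ties break
    toward the smallest aggressiveness.  See the module docstring for the
    ``opponent_a = 0`` supremum case.
    """
    opts = opts or SolverOptions()
    s_f = game.size(focal)
    s_o = game.size(3 - focal)
    a_max = max_aggressiveness(s_f, game.formulation)

    if opponent_a == 0.0:
        # F is upsilon_f(a) - r*upsilon_o(0) for any a > 0 (focal wins
        # outright), strictly decreasing, so the supremum sits at a -> 0+.
        limit_val = float(
            direct_fitness(s_f, 0.0, game.formulation)
            - game.relatedness * direct_fitness(s_o, 0.0, game.formulation)
        )
        at_zero = (s_f / (s_f + s_o)) * limit_val
        if limit_val > at_zero + 1e-15:
            return BestResponse(0.0, limit_val, sup_not_attained=True)
        return BestResponse(0.0, at_zero, sup_not_attained=False)

    grid = np.linspace(0.0, a_max, opts.grid_points)
    fvals = np.asarray(_payoff_grid(game, grid, opponent_a, focal))
    if not np.all(np.isfinite(fvals)):
        raise FloatingPointError(
            f"non-finite fitness in best response: game={game}, "
            f"opponent_a={opponent_a}, focal={focal}"
        )
    i = int(np.argmax(fvals))  # first max -> smallest a on exact ties

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, opts.grid_points - 1)]
    candidates = [(grid[i], fvals[i]), (0.0, fvals[0]), (a_max, fvals[-1])]
    if hi > lo:
        res = minimize_scalar(
            lambda a: -_payoff_grid(game, np.asarray(a), opponent_a, focal),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": opts.refine_tol},
        )
        candidates.append((float(res.x), float(-res.fun)))
    # max fitness; ties (within a numerical sliver) toward smallest a
    best_f = max(f for _, f in candidates)
    tol = 1e-13 * max(1.0, abs(best_f))
    a_star = min(a for a, f in candidates if f >= best_f - tol)
    return BestResponse(float(a_star), float(best_f))


def symmetric_equilibrium_analytic(
    s: float, r: float, formulation: FitnessFormulation
) -> float:
    """Closed-form symmetric equilibrium aggressiveness (equal sizes).

    Root of the symmetric first-order condition (1-r) * upsilon(a) scaled
    by the cost curvature, giving (1-r)/(5-r) inside the square root for
    every formulation; degenerate at r = 1 where the numerator vanishes.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("relatedness must be in [0, 1]")
    core = math.sqrt((1.0 - r) / (5.0 - r))
    if formulation is FitnessFormulation.SIZE_INDEPENDENT:
        return core
    if formulation is FitnessFormulation.SIZE_PROPORTIONAL:
        return math.sqrt(s) * core
    if formulation is FitnessFormulation.SIZE_SCALED_COST:
        return s * core
    raise TypeError(f"unknown formulation {formulation!r}")


def _initial_pairs(game: DyadGame, opts: SolverOptions):
    """Two corner starts plus quasi-random interior starts (golden-ratio lattice)."""
    m1 = max_aggressiveness(game.s1, game.formulation)
    m2 = max_aggressiveness(game.s2, game.formulation)
    pairs = [(0.0, 0.0), (m1, m2)]
    g1, g2 = 0.6180339887498949, 0.7548776662466927
    for k in range(1, opts.restarts + 1):
        pairs.append((m1 * ((k * g1) % 1.0), m2 * ((k * g2) % 1.0)))
    return pairs


def _iterate_br(game, a1, a2, opts, damping):
    """Gauss-Seidel iterated best response; returns (a1, a2, it, converged, flags)."""
    sup1 = sup2 = False
    for it in range(1, opts.max_iterations + 1):
        br1 = best_response(game, a2, focal=1, opts=opts)
        new1 = _SUP_PROBE if br1.sup_not_attained else br1.value
        new1 = a1 + damping * (new1 - a1)
        br2 = best_response(game, new1, focal=2, opts=opts)
        new2 = _SUP_PROBE if br2.sup_not_attained else br2.value
        new2 = a2 + damping * (new2 - a2)
        delta = max(abs(new1 - a1), abs(new2 - a2))
        a1, a2, sup1, sup2 = new1, new2, br1.sup_not_attained, br2.sup_not_attained
        if delta < opts.br_tol:
            return a1, a2, it, True, sup1, sup2
    return a1, a2, opts.max_iterations, False, sup1, sup2


def nash_equilibrium(game: DyadGame, opts: SolverOptions | None = None) -> EquilibriumResult:
    """Mutual-best-response aggressiveness pair by iterated best response.

    Runs from two corner starts and ``opts.restarts`` quasi-random interior
    starts; distinct fixed points found across restarts are recorded in
    ``multiplicity_note``.  A restart that fails to settle is retried once
    with damping 0.5 (flagged as oscillation).  Never raises on
    non-convergence: the result carries ``converged=False``.
    """
    opts = opts or SolverOptions()
    sep = 10.0 * opts.refine_tol
    found: list[tuple] = []  # (a1, a2, iterations, sup1, sup2, oscillated)
    any_converged = False
    for a1_0, a2_0 in _initial_pairs(game, opts):
        a1, a2, it, ok, s1f, s2f = _iterate_br(game, a1_0, a2_0, opts, opts.damping)
        osc = False
        if not ok and opts.damping == 1.0:
            a1, a2, it2, ok, s1f, s2f = _iterate_br(game, a1, a2, opts, 0.5)
            it += it2
            osc = True
        if ok:
            any_converged = True
            r1 = 0.0 if s1f else a1
            r2 = 0.0 if s2f else a2
            if not any(
                abs(r1 - f[0]) <= sep and abs(r2 - f[1]) <= sep for f in found
            ):
                found.append((r1, r2, it, s1f, s2f, osc))
    if not any_converged:
        a1, a2, it, _, s1f, s2f = _iterate_br(
            game, *_initial_pairs(game, opts)[0], opts, opts.damping
        )
        return EquilibriumResult(a1, a2, False, it, False,
                                 sup_not_attained=s1f or s2f,
                                 oscillation_detected=True)

    # deterministic representative: smallest (a1, a2) lexicographically
    found.sort(key=lambda f: (f[0], f[1]))
    a1_star, a2_star, it, s1f, s2f, osc = found[0]
    m1 = max_aggressiveness(game.s1, game.formulation)
    m2 = max_aggressiveness(game.s2, game.formulation)
    edge = 10.0 * opts.refine_tol
    corner = (
        min(a1_star, a2_star) <= edge
        or a1_star >= m1 - edge
        or a2_star >= m2 - edge
    )
    return EquilibriumResult(
        a1_star,
        a2_star,
        True,
        it,
        corner,
        sup_not_attained=s1f or s2f,
        oscillation_detected=osc,
        multiplicity_note=[(f[0], f[1]) for f in found[1:]],
    )


def verify_mutual_best_response(
    game: DyadGame,
    a1: float,
    a2: float,
    tol: float = 1e-5,
    grid_points: int = 200_001,
) -> bool:
    """Independent fine-grid check that (a1, a2) are best responses to each other.

    Uses a dense grid (default 2e5 points, independent of the solver's
    coarse grid + refinement path).  A supremum-type best response matches
    any candidate within ``tol`` of the limit point 0.
    """
    fine = SolverOptions(
        grid_points=grid_points,
        refine_tol=min(1e-10, tol / 10),
        br_tol=tol,
    )
    for focal, mine, theirs in ((1, a1, a2), (2, a2, a1)):
        br = best_response(game, theirs, focal=focal, opts=fine)
        if abs(br.value - mine) > tol:
            return False
    return True


def sweep(
    s_small: float = 0.1,
    s_large_grid=None,
    r_values=(0.0, 0.25, 0.5),
    formulations=tuple(FitnessFormulation),
    opts: SolverOptions | None = None,
) -> pd.DataFrame:
    """Equilibrium table over size difference x relatedness x formulation.

    Defaults regenerate the structure of the model-prediction figure: the
    smaller contestant's size held at 0.1, the larger contestant's size on a
    grid from 0.1 to 1.0 in steps of 0.01, relatedness 0 / 0.25 / 0.5, and
    all three fitness formulations.  Contestant 1 is the smaller tadpole.
    Rows that fail convergence are emitted with converged=False, never
    dropped.
    """
    if s_large_grid is None:
        s_large_grid = np.round(np.arange(0.1, 1.0 + 1e-9, 0.01), 10)
    s_large_grid = np.asarray(s_large_grid, dtype=float)
    if s_large_grid.size and s_large_grid[0] < s_small:
        raise ValueError("s_large grid must start at or above s_small")
    opts = opts or SolverOptions()
    rows = []
    for formulation, r, s_large in itertools.product(
        formulations, r_values, s_large_grid
    ):
        game = DyadGame(float(s_small), float(s_large), float(r), formulation)
        res = nash_equilibrium(game, opts)
        rows.append(
            {
                "formulation": formulation.value,
                "r": float(r),
                "s_small": float(s_small),
                "s_large": float(s_large),
                "a_small": res.a1_star,
                "a_large": res.a2_star,
                "converged": res.converged,
                "is_corner": res.is_corner,
                "iterations": res.iterations,
            }
        )
    return pd.DataFrame(rows)
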