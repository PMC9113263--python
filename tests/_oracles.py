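"""Independent straight-line reimplementations used as test oracles.

Deliberately kept free of any import from the package's game/equilibrium
modules: the payoff equations are re-typed from scratch so that agreement
with the package is a genuine cross-check, not a tautology.
"""

import math

import numpy as np

SIZE_INDEPENDENT = "size_independent"
SIZE_PROPORTIONAL = "size_proportional"
SIZE_SCALED_COST = "size_scaled_cost"


def oracle_amax(s, form):
    return {SIZE_INDEPENDENT: 1.0, SIZE_PROPORTIONAL: math.sqrt(s),
            SIZE_SCALED_COST: s}[form]


def oracle_upsilon(s, a, form):
    if form == SIZE_INDEPENDENT:
        return 1.0 - a**2
    if form == SIZE_PROPORTIONAL:
        return s - a**2
    return 1.0 - (a / s) ** 2


def oracle_payoff(s1, s2, r, form, a1, a2):
    """Expected inclusive fitness of player 1; a1 may be an array."""
    a1 = np.asarray(a1, dtype=float)
    th1, th2 = s1 * a1, s2 * a2
    tot = th1 + th2
    w = np.where(tot > 0, th1 / np.where(tot > 0, tot, 1.0), s1 / (s1 + s2))
    return w * (oracle_upsilon(s1, a1, form) - r * oracle_upsilon(s2, a2, form))


def brute_force_best_response(s1, s2, r, form, a2, n=1_000_000):
    """Argmax of player 1's payoff on a dense grid (first index on ties)."""
    grid = np.linspace(0.0, oracle_amax(s1, form), n)
    return float(grid[np.argmax(oracle_payoff(s1, s2, r, form, grid, a2))])
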