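"""Exhaustive-enumeration oracle for the bone-localization dynamic program.

Evaluates every possible path (one row per column) with exactly the same
floating-point expression and accumulation order as the DP, so optimal
costs can be compared for exact float equality.
"""

from __future__ import annotations

import itertools

import numpy as np

from kneeus.localization import BONE, JUMP, LocalizationParams


def path_costs(eint_cost: np.ndarray, labels: np.ndarray, params: LocalizationParams,
               paths: np.ndarray) -> np.ndarray:
    """Accumulated cost of each path in ``paths`` (n_paths, n_cols)."""
    n_cols = eint_cost.shape[1]
    cost = eint_cost[paths[:, 0], 0].astype(float).copy()
    for j in range(1, n_cols):
        d = (paths[:, j] - paths[:, j - 1]).astype(float)
        if j >= 2:
            curv = d - (paths[:, j - 1] - paths[:, j - 2]).astype(float)
        else:
            curv = np.zeros_like(d)
        lbl = labels[paths[:, j], j]
        bone_cost = (params.nu * (d * d) + params.xi * (curv * curv)) - params.sigma_c
        boneless_cost = params.nu * (params.d1 * params.d1) + params.xi * (
            params.d2 * params.d2
        )
        trans = np.where(lbl == BONE, bone_cost,
                         np.where(lbl == JUMP, params.jump_cost, boneless_cost))
        cost = (cost + trans) + eint_cost[paths[:, j], j]
    return cost


def brute_force(eint_cost: np.ndarray, labels: np.ndarray, params: LocalizationParams):
    """(min cost, all optimal paths) by full enumeration."""
    n_rows, n_cols = eint_cost.shape
    paths = np.array(
        list(itertools.product(range(n_rows), repeat=n_cols)), dtype=int
    )
    costs = path_costs(eint_cost, labels, params, paths)
    best = costs.min()
    return best, paths[costs == best]
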