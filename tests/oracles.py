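"""Independent oracles used by the test suite.

These deliberately avoid the package's own LP path: vertex enumeration
works directly on (S, lb, ub) with numpy, and the FVA oracle goes through
scipy.optimize.linprog.  Both are only practical at toy scale, which is
the point.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog


def vertex_enumerate_max(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray
) -> float:
    """Maximum of c·v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex of the (bounded) polytope has at least n - rank(S)
    variables at a bound; enumerate those active sets, solve the remaining
    square-ish system, keep consistent in-bounds solutions.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    n_fixed = n - r
    best = -np.inf
    idx = np.arange(n)
    for fixed in combinations(idx, n_fixed):
        free = np.array([j for j in idx if j not in fixed], dtype=int)
        Sf = S[:, free]
        if free.size and np.linalg.matrix_rank(Sf) < free.size:
            continue  # non-unique; vertex reachable from another active set
        for bounds_choice in product((0, 1), repeat=n_fixed):
            v = np.empty(n)
            for j, pick in zip(fixed, bounds_choice):
                v[j] = lb[j] if pick == 0 else ub[j]
            rhs = -S[:, list(fixed)] @ v[list(fixed)] if n_fixed else np.zeros(m)
            if free.size:
                sol, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                if np.linalg.norm(Sf @ sol - rhs) > 1e-9:
                    continue
                v[free] = sol
            elif np.linalg.norm(rhs) > 1e-9:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            best = max(best, float(c @ v))
    return best


def linprog_optimum(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray,
    extra_A_ub: np.ndarray | None = None, extra_b_ub: np.ndarray | None = None,
    maximize: bool = True,
):
    """LP optimum via scipy HiGHS; returns (value, x) or (None, None)."""
    res = linprog(
        -c if maximize else c,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        A_ub=extra_A_ub, b_ub=extra_b_ub,
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        return None, None
    return (-res.fun if maximize else res.fun), res.x


def fva_oracle(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c_obj: np.ndarray,
    fraction: float,
) -> np.ndarray:
    """Brute-force FVA: per-reaction min/max with objective >= fraction*opt."""
    opt, _ = linprog_optimum(S, lb, ub, c_obj)
    assert opt is not None
    A_ub = -c_obj.reshape(1, -1)
    b_ub = np.array([-fraction * opt])
    n = S.shape[1]
    out = np.empty((n, 2))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        lo, _ = linprog_optimum(S, lb, ub, e, A_ub, b_ub, maximize=False)
        hi, _ = linprog_optimum(S, lb, ub, e, A_ub, b_ub, maximize=True)
        out[j] = (lo, hi)
    return out


def random_instance(rng: np.random.Generator):
    """Small random bounded network: (S, lb, ub, objective index).

    v = 0 is always feasible (0 in every bound interval) and the box keeps
    the polytope bounded; every reaction touches at least one metabolite.
    """
    m = int(rng.integers(2, 4))
    n = int(rng.integers(5, 9))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        mask = rng.random((m, n)) < 0.4
        S[mask] = 0.0
        if np.all(np.any(S != 0, axis=0)) and np.linalg.matrix_rank(S) >= 1:
            break
    lb = np.where(rng.random(n) < 0.5, -rng.integers(1, 11, n).astype(float), 0.0)
    ub = rng.integers(1, 11, n).astype(float)
    obj = int(rng.integers(0, n))
    return S, lb, ub, obj
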