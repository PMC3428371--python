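"""Comparison solvers: tableau simplex and primal affine-scaling.

These are the reference methods the conic-sampling solver is benchmarked
against, implemented in the same plain, didactic style:

* :func:`simplex_solve` — primal simplex on the slack-form tableau of
  ``min c @ x, A x <= b, x >= 0`` with the slack variables as the starting
  basis (valid because the benchmark polytopes contain the origin).  Two
  pivot rules are offered, steepest edge and random edge, with Bland's rule
  engaged after a stall to guarantee termination on degenerate problems.
  Explicit ``-x_j <= 0`` rows are redundant in slack form and are skipped.

* :func:`affine_scaling_solve` — primal affine scaling from a strictly
  interior point.  Each iterate rescales space by the constraint slacks so
  that no single nearby constraint dominates, moves along the steepest
  feasible descent direction in that metric, and steps a fraction ``beta``
  of the distance to the nearest constraint.  The result is approximate to
  tolerance ``tau``, not a vertex.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .config import EPS
from .problems import (
    LinearProgram,
    SolveResult,
    STATUS_INFEASIBLE_START,
    STATUS_MAX_ITER,
    STATUS_OPTIMAL,
    STATUS_UNBOUNDED,
)

RULE_STEEPEST = "steepest_edge"
RULE_RANDOM = "random_edge"

#: pivots without objective improvement before switching to Bland's rule
STALL_LIMIT = 30


def _nonnegativity_rows(P: LinearProgram) -> tuple[set[int], set[int]]:
    """Rows of the form ``alpha * (-x_j) <= 0``; returns (row set, var set)."""
    rows: set[int] = set()
    covered: set[int] = set()
    A = P.A.tocsr()
    for i in range(P.k):
        start, end = A.indptr[i], A.indptr[i + 1]
        if end - start == 1 and A.data[start] < 0 and abs(P.b[i]) <= EPS:
            rows.add(i)
            covered.add(int(A.indices[start]))
    rows.update(P.nonneg_rows)
    return rows, covered


def simplex_solve(P: LinearProgram, rule: str = RULE_STEEPEST,
                  seed: int | np.random.Generator = 0,
                  max_pivots: int = 100_000) -> SolveResult:
    """Primal simplex from the all-slack basis; requires ``0`` feasible.

    The LP must imply ``x >= 0`` through explicit ``-x_j <= 0`` rows for
    every variable (as the benchmark generator produces); those rows are
    dropped from the tableau since slack form builds them in.
    """
    if rule not in (RULE_STEEPEST, RULE_RANDOM):
        raise ValueError(f"unknown pivot rule {rule!r}")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)

    nn_rows, covered = _nonnegativity_rows(P)
    if covered != set(range(P.n)):
        missing = sorted(set(range(P.n)) - covered)
        raise ValueError(
            f"simplex baseline needs -x_j <= 0 rows for all variables; "
            f"missing for {missing}")
    keep = [i for i in range(P.k) if i not in nn_rows]
    A = P.A[keep].toarray() if keep else np.zeros((0, P.n))
    b = P.b[list(keep)] if keep else np.zeros(0)
    if np.any(b < -EPS * (1.0 + np.abs(b))):
        return SolveResult(np.zeros(P.n), np.nan, STATUS_INFEASIBLE_START)
    b = np.maximum(b, 0.0)

    m, n = A.shape
    # tableau: [A I b] over structural + slack columns; last row = reduced costs
    T = np.zeros((m + 1, n + m + 1))
    T[:m, :n] = A
    T[:m, n:n + m] = np.eye(m)
    T[:m, -1] = b
    T[-1, :n] = P.c
    basis = list(range(n, n + m))  # slack variables

    pivots = 0
    stall = 0
    best_obj = 0.0
    while pivots < max_pivots:
        red = T[-1, :n + m]
        candidates = np.nonzero(red < -EPS * (1.0 + np.abs(T[-1, -1])))[0]
        if candidates.size == 0:
            break  # optimal
        if stall >= STALL_LIMIT:
            enter = int(candidates[0])  # Bland: smallest variable index
        elif rule == RULE_RANDOM:
            enter = int(rng.choice(candidates))
        else:
            cols = T[:m, candidates]
            gamma = np.sqrt(1.0 + np.sum(cols * cols, axis=0))
            enter = int(candidates[np.argmin(red[candidates] / gamma)])

        col = T[:m, enter]
        pos = np.nonzero(col > EPS)[0]
        if pos.size == 0:
            return SolveResult(np.zeros(P.n), -np.inf, STATUS_UNBOUNDED,
                               iterations=pivots)
        ratios = T[pos, -1] / col[pos]
        t_min = float(np.min(ratios))
        tied = pos[ratios <= t_min + 1e-12 * (1.0 + t_min)]
        # leaving tie-break: smallest basis-variable index (Bland-compatible)
        leave = int(tied[np.argmin([basis[i] for i in tied])])

        piv = T[leave, enter]
        T[leave] /= piv
        rows = np.arange(m + 1) != leave
        T[rows] -= np.outer(T[rows, enter], T[leave])
        basis[leave] = enter
        pivots += 1

        obj = -float(T[-1, -1])
        if obj < best_obj - EPS * (1.0 + abs(best_obj)):
            best_obj = obj
            stall = 0
        else:
            stall += 1

    x = np.zeros(n + m)
    for i, var in enumerate(basis):
        x[var] = T[i, -1]
    result_x = x[:P.n]
    status = STATUS_OPTIMAL if pivots < max_pivots else STATUS_MAX_ITER
    return SolveResult(result_x, P.objective(result_x), status,
                       iterations=pivots)


def interior_start(P: LinearProgram, x0: np.ndarray | None = None,
                   ) -> np.ndarray:
    """Nudge a feasible start off any tight constraints into the interior.

    The benchmark polytopes contain the origin, but their nonnegativity rows
    are tight there; stepping halfway to the nearest constraint along the
    averaged inward normal of the tight rows yields a strictly interior
    point whenever one exists in that direction.
    """
    x = np.zeros(P.n) if x0 is None else np.asarray(x0, dtype=float).copy()
    slack = P.b - P.A @ x
    tol = EPS * (1.0 + np.abs(P.b))
    tight = np.nonzero(slack <= tol)[0]
    if tight.size == 0:
        return x
    rows = P.A[tight].toarray()
    rows /= np.linalg.norm(rows, axis=1)[:, None]
    d = -rows.sum(axis=0)
    Ad_tight = rows @ d
    if np.any(Ad_tight >= -EPS):
        raise ValueError("could not find a strictly interior start from x0")
    Ad = P.A @ d
    blocking = Ad > EPS
    t = 1.0 if not np.any(blocking) else \
        0.5 * float(np.min(slack[blocking] / Ad[blocking]))
    x = x + t * d
    if np.any(P.b - P.A @ x <= tol):
        raise ValueError("could not find a strictly interior start from x0")
    return x


def affine_scaling_solve(P: LinearProgram, x0: np.ndarray | None = None,
                         beta: float = 0.9, tau: float = 1e-9,
                         max_iter: int = 10_000) -> SolveResult:
    """Primal affine scaling from a strictly interior start.

    At each iterate with slacks ``v = b - A x > 0``, the step direction
    solves the slack-weighted normal equations
    ``(A.T diag(v)^-2 A) d = -c`` — the steepest descent direction of the
    objective inside the ellipsoid that gives every nearby constraint equal
    slack.  The step length is ``beta`` times the distance to the nearest
    constraint along ``d``.  Iteration stops when the relative objective
    improvement falls below ``tau``; the returned point is an approximate
    interior optimum (no crossover to a vertex is performed).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    x = interior_start(P) if x0 is None else np.asarray(x0, dtype=float).copy()
    v = P.b - P.A @ x
    if np.any(v <= EPS * (1.0 + np.abs(P.b))):
        raise ValueError("affine scaling requires a strictly interior start")

    if not np.any(P.c):
        return SolveResult(x, 0.0, STATUS_OPTIMAL, iterations=0)

    obj = P.objective(x)
    for it in range(max_iter):
        A_w = sp.csr_matrix(P.A).multiply(1.0 / v[:, None]).tocsr()
        M = np.asarray((A_w.T @ A_w).todense())
        try:
            d = np.linalg.solve(M, -P.c)
        except np.linalg.LinAlgError:
            d, *_ = np.linalg.lstsq(M, -P.c, rcond=None)
        dnorm = float(np.linalg.norm(d))
        # the raw direction shrinks quadratically with the boundary distance,
        # so compare against a near-machine threshold and renormalize
        if dnorm <= 1e-15 * (1.0 + float(np.linalg.norm(x))):
            return SolveResult(x, obj, STATUS_OPTIMAL, iterations=it)
        d /= dnorm
        dnorm = 1.0
        Ad = P.A @ d
        pos = Ad > EPS * dnorm
        if not np.any(pos):
            if P.c @ d < -EPS * (1.0 + float(np.linalg.norm(P.c))):
                return SolveResult(x, -np.inf, STATUS_UNBOUNDED, iterations=it)
            return SolveResult(x, obj, STATUS_OPTIMAL, iterations=it)
        t = beta * float(np.min(v[pos] / Ad[pos]))
        x = x + t * d
        v = P.b - P.A @ x
        new_obj = P.objective(x)
        if obj - new_obj <= tau * (1.0 + abs(obj)):
            return SolveResult(x, new_obj, STATUS_OPTIMAL, iterations=it + 1)
        obj = new_obj

    return SolveResult(x, obj, STATUS_MAX_ITER, iterations=max_iter)
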