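"""Euclidean projection onto a polytope by modified conic sampling.

The quadratic program ``min ||x - z||^2  s.t.  A x <= b`` is solved with the
same descend-then-sample scheme as the LP solver, with two changes:

* the descent direction uses the *local gradient* ``g = x - z`` in place of
  the fixed objective vector, re-evaluated after every move;
* a move along a direction ``d`` stops early at the one-dimensional
  minimizer ``t_q = ((z - x) @ d) / (d @ d)`` whenever that point lies
  inside the polytope (no constraint is added in that case).

Because the objective is an exact quadratic with identity Hessian, an
interior stop makes the projected gradient vanish immediately, so each
descent phase performs at most ``n`` constraint insertions plus one interior
step before reaching fixation.  Unboundedness cannot occur: ``t_q`` is
always finite and the distance to ``z`` never increases.

At fixation, stationarity demands ``z - x`` be a nonnegative combination of
the tight rows' normals (the KKT condition for the nearest point of a convex
set).  The same NNLS Farkas alternative used by the LP solver either
certifies this or returns a strictly descending feasible direction, which
also serves as the anticycling fallback on degenerate polytopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EPS
from .conic import (
    MAX_RESAMPLES,
    ActiveBasis,
    ContractViolation,
    UNBOUNDED,
    advance,
    certify_or_direction,
    random_forward_direction,
)
from .problems import (
    ProjectionProblem,
    SolveResult,
    STATUS_INFEASIBLE_START,
    STATUS_MAX_ITER,
    STATUS_OPTIMAL,
    is_feasible,
)


@dataclass
class ProjectionState:
    """Current point, its local gradient ``g = x - z``, and the active basis."""

    x: np.ndarray
    P: ProjectionProblem
    basis: ActiveBasis

    @property
    def gradient(self) -> np.ndarray:
        return self.x - self.P.z


INTERIOR_MINIMUM = "INTERIOR_MINIMUM"


def advance_projection(state: ProjectionState, d: np.ndarray,
                       ) -> "int | str":
    """Move along ``d`` to ``min(t_q, t_c)``; return what stopped the move.

    ``t_q`` is the unconstrained 1-D minimizer of the squared distance along
    the ray, ``t_c`` the step to the nearest blocking constraint.  Returns
    the limiting row index, or :data:`INTERIOR_MINIMUM` when the quadratic
    minimizer is reached first (the caller adds no constraint then).
    Requires ``d`` to be a strict descent direction for ``||x - z||^2``.
    """
    P = state.P
    g = state.gradient
    d = np.asarray(d, dtype=float)
    dd = float(d @ d)
    if dd <= EPS * EPS:
        raise ContractViolation("direction has (near-)zero norm")
    gd = float(g @ d)
    if gd >= -EPS * max(float(np.linalg.norm(g)), 1.0) * np.sqrt(dd):
        raise ContractViolation("not a descent direction for the distance")
    t_q = -gd / dd
    x_c, j, t_c = advance(state.x, d, P)
    if t_q <= t_c:
        state.x = state.x + t_q * d
        return INTERIOR_MINIMUM
    state.x = x_c
    assert j != UNBOUNDED  # t_q finite ensures a bounded move
    return int(j)


def _descend_to_fixation(state: ProjectionState) -> int:
    """Projected-gradient descent until the projected gradient vanishes.

    Returns the number of advances made.  Each step either inserts an
    independent row (at most ``n`` times) or stops at an interior minimum,
    which zeroes the projected gradient exactly.
    """
    advances = 0
    inserted = 0
    while True:
        g = state.gradient
        gnorm = float(np.linalg.norm(g))
        if gnorm <= EPS:
            return advances  # already at the target
        d = -state.basis.project_orthogonal(g)
        if float(np.linalg.norm(d)) <= EPS * max(gnorm, 1.0):
            return advances
        stopped = advance_projection(state, d)
        advances += 1
        if stopped == INTERIOR_MINIMUM:
            continue
        if state.basis.insert_row(state.P, stopped):
            inserted += 1
            if inserted > state.P.n:
                raise AssertionError(
                    "descent inserted more rows than the dimension")
        elif not state.basis.constraint_ids or \
                state.basis.constraint_ids[-1] != stopped:
            # dependent blocking row at a degenerate touch: hand over to the
            # caller's certificate/fallback logic
            return advances


def project_onto_polytope(P: ProjectionProblem,
                          x0: np.ndarray | None = None,
                          seed: int | np.random.Generator = 0,
                          max_fixations: int | None = None) -> SolveResult:
    """Project ``P.z`` onto the polytope starting from feasible ``x0``.

    Returns the unique nearest point with a KKT certificate; ``objective``
    is the squared distance ``||x* - z||^2``.  The optimum is independent of
    the seed (projections onto convex sets are unique); only the trajectory
    and counters vary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    x = np.zeros(P.n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if max_fixations is None:
        max_fixations = 10 * (P.n + P.k)
    if not is_feasible(x, P):
        return SolveResult(x, np.nan, STATUS_INFEASIBLE_START)

    state = ProjectionState(x, P, ActiveBasis(P.n))
    fixations = advances = 0
    max_ins = 0

    for _ in range(max_fixations):
        advances += _descend_to_fixation(state)
        max_ins = max(max_ins, state.basis.rank)
        fixations += 1

        g = state.gradient
        gnorm = float(np.linalg.norm(g))
        if gnorm <= EPS:  # the target itself is feasible
            cert, _ = certify_or_direction(state.x, P, P.z - state.x)
            return SolveResult(state.x, P.objective(state.x), STATUS_OPTIMAL,
                               fixations, advances, certificate=cert,
                               max_descent_insertions=max_ins)

        moved = False
        for _ in range(MAX_RESAMPLES):
            if state.basis.rank == 0:
                break
            out = random_forward_direction(state.basis, P, rng,
                                           objective=state.gradient)
            if isinstance(out, str):  # no improving ray in the sampled cone
                break
            if float(state.gradient @ out) >= -EPS * max(gnorm, 1.0):
                continue  # numerically flat combination; resample
            stopped = advance_projection(state, out)
            if stopped == INTERIOR_MINIMUM:
                state.basis = ActiveBasis(P.n)
                advances += 1
                moved = True
                break
            # nonzero move iff the distance strictly decreased; a zero-length
            # degenerate touch leaves x (and the gradient) unchanged
            if float(np.linalg.norm(state.gradient)) < gnorm * (1.0 - EPS):
                new_basis = ActiveBasis(P.n)
                new_basis.insert_row(P, stopped)
                state.basis = new_basis
                advances += 1
                moved = True
                break
        if moved:
            continue

        cert, d = certify_or_direction(state.x, P, P.z - state.x)
        if cert is not None:
            return SolveResult(state.x, P.objective(state.x), STATUS_OPTIMAL,
                               fixations, advances, certificate=cert,
                               max_descent_insertions=max_ins)
        stopped = advance_projection(state, d)
        advances += 1
        state.basis = ActiveBasis(P.n)
        if stopped != INTERIOR_MINIMUM:
            state.basis.insert_row(P, stopped)

    return SolveResult(state.x, P.objective(state.x), STATUS_MAX_ITER,
                       fixations, advances, max_descent_insertions=max_ins)
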