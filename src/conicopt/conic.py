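"""Conic-sampling solver for linear programs.

The solver alternates two phases over the polytope ``A x <= b``:

1. **Descent to fixation.**  From a feasible point it repeatedly moves along
   the negated objective projected orthogonal to the constraint rows met so
   far, adding each limiting row to an :class:`ActiveBasis`.  Because every
   accepted row is linearly independent of its predecessors, at most ``n``
   rows are inserted before the projected objective vanishes (fixation).

2. **Ray sampling.**  At fixation the active rows carve out a polyhedral
   cone of feasible directions.  Its spanning rays are the inward normals of
   the basis rows, each projected orthogonal to all other basis rows.  A
   random conic combination of the improving rays (those with negative
   objective slope) is followed back through the interior to the next
   limiting constraint, after which descent resumes.  If no spanning ray
   improves the objective, the current vertex is optimal.

Optimality is always confirmed by an explicit nonnegative-combination
certificate: solving ``min ||A[T].T @ lam + c||`` over ``lam >= 0`` on the
tight rows ``T`` (scipy NNLS).  By a Farkas-type alternative, a residual of
zero certifies optimality, while a nonzero residual vector ``r`` yields the
strictly improving feasible direction ``-r`` (``A[T] @ (-r) <= 0`` by the
NNLS first-order conditions and ``c @ (-r) = -||r||^2 < 0``).  That
alternative doubles as the deterministic anticycling fallback at degenerate
vertices, where randomly sampled rays can be blocked at zero step: after a
bounded number of resamples the solver takes the certified direction, which
is guaranteed a nonzero advance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.optimize

from .config import CERT_TOL, EPS
from .linalg import OrthogonalBasis
from .problems import (
    Certificate,
    LinearProgram,
    ProjectionProblem,
    SolveResult,
    STATUS_INFEASIBLE_START,
    STATUS_MAX_ITER,
    STATUS_OPTIMAL,
    STATUS_UNBOUNDED,
    active_rows,
    is_feasible,
)

#: sentinel returned by :func:`advance` when no constraint limits the step
UNBOUNDED = "UNBOUNDED"
#: sentinel returned by :func:`random_forward_direction` when no ray improves
OPTIMAL = "OPTIMAL"

#: resamples of a blocked (zero-step) ray before the deterministic fallback
MAX_RESAMPLES = 25


class ContractViolation(RuntimeError):
    """A solver subroutine was called outside its preconditions."""


@dataclass
class ActiveBasis:
    """Linearly independent active constraint rows plus their orthogonal span.

    ``constraint_ids`` lists row indices of ``A`` in insertion order; ``ortho``
    holds the matching orthonormalized rows.  Inserts that would make the set
    dependent are rejected, so ``len(constraint_ids) <= n`` always holds.
    """

    dimension: int
    constraint_ids: list[int] = field(default_factory=list)
    ortho: OrthogonalBasis = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ortho is None:
            self.ortho = OrthogonalBasis(self.dimension)

    @property
    def rank(self) -> int:
        return self.ortho.rank

    def insert_row(self, P: "LinearProgram | ProjectionProblem", i: int) -> bool:
        accepted = self.ortho.insert(P.row(i), source_id=i)
        if accepted:
            self.constraint_ids.append(int(i))
        return accepted

    def project_orthogonal(self, v: np.ndarray) -> np.ndarray:
        return self.ortho.project_orthogonal(v)


# ---------------------------------------------------------------------------
# Advance: ratio test along a direction
# ---------------------------------------------------------------------------

def advance(x: np.ndarray, d: np.ndarray,
            P: "LinearProgram | ProjectionProblem",
            ) -> tuple[np.ndarray, "int | None | str", float]:
    """Move from ``x`` along ``d`` until the first constraint is met.

    Returns ``(x', limiting_row | None | UNBOUNDED, t*)`` where
    ``t* = min over rows with A_i @ d > eps of (b_i - A_i @ x)/(A_i @ d)``.
    Ties are broken toward the smallest row index (lexicographic, part of
    the anticycling policy).  ``t* = 0`` is legal: a tight row not in the
    caller's basis blocks the move (degenerate touch).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    dnorm = float(np.linalg.norm(d))
    if dnorm <= EPS:
        raise ContractViolation("direction has (near-)zero norm")
    if not is_feasible(x, P, tol=1e-6 * (1.0 + float(np.max(np.abs(P.b))))):
        raise ContractViolation("advance called from an infeasible point")

    Ad = P.A @ d
    slack = np.maximum(P.b - P.A @ x, 0.0)  # clip fp negatives on tight rows
    blocking = np.nonzero(Ad > EPS * dnorm)[0]
    if blocking.size == 0:
        return x, UNBOUNDED, np.inf
    ratios = slack[blocking] / Ad[blocking]
    t_star = float(np.min(ratios))
    # lexicographic tie-break: smallest row index among (near-)minimizers
    near = blocking[ratios <= t_star + 1e-12 * (1.0 + t_star)]
    j = int(np.min(near))
    return x + t_star * d, j, t_star


# ---------------------------------------------------------------------------
# Descent to fixation
# ---------------------------------------------------------------------------

def advance_to_fixation(x: np.ndarray, P: LinearProgram, basis: ActiveBasis,
                        ) -> tuple[np.ndarray, bool, int]:
    """Descend along the projected negative objective until it vanishes.

    Mutates ``basis`` in place.  Returns ``(x, unbounded, advances)``.  The
    number of basis insertions is bounded by the dimension ``n``: each
    limiting row has a nonzero component outside the current span (its inner
    product with the step direction is positive while the direction is
    orthogonal to the span), so every insert increases the rank.
    """
    c = P.c
    cnorm = float(np.linalg.norm(c))
    advances = 0
    inserted = 0
    while True:
        d = -basis.project_orthogonal(c)
        if float(np.linalg.norm(d)) <= EPS * max(cnorm, 1.0):
            return x, False, advances
        x_new, j, t = advance(x, d, P)
        if j == UNBOUNDED:
            return x, True, advances
        x = x_new
        advances += 1
        if basis.insert_row(P, j):
            inserted += 1
            if inserted > P.n:
                raise AssertionError(
                    "descent inserted more rows than the dimension")
        # a rejected (dependent) row can only occur at t == 0 on degenerate
        # polytopes; the projected objective is then re-examined and the
        # sampling phase takes over if it has not vanished
        if basis.rank >= P.n:
            d = -basis.project_orthogonal(c)
            if float(np.linalg.norm(d)) <= EPS * max(cnorm, 1.0):
                return x, False, advances
        if t == 0.0 and not _made_progress(j, basis):
            # dependent blocking row with zero step: defer to the caller's
            # anticycling fallback rather than loop forever
            return x, False, advances


def _made_progress(j: "int | str", basis: ActiveBasis) -> bool:
    return bool(basis.constraint_ids) and basis.constraint_ids[-1] == j


# ---------------------------------------------------------------------------
# Cone rays and sampling
# ---------------------------------------------------------------------------

def spanning_rays(basis: ActiveBasis,
                  P: "LinearProgram | ProjectionProblem") -> np.ndarray:
    """Unit spanning rays of the cone of the basis rows' feasible directions.

    Ray ``i`` is the inward normal ``-A_i`` projected orthogonal to every
    other basis row, i.e. the direction that releases constraint ``i`` while
    staying on all the others: ``A_j @ r_i = 0`` for ``j != i`` and
    ``A_i @ r_i < 0``.  Computed in closed form as the negated rows of
    ``(A_S A_S^T)^{-1} A_S`` (which satisfy ``A_i @ h_j = delta_ij``).
    """
    ids = basis.constraint_ids
    if not ids:
        raise ContractViolation("spanning_rays requires a nonempty basis")
    A_S = np.vstack([P.row(i) for i in ids])
    G = A_S @ A_S.T
    try:
        H = scipy.linalg.solve(G, A_S, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        raise ContractViolation("basis rows are linearly dependent") from exc
    rays = -H
    norms = np.linalg.norm(rays, axis=1)
    if np.any(norms <= EPS):
        raise ContractViolation("basis rows are linearly dependent")
    return rays / norms[:, None]


def random_forward_direction(basis: ActiveBasis,
                             P: "LinearProgram | ProjectionProblem",
                             rng: np.random.Generator,
                             objective: Optional[np.ndarray] = None,
                             ) -> "np.ndarray | str":
    """Sample an improving direction from the cone at a fixation point.

    ``objective`` defaults to the LP objective ``P.c``; the projection solver
    passes the current gradient instead.  Weights are i.i.d. Uniform(0, 1]
    over the improving rays only (rays with slope ``>= -eps||c||`` get weight
    zero), which guarantees a strictly improving combination in one draw.
    When the basis spans less than the full space — fixation on a face — a
    random vector from the orthogonal complement is mixed in; it has zero
    objective slope there, so improvement is unaffected while the move can
    leave the face's affine hull.
    Returns :data:`OPTIMAL` when no spanning ray improves.
    """
    c = P.c if objective is None else objective  # type: ignore[union-attr]
    cnorm = float(np.linalg.norm(c))
    rays = spanning_rays(basis, P)
    slopes = rays @ c
    improving = np.nonzero(slopes < -EPS * max(cnorm, 1.0))[0]
    if improving.size == 0:
        return OPTIMAL
    lam = rng.uniform(low=np.nextafter(0.0, 1.0), high=1.0,
                      size=improving.size)
    d = lam @ rays[improving]
    if basis.rank < basis.dimension:
        w = basis.project_orthogonal(rng.standard_normal(basis.dimension))
        wnorm = float(np.linalg.norm(w))
        if wnorm > EPS:
            w /= wnorm
            if w @ c > 0:
                w = -w
            d = d + rng.uniform(0.0, 1.0) * float(np.linalg.norm(d)) * w
    return d / float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# Certificates and the Farkas fallback
# ---------------------------------------------------------------------------

def certify_or_direction(x: np.ndarray,
                         P: "LinearProgram | ProjectionProblem",
                         target: np.ndarray,
                         ) -> tuple[Optional[Certificate], Optional[np.ndarray]]:
    """Either certify optimality at ``x`` or produce an improving direction.

    ``target`` is the vector that must lie in the cone of the tight rows'
    outward normals: ``-c`` for the LP, ``z - x`` for a projection.  Solves
    ``min ||A[T].T @ lam - target||, lam >= 0`` with NNLS.  Small residual ->
    certificate; otherwise the negated residual vector is returned as a
    feasible direction of strict improvement (zero slope on every tight row
    by the NNLS optimality conditions).
    """
    T = active_rows(x, P)
    scale = 1.0 + float(np.linalg.norm(target))
    if T.size == 0:
        resid = float(np.linalg.norm(target))
        if resid <= CERT_TOL * scale:
            return Certificate((), np.zeros(0), resid), None
        return None, target / max(resid, EPS)
    At = np.vstack([P.row(i) for i in T]).T  # n x |T|
    lam, _ = scipy.optimize.nnls(At, target)
    r = At @ lam - target
    resid = float(np.linalg.norm(r))
    if resid <= CERT_TOL * scale:
        return Certificate(tuple(int(i) for i in T), lam, resid), None
    return None, -r / resid


# ---------------------------------------------------------------------------
# Full solver
# ---------------------------------------------------------------------------

def solve_lp(P: LinearProgram, x0: np.ndarray | None = None,
             seed: int | np.random.Generator = 0,
             max_fixations: int | None = None) -> SolveResult:
    """Solve ``min c @ x, A x <= b`` by conic sampling from feasible ``x0``.

    ``x0`` defaults to the origin (the benchmark polytopes contain it).
    Identical ``(P, x0, seed)`` reproduce the full trajectory, including the
    fixation and advance counters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    x = np.zeros(P.n) if x0 is None else np.asarray(x0, dtype=float).copy()
    if max_fixations is None:
        max_fixations = 10 * (P.n + P.k)
    if not is_feasible(x, P):
        return SolveResult(x, np.nan, STATUS_INFEASIBLE_START)

    basis = ActiveBasis(P.n)
    fixations = advances = 0
    max_ins = 0

    for _ in range(max_fixations):
        x, unbounded, adv = advance_to_fixation(x, P, basis)
        advances += adv
        max_ins = max(max_ins, basis.rank)
        if unbounded:
            return SolveResult(x, -np.inf, STATUS_UNBOUNDED,
                               fixations, advances,
                               max_descent_insertions=max_ins)
        fixations += 1

        moved = False
        for _ in range(MAX_RESAMPLES):
            if basis.rank == 0:
                break  # no cone to sample; fall through to the certificate
            out = random_forward_direction(basis, P, rng)
            if isinstance(out, str):  # OPTIMAL per the sampled cone
                break
            if float(P.c @ out) >= -EPS * max(float(np.linalg.norm(P.c)), 1.0):
                continue  # numerically flat combination; resample
            x_new, j, t = advance(x, out, P)
            if j == UNBOUNDED:
                return SolveResult(x, -np.inf, STATUS_UNBOUNDED,
                                   fixations, advances + 1,
                                   max_descent_insertions=max_ins)
            if t > EPS * (1.0 + float(np.linalg.norm(x))):
                x = x_new
                basis = ActiveBasis(P.n)
                basis.insert_row(P, j)  # limiting row stays active
                advances += 1
                moved = True
                break
            # zero-length move: a tight non-basis row blocks the ray; resample

        if moved:
            continue

        # No nonzero random move (or rays report optimal): decide with the
        # Farkas certificate over *all* tight rows, which also covers
        # degenerate vertices where the sampled cone was too small.
        cert, d = certify_or_direction(x, P, -P.c)
        if cert is not None:
            return SolveResult(x, P.objective(x), STATUS_OPTIMAL,
                               fixations, advances, certificate=cert,
                               max_descent_insertions=max_ins)
        x_new, j, t = advance(x, d, P)
        if j == UNBOUNDED:
            return SolveResult(x, -np.inf, STATUS_UNBOUNDED,
                               fixations, advances + 1,
                               max_descent_insertions=max_ins)
        x = x_new
        basis = ActiveBasis(P.n)
        basis.insert_row(P, j)
        advances += 1

    return SolveResult(x, P.objective(x), STATUS_MAX_ITER,
                       fixations, advances, max_descent_insertions=max_ins)
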