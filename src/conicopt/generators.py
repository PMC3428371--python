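"""Random benchmark instances and brute-force reference oracles.

The LP generator reproduces the benchmark design used throughout the test
grid: rows of ``A`` and the objective drawn uniformly, a configurable
fraction of entries of ``A`` forced to zero (rows are redrawn if they come
out all zero), a strictly positive right-hand side so the origin is always
strictly feasible, and explicit nonnegativity rows ``-x_j <= 0`` appended
for every variable (flagged so the simplex baseline can skip them).

The oracles are deliberately naive and independent of the solvers: the LP
oracle enumerates every potential vertex as an ``n``-subset of constraint
rows; the projection oracle enumerates candidate active sets.  Both refuse
instances too large to enumerate.  Unboundedness of an LP is decided by an
improving-ray feasibility check delegated to ``scipy.optimize.linprog``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .config import EPS
from .problems import LinearProgram, ProjectionProblem

ORACLE_UNBOUNDED = "UNBOUNDED"

#: hard cap on the number of row subsets an oracle will enumerate
MAX_ENUMERATION = 2_000_000


class OracleRefusalError(ValueError):
    """The instance is too large for brute-force enumeration."""


@dataclass
class LpGenSpec:
    """Parameters of the random-LP generator."""

    n: int
    k: int
    sparsity: float = 0.0
    value_range: tuple[float, float] = (-1.0, 1.0)
    b_range: tuple[float, float] = (0.1, 1.1)
    sparsify_c: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1:
            raise ValueError("n and k must be positive")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.b_range[0] <= 0.0:
            raise ValueError("b must be strictly positive (0 must be interior)")


def gen_random_lp(spec: LpGenSpec) -> LinearProgram:
    """Draw a random LP with the origin strictly feasible.

    ``A`` has ``spec.k`` dense-drawn rows with the requested fraction of
    entries zeroed (all-zero rows are redrawn), ``b`` is positive, and ``n``
    nonnegativity rows are appended, so the full constraint count is
    ``k + n``.  Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.value_range
    rows = np.empty((spec.k, spec.n))
    for i in range(spec.k):
        while True:
            row = rng.uniform(lo, hi, size=spec.n)
            if spec.sparsity > 0.0:
                row[rng.random(spec.n) < spec.sparsity] = 0.0
            if np.any(np.abs(row) > EPS):
                rows[i] = row
                break
    b = rng.uniform(*spec.b_range, size=spec.k)
    c = rng.uniform(lo, hi, size=spec.n)
    if spec.sparsify_c and spec.sparsity > 0.0:
        c[rng.random(spec.n) < spec.sparsity] = 0.0

    A = sp.vstack([sp.csr_matrix(rows), -sp.identity(spec.n, format="csr")])
    b_full = np.concatenate([b, np.zeros(spec.n)])
    nonneg = tuple(range(spec.k, spec.k + spec.n))
    return LinearProgram(A.tocsr(), b_full, c, nonneg_rows=nonneg)


def gen_random_projection(spec: LpGenSpec, z_scale: float = 2.0,
                          ) -> ProjectionProblem:
    """Random projection instance over the same polytope family.

    The target ``z`` is an isotropic Gaussian scaled by ``z_scale``, which
    places most targets outside the (unit-scale) polytope while keeping the
    feasible-target case exercised.  Deterministic in ``spec.seed``.
    """
    lp = gen_random_lp(spec)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    z = z_scale * rng.standard_normal(spec.n)
    return ProjectionProblem(lp.A, lp.b, z)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def _feasible(A: np.ndarray, b: np.ndarray, x: np.ndarray,
              tol: float = 1e-8) -> bool:
    return bool(np.all(A @ x <= b + tol * (1.0 + np.abs(b))))


def oracle_lp(P: LinearProgram) -> "float | str":
    """Optimal objective by exhaustive vertex enumeration.

    Every ``n``-subset of constraint rows is solved as a square system; the
    minimum objective over feasible solutions is returned.  Unboundedness is
    decided first by checking for an improving recession ray
    (``A d <= 0, c @ d <= -1``) with a box-bounded feasibility LP.
    """
    n, k = P.n, P.k
    if math.comb(k, n) > MAX_ENUMERATION:
        raise OracleRefusalError(f"C({k},{n}) subsets exceed the cap")
    A = P.A.toarray()
    b = P.b

    ray = scipy.optimize.linprog(
        np.zeros(n), A_ub=np.vstack([A, P.c[None, :]]),
        b_ub=np.concatenate([np.zeros(k), [-1.0]]),
        bounds=[(-1e6, 1e6)] * n, method="highs")
    if ray.status == 0:
        return ORACLE_UNBOUNDED

    best = np.inf
    for subset in itertools.combinations(range(k), n):
        As = A[list(subset)]
        try:
            x = np.linalg.solve(As, b[list(subset)])
        except np.linalg.LinAlgError:
            continue
        if _feasible(A, b, x):
            best = min(best, float(P.c @ x))
    if not np.isfinite(best):
        raise OracleRefusalError("no feasible vertex found by enumeration")
    return best


def oracle_projection(P: ProjectionProblem) -> float:
    """Optimal squared distance by active-set enumeration.

    For every subset ``S`` of rows up to size ``n``, project ``z`` onto the
    affine subspace where the rows of ``S`` are tight (via least squares on
    the Gram system) and keep the feasible candidates; the minimum squared
    distance over candidates is the projection distance, since the true
    active set is among the subsets.
    """
    n, k = P.n, P.k
    if k > 20:
        raise OracleRefusalError("projection oracle limited to k <= 20 rows")
    total = sum(math.comb(k, m) for m in range(min(n, k) + 1))
    if total > MAX_ENUMERATION:
        raise OracleRefusalError("too many active-set candidates")
    A = P.A.toarray()
    b = P.b
    z = P.z

    best = np.inf
    if _feasible(A, b, z):
        return 0.0
    for m in range(1, min(n, k) + 1):
        for subset in itertools.combinations(range(k), m):
            As = A[list(subset)]
            bs = b[list(subset)]
            G = As @ As.T
            alpha, *_ = np.linalg.lstsq(G, bs - As @ z, rcond=None)
            x = z + As.T @ alpha
            # skip inconsistent (rank-deficient, unattainable) subsets
            if np.max(np.abs(As @ x - bs)) > 1e-7 * (1.0 + np.max(np.abs(bs))):
                continue
            if _feasible(A, b, x):
                best = min(best, float((x - z) @ (x - z)))
    if not np.isfinite(best):
        raise OracleRefusalError("no feasible candidate found by enumeration")
    return best
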