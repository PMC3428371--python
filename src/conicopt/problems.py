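"""Problem containers, feasibility checks, and JSON file I/O.

Both problem kinds share the inequality convention ``A x <= b`` over a
polytope with ``k`` constraint rows in ``n`` dimensions:

* :class:`LinearProgram` — minimize ``c @ x`` over the polytope;
* :class:`ProjectionProblem` — find the point of the polytope nearest a
  target ``z`` (minimize ``||x - z||^2``).

Constraint matrices are held as :class:`scipy.sparse.csr_matrix`; the
benchmark polytopes are sparse by construction and every solver touches
``A`` only through matrix-vector products and row extraction.

File format (JSON, 0-based indices)::

    {"n": 2, "k": 4, "A": [[0, 0, 1.0], ...], "b": [...], "c": [...]}

where ``A`` is a triplet list ``[row, col, value]``.  A projection instance
replaces ``"c"`` with ``"z"``.  An optional ``"nonneg_rows"`` array flags
rows of the form ``-x_j <= 0`` appended by the generator; the simplex
baseline skips those rows because slack form already implies them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .config import EPS, feasibility_tol
from .linalg import DimensionMismatchError


class ProblemFormatError(ValueError):
    """Raised when a problem file is malformed or violates an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _validate_polytope(A: sp.csr_matrix, b: np.ndarray) -> None:
    k, n = A.shape
    if k < 1 or n < 1:
        raise ProblemFormatError("need at least one row and one column")
    if b.shape != (k,):
        raise ProblemFormatError(f"b has length {b.shape[0]}, expected {k}")
    row_norms = np.sqrt(np.asarray(A.multiply(A).sum(axis=1)).ravel())
    bad = np.nonzero(row_norms <= EPS)[0]
    if bad.size:
        raise ProblemFormatError(f"zero-norm constraint rows: {bad.tolist()}")


@dataclass
class LinearProgram:
    """``min c @ x  s.t.  A x <= b`` with sparse rows."""

    A: sp.csr_matrix
    b: np.ndarray
    c: np.ndarray
    #: indices of rows of the form ``-x_j <= 0``; solvers that imply
    #: nonnegativity structurally (tableau simplex) may skip them.
    nonneg_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.c = np.asarray(self.c, dtype=float).ravel()
        _validate_polytope(self.A, self.b)
        if self.c.shape != (self.n,):
            raise ProblemFormatError(
                f"c has length {self.c.shape[0]}, expected {self.n}")
        self.nonneg_rows = tuple(int(i) for i in self.nonneg_rows)

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def k(self) -> int:
        return self.A.shape[0]

    def objective(self, x: np.ndarray) -> float:
        return float(self.c @ np.asarray(x, dtype=float))

    def row(self, i: int) -> np.ndarray:
        return self.A.getrow(i).toarray().ravel()


@dataclass
class ProjectionProblem:
    """Find ``argmin ||x - z||^2`` over the polytope ``A x <= b``."""

    A: sp.csr_matrix
    b: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.A = sp.csr_matrix(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        _validate_polytope(self.A, self.b)
        if self.z.shape != (self.n,):
            raise ProblemFormatError(
                f"z has length {self.z.shape[0]}, expected {self.n}")

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def k(self) -> int:
        return self.A.shape[0]

    def objective(self, x: np.ndarray) -> float:
        """Squared Euclidean distance to the target."""
        d = np.asarray(x, dtype=float) - self.z
        return float(d @ d)

    def row(self, i: int) -> np.ndarray:
        return self.A.getrow(i).toarray().ravel()


@dataclass
class Certificate:
    """Nonnegative-combination optimality certificate.

    At an optimum of the LP, ``-c`` lies in the cone of the active rows:
    ``A[active].T @ multipliers ~= -c`` with ``multipliers >= 0``.  For a
    projection the target of the combination is ``z - x*`` instead (KKT
    stationarity of the nearest point).
    """

    active_rows: tuple[int, ...]
    multipliers: np.ndarray
    residual: float


@dataclass
class SolveResult:
    x: np.ndarray
    objective: float
    status: str  # optimal | unbounded | infeasible_start | max_iter
    fixations: int = 0
    advances: int = 0
    iterations: int = 0
    certificate: Optional[Certificate] = None
    #: largest number of basis insertions in any single descent-to-fixation
    #: call; bounded by the dimension n.
    max_descent_insertions: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()


STATUS_OPTIMAL = "optimal"
STATUS_UNBOUNDED = "unbounded"
STATUS_INFEASIBLE_START = "infeasible_start"
STATUS_MAX_ITER = "max_iter"


# ---------------------------------------------------------------------------
# feasibility
# ---------------------------------------------------------------------------

def is_feasible(x: Sequence[float], P: "LinearProgram | ProjectionProblem",
                tol: float | None = None) -> bool:
    """True iff ``A_i @ x <= b_i + tol_i`` for every row.

    With ``tol=None`` the per-row scaled slack ``EPS * (1 + |b_i|)`` is used;
    a scalar ``tol`` applies uniformly.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (P.n,):
        raise DimensionMismatchError(f"point has shape {x.shape}, expected ({P.n},)")
    slack = P.b - P.A @ x
    tols = feasibility_tol(P.b) if tol is None else np.full(P.k, float(tol))
    return bool(np.all(slack >= -tols))


def active_rows(x: np.ndarray, P: "LinearProgram | ProjectionProblem",
                tol_scale: float = 1e3) -> np.ndarray:
    """Indices of rows tight at ``x`` within ``tol_scale * EPS * (1+|b_i|)``."""
    resid = np.abs(P.A @ np.asarray(x, dtype=float) - P.b)
    return np.nonzero(resid <= tol_scale * feasibility_tol(P.b))[0]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _triplets(A: sp.csr_matrix) -> list[list[float]]:
    coo = A.tocoo()
    order = np.lexsort((coo.col, coo.row))
    return [[int(coo.row[i]), int(coo.col[i]), float(coo.data[i])]
            for i in order]


def _matrix_from_triplets(trips, k: int, n: int) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for t in trips:
        if len(t) != 3:
            raise ProblemFormatError(f"A triplet {t!r} must be [row, col, value]")
        i, j, v = int(t[0]), int(t[1]), float(t[2])
        if not (0 <= i < k and 0 <= j < n):
            raise ProblemFormatError(f"A triplet {t!r} outside {k}x{n}")
        rows.append(i); cols.append(j); vals.append(v)
    return sp.csr_matrix((vals, (rows, cols)), shape=(k, n))


def write_problem(P: "LinearProgram | ProjectionProblem", path: str | Path) -> None:
    doc: dict = {
        "n": P.n,
        "k": P.k,
        "A": _triplets(P.A),
        "b": P.b.tolist(),
    }
    if isinstance(P, LinearProgram):
        doc["c"] = P.c.tolist()
        if P.nonneg_rows:
            doc["nonneg_rows"] = list(P.nonneg_rows)
    else:
        doc["z"] = P.z.tolist()
    Path(path).write_text(json.dumps(doc))


def read_problem(path: str | Path) -> "LinearProgram | ProjectionProblem":
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ProblemFormatError(f"not valid JSON: {exc}") from exc
    for key in ("n", "k", "A", "b"):
        if key not in doc:
            raise ProblemFormatError(f"missing required field {key!r}")
    n, k = int(doc["n"]), int(doc["k"])
    A = _matrix_from_triplets(doc["A"], k, n)
    b = np.asarray(doc["b"], dtype=float)
    if "c" in doc and "z" in doc:
        raise ProblemFormatError("file declares both 'c' and 'z'")
    if "c" in doc:
        return LinearProgram(A, b, np.asarray(doc["c"], dtype=float),
                             nonneg_rows=tuple(doc.get("nonneg_rows", ())))
    if "z" in doc:
        return ProjectionProblem(A, b, np.asarray(doc["z"], dtype=float))
    raise ProblemFormatError("missing field 'c' (LP) or 'z' (projection)")


def write_solution(res: SolveResult, path: str | Path) -> None:
    doc = {
        "x": res.x.tolist(),
        "objective": res.objective,
        "status": res.status,
        "fixations": res.fixations,
        "advances": res.advances,
    }
    Path(path).write_text(json.dumps(doc))
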