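"""Sparse vector primitives and incremental orthogonal-basis maintenance.

The solvers repeatedly project directions orthogonal to the constraint rows
accumulated while descending along the polytope.  :class:`OrthogonalBasis`
maintains an orthonormal basis of the span of inserted rows using modified
Gram-Schmidt, adding one row at a time and never revisiting existing rows.
A second Gram-Schmidt pass on the inserted vector keeps the basis orthogonal
to working precision even for nearly dependent inputs.

:class:`SparseVector` is a minimal index->value container used by the problem
file format and the bipartite-graph compiler; dense numpy arrays are used
inside the numerical kernels, where the dimensions are moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .config import EPS


class DimensionMismatchError(ValueError):
    """Raised when operands of a vector operation disagree on dimension."""


@dataclass
class SparseVector:
    """A real vector of fixed dimension storing only nonzero entries.

    Entries with magnitude at most ``EPS`` are dropped on construction and
    after arithmetic, so a stored entry is always numerically nonzero.
    """

    dimension: int
    entries: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        clean: dict[int, float] = {}
        for idx, val in self.entries.items():
            if not 0 <= idx < self.dimension:
                raise IndexError(f"index {idx} outside [0, {self.dimension})")
            if abs(val) > EPS:
                clean[int(idx)] = float(val)
        self.entries = clean

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dense(cls, v: Iterable[float]) -> "SparseVector":
        arr = np.asarray(list(v), dtype=float)
        return cls(arr.size, {i: x for i, x in enumerate(arr) if abs(x) > EPS})

    # -- conversions ---------------------------------------------------
    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.dimension)
        for i, v in self.entries.items():
            out[i] = v
        return out

    # -- arithmetic ----------------------------------------------------
    def dot(self, other: "SparseVector | np.ndarray") -> float:
        if isinstance(other, SparseVector):
            if other.dimension != self.dimension:
                raise DimensionMismatchError(
                    f"{self.dimension} vs {other.dimension}"
                )
            if len(other.entries) < len(self.entries):
                self, other = other, self
            return sum(v * other.entries.get(i, 0.0) for i, v in self.entries.items())
        other = np.asarray(other, dtype=float)
        if other.size != self.dimension:
            raise DimensionMismatchError(f"{self.dimension} vs {other.size}")
        return sum(v * other[i] for i, v in self.entries.items())

    def norm(self) -> float:
        return float(np.sqrt(sum(v * v for v in self.entries.values())))

    def scaled(self, alpha: float) -> "SparseVector":
        return SparseVector(self.dimension, {i: alpha * v for i, v in self.entries.items()})

    def axpy(self, alpha: float, other: "SparseVector") -> "SparseVector":
        """Return ``self + alpha * other`` with tiny entries pruned."""
        if other.dimension != self.dimension:
            raise DimensionMismatchError(f"{self.dimension} vs {other.dimension}")
        out = dict(self.entries)
        for i, v in other.entries.items():
            out[i] = out.get(i, 0.0) + alpha * v
        return SparseVector(self.dimension, out)

    def __iter__(self) -> Iterator[tuple[int, float]]:
        return iter(sorted(self.entries.items()))

    def __len__(self) -> int:
        return len(self.entries)


class OrthogonalBasis:
    """Orthonormal basis grown one vector at a time via modified Gram-Schmidt.

    Rows are stored unit-normalized; insertion order (and the caller-supplied
    ``source_ids``) is preserved, which the anticycling logic relies on.
    Only the newly inserted vector is orthogonalized — prior rows are never
    touched, matching the incremental update cost of one Gram-Schmidt sweep.
    """

    def __init__(self, dimension: int):
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self._rows: list[np.ndarray] = []
        self.source_ids: list[int] = []

    # -- inspection ----------------------------------------------------
    @property
    def rank(self) -> int:
        return len(self._rows)

    @property
    def rows(self) -> np.ndarray:
        """Orthonormal rows as a ``(rank, dimension)`` array (copy-free view)."""
        if not self._rows:
            return np.zeros((0, self.dimension))
        return np.vstack(self._rows)

    def copy(self) -> "OrthogonalBasis":
        dup = OrthogonalBasis(self.dimension)
        dup._rows = [r.copy() for r in self._rows]
        dup.source_ids = list(self.source_ids)
        return dup

    # -- core operations -----------------------------------------------
    def _coerce(self, v: "SparseVector | np.ndarray") -> np.ndarray:
        if isinstance(v, SparseVector):
            if v.dimension != self.dimension:
                raise DimensionMismatchError(f"{self.dimension} vs {v.dimension}")
            return v.to_dense()
        arr = np.asarray(v, dtype=float)
        if arr.shape != (self.dimension,):
            raise DimensionMismatchError(f"{self.dimension} vs {arr.shape}")
        return arr

    def project_orthogonal(self, v: "SparseVector | np.ndarray") -> np.ndarray:
        """Component of ``v`` orthogonal to the span of the basis rows."""
        r = self._coerce(v).copy()
        for u in self._rows:  # modified Gram-Schmidt sweep
            r -= (r @ u) * u
        return r

    def insert(self, v: "SparseVector | np.ndarray", source_id: int = -1) -> bool:
        """Insert ``v``; return True if accepted, False if linearly dependent.

        The residual of ``v`` after orthogonalization against the current rows
        must exceed ``EPS * ||v||`` to be accepted; a second sweep re-cleans
        the residual before normalization (twice-is-enough reorthogonalization).
        """
        arr = self._coerce(v)
        vnorm = float(np.linalg.norm(arr))
        if vnorm <= EPS:
            return False
        if self.rank >= self.dimension:
            return False
        r = self.project_orthogonal(arr)
        rnorm = float(np.linalg.norm(r))
        if rnorm <= EPS * vnorm:
            return False
        r = self.project_orthogonal(r)
        rnorm = float(np.linalg.norm(r))
        if rnorm <= EPS * vnorm:
            return False
        self._rows.append(r / rnorm)
        self.source_ids.append(int(source_id))
        return True

    def complement_vector(self, v: "SparseVector | np.ndarray") -> np.ndarray:
        """Alias of :meth:`project_orthogonal` (readability at call sites)."""
        return self.project_orthogonal(v)


def basis_insert(basis: OrthogonalBasis, v: "SparseVector | np.ndarray",
                 source_id: int = -1) -> bool:
    """Functional wrapper over :meth:`OrthogonalBasis.insert`."""
    return basis.insert(v, source_id)


def project_orthogonal(v: "SparseVector | np.ndarray",
                       basis: OrthogonalBasis) -> np.ndarray:
    """Functional wrapper over :meth:`OrthogonalBasis.project_orthogonal`."""
    return basis.project_orthogonal(v)
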