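"""Global numerical tolerances.

Every comparison against zero in the solvers (activity tests, feasibility
slack, linear-dependence rejection, improving-direction thresholds) routes
through the single tolerance :data:`EPS` so that the whole stack shares one
notion of "numerically zero".
"""

from __future__ import annotations

import numpy as np

#: Global zero tolerance for scaled comparisons.
EPS: float = 1e-9

#: Residual tolerance for optimality certificates (nonnegative-combination /
#: KKT residuals), relative to 1 + the norm of the objective or target.
CERT_TOL: float = 1e-6


def is_zero(value: float, scale: float = 1.0, eps: float = EPS) -> bool:
    """True if ``value`` is zero within ``eps`` at the given ``scale``."""
    return abs(value) <= eps * max(scale, 1.0)


def leq(a: float, b: float, scale: float = 1.0, eps: float = EPS) -> bool:
    """Tolerant ``a <= b`` at the given scale."""
    return a <= b + eps * max(scale, 1.0)


def feasibility_tol(b: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Per-row feasibility slack ``eps * (1 + |b_i|)``."""
    return eps * (1.0 + np.abs(b))
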