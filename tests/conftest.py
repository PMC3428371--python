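import numpy as np
import pytest
import scipy.sparse as sp

from conicopt.problems import LinearProgram, ProjectionProblem


@pytest.fixture
def unit_box_lp() -> LinearProgram:
    """min -x1 - x2 over the unit box [0, 1]^2 (optimum -2 at (1, 1))."""
    A = sp.csr_matrix(np.vstack([np.eye(2), -np.eye(2)]))
    b = np.array([1.0, 1.0, 0.0, 0.0])
    return LinearProgram(A, b, np.array([-1.0, -1.0]), nonneg_rows=(2, 3))


@pytest.fixture
def square_lp() -> LinearProgram:
    """min -x1 - x2 over [0, 2]^2 (optimum -4 at (2, 2))."""
    A = sp.csr_matrix(np.vstack([np.eye(2), -np.eye(2)]))
    b = np.array([2.0, 2.0, 0.0, 0.0])
    return LinearProgram(A, b, np.array([-1.0, -1.0]), nonneg_rows=(2, 3))


@pytest.fixture
def unit_box_projection() -> ProjectionProblem:
    """Project z = (2, 0.5) onto the unit box (answer (1, 0.5), distance^2 = 1)."""
    A = sp.csr_matrix(np.vstack([np.eye(2), -np.eye(2)]))
    b = np.array([1.0, 1.0, 0.0, 0.0])
    return ProjectionProblem(A, b, np.array([2.0, 0.5]))
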