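"""Conic sampling on linear programs: subroutines and full solves."""

import numpy as np
import pytest
import scipy.sparse as sp

from conicopt.conic import (
    OPTIMAL,
    UNBOUNDED,
    ActiveBasis,
    ContractViolation,
    advance,
    advance_to_fixation,
    certify_or_direction,
    random_forward_direction,
    solve_lp,
    spanning_rays,
)
from conicopt.generators import (
    ORACLE_UNBOUNDED,
    LpGenSpec,
    gen_random_lp,
    oracle_lp,
)
from conicopt.problems import LinearProgram


def _lp(A, b, c, **kw):
    return LinearProgram(sp.csr_matrix(np.asarray(A, dtype=float)),
                         np.asarray(b, dtype=float),
                         np.asarray(c, dtype=float), **kw)


class TestAdvance:
    def test_hits_nearest_constraint(self, square_lp):
        x, j, t = advance(np.zeros(2), np.array([1.0, 0.0]), square_lp)
        assert j == 0 and t == pytest.approx(2.0)
        assert np.allclose(x, [2.0, 0.0])

    def test_unbounded_direction_flagged(self):
        P = _lp([[-1.0, 0.0]], [0.0], [0.0, 0.0])
        x, j, t = advance(np.zeros(2), np.array([1.0, 0.0]), P)
        assert j == UNBOUNDED and np.isinf(t)

    def test_degenerate_zero_step(self, square_lp):
        d = np.array([1.0, 1.0]) / np.sqrt(2.0)
        x, j, t = advance(np.array([2.0, 0.0]), d, square_lp)
        assert t == 0.0 and j == 0
        assert np.allclose(x, [2.0, 0.0])

    def test_contract_violations(self, square_lp):
        with pytest.raises(ContractViolation):
            advance(np.array([5.0, 0.0]), np.array([1.0, 0.0]), square_lp)
        with pytest.raises(ContractViolation):
            advance(np.zeros(2), np.zeros(2), square_lp)


class TestAdvanceToFixation:
    def test_square_descends_to_far_corner(self, square_lp):
        basis = ActiveBasis(2)
        x, unbounded, adv = advance_to_fixation(np.zeros(2), square_lp, basis)
        assert not unbounded
        assert np.allclose(x, [2.0, 2.0])
        assert basis.rank == 2 and adv <= 2
        # brute force: (2,2) minimizes -x1-x2 over the square's vertices
        vertices = [(0, 0), (0, 2), (2, 0), (2, 2)]
        assert min(vertices, key=lambda v: -v[0] - v[1]) == (2, 2)

    def test_immediate_return_at_full_basis(self, square_lp):
        basis = ActiveBasis(2)
        basis.insert_row(square_lp, 0)
        basis.insert_row(square_lp, 1)
        x, unbounded, adv = advance_to_fixation(
            np.array([2.0, 2.0]), square_lp, basis)
        assert adv == 0 and np.allclose(x, [2.0, 2.0])

    def test_halfspace_fixes_on_facet(self):
        P = _lp([[1.0, 0.0]], [1.0], [-1.0, 0.0])
        basis = ActiveBasis(2)
        x, unbounded, adv = advance_to_fixation(np.zeros(2), P, basis)
        assert not unbounded
        assert np.allclose(x, [1.0, 0.0]) and basis.rank == 1

    def test_unbounded_descent_propagates(self):
        P = _lp([[-1.0, 0.0]], [0.0], [-1.0, 0.0])
        x, unbounded, adv = advance_to_fixation(np.zeros(2), P, ActiveBasis(2))
        assert unbounded


class TestSpanningRays:
    def test_axis_aligned_corner(self, square_lp):
        basis = ActiveBasis(2)
        basis.insert_row(square_lp, 0)
        basis.insert_row(square_lp, 1)
        rays = spanning_rays(basis, square_lp)
        assert np.allclose(sorted(map(tuple, rays)), [(-1, 0), (0, -1)])

    def test_oblique_pair_satisfies_sign_structure(self):
        s = 1.0 / np.sqrt(2.0)
        P = _lp([[1.0, 0.0], [-s, -s]], [1.0, 0.0], [0.0, -1.0])
        basis = ActiveBasis(2)
        basis.insert_row(P, 0)
        basis.insert_row(P, 1)
        rays = spanning_rays(basis, P)
        A = P.A.toarray()
        for i, r in enumerate(rays):
            for j in range(2):
                dot = A[j] @ r
                if i == j:
                    assert dot < -1e-9
                else:
                    assert abs(dot) <= 1e-9

    def test_single_row_gives_inward_normal(self):
        P = _lp([[1.0, 0.0]], [1.0], [0.0, 0.0])
        basis = ActiveBasis(2)
        basis.insert_row(P, 0)
        rays = spanning_rays(basis, P)
        assert np.allclose(rays, [[-1.0, 0.0]])


class TestRandomForwardDirection:
    def test_optimal_corner_has_no_improving_ray(self, square_lp):
        basis = ActiveBasis(2)
        basis.insert_row(square_lp, 0)
        basis.insert_row(square_lp, 1)
        rng = np.random.default_rng(0)
        assert random_forward_direction(basis, square_lp, rng) == OPTIMAL

    def test_improving_combination_over_many_draws(self, square_lp):
        # vertex (2, 0): rows x1 <= 2 (non-improving release) and -x2 <= 0
        basis = ActiveBasis(2)
        basis.insert_row(square_lp, 0)
        basis.insert_row(square_lp, 3)
        rng = np.random.default_rng(123)
        A = square_lp.A.toarray()
        for _ in range(1000):
            d = random_forward_direction(basis, square_lp, rng)
            assert not isinstance(d, str)
            assert square_lp.c @ d < 0
            assert A[0] @ d <= 1e-9 or A[3] @ d <= 1e-9  # releases a row
            # the combination never violates a basis row it is not releasing
            assert min(A[0] @ d, A[3] @ d) <= 1e-9

    def test_one_dimensional_optimum(self):
        P = _lp([[1.0]], [1.0], [-1.0])
        basis = ActiveBasis(1)
        basis.insert_row(P, 0)
        rng = np.random.default_rng(7)
        assert random_forward_direction(basis, P, rng) == OPTIMAL


class TestSolveLp:
    def test_unit_box(self, unit_box_lp):
        res = solve_lp(unit_box_lp, seed=0)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(-2.0, abs=1e-9)
        assert np.allclose(res.x, [1.0, 1.0], atol=1e-9)

    def test_zero_objective_returns_start(self, unit_box_lp):
        P = _lp(unit_box_lp.A.toarray(), unit_box_lp.b, [0.0, 0.0])
        res = solve_lp(P, seed=5)
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0)

    def test_infeasible_start_reported(self, unit_box_lp):
        res = solve_lp(unit_box_lp, x0=np.array([5.0, 5.0]))
        assert res.status == "infeasible_start"

    def test_seed_determinism(self):
        P = gen_random_lp(LpGenSpec(n=5, k=15, sparsity=0.3, seed=9))
        a = solve_lp(P, seed=4)
        b = solve_lp(P, seed=4)
        assert np.array_equal(a.x, b.x)
        assert (a.fixations, a.advances) == (b.fixations, b.advances)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for i in range(15):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(4, 13))
            P = gen_random_lp(LpGenSpec(
                n=n, k=k, sparsity=float(rng.choice([0.0, 0.5])),
                seed=1000 * seed + i))
            expected = oracle_lp(P)
            res = solve_lp(P, seed=seed)
            if expected == ORACLE_UNBOUNDED:
                assert res.status == "unbounded"
            else:
                assert res.status == "optimal"
                assert res.objective == pytest.approx(expected, abs=1e-6)
                assert res.max_descent_insertions <= P.n

    def test_duplicated_rows_leave_objective_unchanged(self):
        P = gen_random_lp(LpGenSpec(n=4, k=8, sparsity=0.0, seed=77))
        res = solve_lp(P, seed=1)
        A2 = sp.vstack([P.A, P.A]).tocsr()
        b2 = np.concatenate([P.b, P.b])
        P2 = LinearProgram(A2, b2, P.c)
        res2 = solve_lp(P2, seed=1)
        assert res2.status == res.status == "optimal"
        assert res2.objective == pytest.approx(res.objective, abs=1e-8)


class TestCertificates:
    def test_certificate_accompanies_every_optimum(self):
        for i in range(10):
            P = gen_random_lp(LpGenSpec(n=4, k=10, sparsity=0.0, seed=300 + i))
            res = solve_lp(P, seed=i)
            if res.status != "optimal":
                continue
            cert = res.certificate
            assert cert is not None
            assert np.all(cert.multipliers >= 0)
            scale = 1.0 + float(np.linalg.norm(P.c))
            assert cert.residual <= 1e-6 * scale
            # recombine: A[active].T @ lambda ~ -c
            At = P.A[list(cert.active_rows)].toarray().T
            assert np.linalg.norm(At @ cert.multipliers + P.c) <= 1e-6 * scale

    def test_farkas_alternative_yields_descent_direction(self, square_lp):
        # at (2, 0) the vertex is suboptimal: no certificate, but a strictly
        # improving feasible direction comes back instead
        cert, d = certify_or_direction(np.array([2.0, 0.0]), square_lp,
                                       -square_lp.c)
        assert cert is None
        assert square_lp.c @ d < 0
        tight = square_lp.A.toarray()[[0, 3]]
        assert np.all(tight @ d <= 1e-9)
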