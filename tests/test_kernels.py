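"""Stochastic-matrix algebra: validation, composition, chain structure,
invariant measures, the kernel derivative and flow limits."""

from fractions import Fraction

import numpy as np
import pytest

from markovagents import (
    Kernel,
    PeriodicityReport,
    communicating_classes,
    compose,
    flow,
    invariant_measures,
    is_idempotent,
    kernel_derivative,
    m2_kernel,
    power,
    validate_kernel,
)
from markovagents.fixtures import FixtureSpec, make_fixtures
from markovagents.kernels import KernelValidationError, ShapeError


class TestValidation:
    def test_rectangular_kernel_accepted(self):
        k = validate_kernel([[0.1, 0.3, 0.6], [0.4, 0.4, 0.2]])
        assert k.shape == (2, 3)
        assert not k.is_square

    def test_identity_accepted(self):
        assert validate_kernel(np.eye(2)).is_square

    def test_bad_row_sum_names_row(self):
        with pytest.raises(KernelValidationError, match="row 1 sum 0.9"):
            validate_kernel([[0.5, 0.4]])

    def test_negative_entry_names_cell(self):
        with pytest.raises(KernelValidationError, match=r"\(2, 1\)"):
            validate_kernel([[0.5, 0.5], [-0.1, 1.1]])

    def test_near_one_row_renormalized(self):
        k = validate_kernel([[0.5, 0.5 + 1e-12]])
        assert abs(k.matrix.sum() - 1.0) < 1e-15

    def test_label_count_mismatch(self):
        with pytest.raises(ShapeError):
            validate_kernel(np.eye(2), row_labels=(1, 2, 3))


class TestAlgebra:
    def test_identity_composes_neutrally(self):
        q = m2_kernel(0.3, 0.2)
        ident = validate_kernel(np.eye(2))
        assert compose(ident, q).allclose(q)

    def test_not_kernel_squares_to_identity(self, not2):
        assert compose(not2, not2).allclose(validate_kernel(np.eye(2)))
        assert power(not2, 2).allclose(validate_kernel(np.eye(2)))

    def test_square_offdiagonals_match_closed_form(self):
        # Q(x,y)^2 off-diagonals are x(2-x-y), y(2-x-y)
        x, y = 0.3, 0.2
        q2 = compose(m2_kernel(x, y), m2_kernel(x, y))
        assert q2.matrix[0, 1] == pytest.approx(x * (2 - x - y))  # 0.45
        assert q2.matrix[1, 0] == pytest.approx(y * (2 - x - y))  # 0.30

    def test_power_zero_is_identity(self):
        q = m2_kernel(0.5, 0.25)
        assert power(q, 0).allclose(validate_kernel(np.eye(2)))
        assert power(q, 1).allclose(q)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            power(m2_kernel(0.5, 0.25), -1)

    def test_compose_label_mismatch(self):
        k1 = validate_kernel(np.eye(2), (1, 2), (1, 2))
        k2 = validate_kernel(np.eye(3), (1, 2, 3), (1, 2, 3))
        with pytest.raises(ShapeError):
            compose(k1, k2)

    def test_mixed_exact_arithmetic(self):
        q = m2_kernel(Fraction(1, 2), Fraction(1, 4))
        sq = compose(q, q)
        assert sq.matrix[0, 1] == Fraction(1, 2) * (2 - Fraction(3, 4))


class TestClassStructure:
    def test_nine_state_cycles(self, chain9):
        cs = communicating_classes(chain9)
        got = {frozenset(c) for c in cs.classes}
        assert got == {
            frozenset({1, 5, 8}),
            frozenset({2}),
            frozenset({3, 4}),
            frozenset({6}),
            frozenset({7, 9}),
        }
        assert all(cs.recurrent)
        assert cs.absorbing == frozenset({2, 6})
        periods = dict(zip(map(frozenset, cs.classes), cs.periods))
        assert periods[frozenset({1, 5, 8})] == 3
        assert periods[frozenset({3, 4})] == 2
        assert periods[frozenset({2})] == 1

    def test_identity_two_absorbing_singletons(self, identity2):
        cs = communicating_classes(identity2)
        assert cs.absorbing == frozenset({1, 2})
        assert all(len(c) == 1 for c in cs.classes)

    def test_transient_vs_absorbing(self):
        q = validate_kernel([[0.5, 0.5], [0.0, 1.0]])
        cs = communicating_classes(q)
        assert not cs.is_recurrent(1)
        assert cs.is_recurrent(2)
        assert cs.absorbing == frozenset({2})

    def test_not_kernel_period_two_and_selfloop_aperiodic(self, not2):
        cs = communicating_classes(not2)
        assert cs.periods == (2,)
        loopy = validate_kernel([[0.1, 0.9], [0.9, 0.1]])
        assert communicating_classes(loopy).periods == (1,)


class TestInvariantMeasures:
    def test_single_measure_interior(self):
        (mu,) = invariant_measures(m2_kernel(0.5, 0.25))
        assert mu == pytest.approx([1 / 3, 2 / 3])

    def test_identity_two_extremal_measures(self, identity2):
        mus = invariant_measures(identity2)
        assert len(mus) == 2
        assert mus[0] == pytest.approx([1, 0])
        assert mus[1] == pytest.approx([0, 1])

    def test_not_kernel_uniform(self, not2):
        (mu,) = invariant_measures(not2)
        assert mu == pytest.approx([0.5, 0.5])

    def test_agrees_with_eigenvector_oracle(self):
        # brute-force: left eigenvector of eigenvalue 1 restricted to a class
        for k in make_fixtures(FixtureSpec(n=4, count=20, seed=11)):
            mus = invariant_measures(k)
            assert len(mus) == 1  # dirichlet kernels are irreducible
            w, v = np.linalg.eig(k.matrix.T)
            i = int(np.argmin(np.abs(w - 1)))
            oracle = np.real(v[:, i])
            oracle = oracle / oracle.sum()
            assert mus[0] == pytest.approx(oracle, abs=1e-9)

    def test_exact_rational_measure(self):
        q = m2_kernel(Fraction(1, 2), Fraction(1, 4))
        (mu,) = invariant_measures(q)
        assert list(mu) == [Fraction(1, 3), Fraction(2, 3)]


class TestDerivativeAndFlow:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (0.2, 0.2, (0.12, 0.12)),
            (0.5, 0.5, (0.0, 0.0)),  # on the fusion line
            (1.0, 1.0, (-1.0, -1.0)),  # NOT kernel
        ],
    )
    def test_derivative_offdiagonals(self, x, y, expected):
        d = kernel_derivative(m2_kernel(x, y))
        assert d[0, 1] == pytest.approx(expected[0], abs=1e-12)
        assert d[1, 0] == pytest.approx(expected[1], abs=1e-12)

    def test_derivative_identity_on_grid(self):
        for x in np.linspace(0, 1, 10):
            for y in np.linspace(0, 1, 10):
                d = kernel_derivative(m2_kernel(x, y))
                assert abs(d[0, 1] - x * (1 - x - y)) < 1e-12
                assert abs(d[1, 0] - y * (1 - x - y)) < 1e-12
                assert abs(d.sum(axis=1)).max() < 1e-12  # rows sum to zero

    def test_flow_reaches_fusion_line(self):
        f = flow(m2_kernel(0.5, 0.25))
        assert f.matrix == pytest.approx(np.array([[1 / 3, 2 / 3]] * 2))
        assert is_idempotent(f)

    def test_not_kernel_power_flow_reports_period(self, not2):
        report = flow(not2, mode="power")
        assert isinstance(report, PeriodicityReport)
        assert report.periodic_classes[0][1] == 2

    def test_not_kernel_cesaro_flow(self, not2):
        f = flow(not2, mode="cesaro")
        assert f.matrix == pytest.approx(np.full((2, 2), 0.5))

    def test_flow_with_transient_states_matches_iteration(self):
        q = validate_kernel([[0.5, 0.3, 0.2], [0.0, 0.6, 0.4], [0.0, 0.1, 0.9]])
        f = flow(q)
        iterated = np.linalg.matrix_power(q.matrix, 4000)
        assert f.matrix == pytest.approx(iterated, abs=1e-9)
        assert is_idempotent(f)

    def test_flow_rows_mix_extremal_measures(self):
        # two absorbing states, one transient: rows are convex mixes
        q = validate_kernel([[1, 0, 0], [0, 1, 0], [0.25, 0.25, 0.5]])
        f = flow(q)
        assert f.matrix[2] == pytest.approx([0.5, 0.5, 0.0])

    def test_exact_flow(self):
        q = m2_kernel(Fraction(1, 2), Fraction(1, 4))
        f = flow(q)
        assert f.matrix[0, 0] == Fraction(1, 3)
        assert f.matrix[1, 1] == Fraction(2, 3)


class TestIdempotence:
    def test_rank_one_idempotent(self):
        q = validate_kernel([[0.7, 0.3], [0.7, 0.3]])
        assert is_idempotent(q)

    def test_identity_idempotent_not_kernel_not(self, identity2, not2):
        assert is_idempotent(identity2)
        assert not is_idempotent(not2)

    def test_m2_idempotent_set_is_origin_and_fusion_line(self):
        # exact boundary points
        assert is_idempotent(m2_kernel(0.0, 0.0))
        for x in np.linspace(0, 1, 11):
            assert is_idempotent(m2_kernel(x, 1 - x))
        # a fine grid away from {(0,0)} u {x+y=1} is never idempotent
        for x in np.linspace(0, 1, 21):
            for y in np.linspace(0, 1, 21):
                on_locus = (x == 0 and y == 0) or abs(x + y - 1) < 1e-12
                assert is_idempotent(m2_kernel(x, y)) == on_locus


class TestRandomizedInvariants:
    def test_operations_preserve_stochasticity(self):
        count = 0
        for n in range(2, 7):
            for k in make_fixtures(FixtureSpec(n=n, count=40, seed=100 + n)):
                for result in (power(k, 3), flow(k, mode="cesaro")):
                    sums = np.asarray(
                        [row.sum() for row in result.matrix], dtype=float
                    )
                    assert np.abs(sums - 1).max() < 1e-9
                count += 1
        assert count == 200
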