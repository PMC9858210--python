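"""The Markov polytope: vertices, adjacency, cells, fusion, and the M2 flow
field and invariant-measure lines."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from markovagents import (
    FusionPoint,
    cell_of,
    enumerate_support_cells,
    flow,
    flow_field_m2,
    fuse,
    fusion_kernel,
    invariant_line_slope,
    invariant_measures,
    is_idempotent,
    m2_kernel,
    polytope_summary,
    polytope_vertices,
    qualia_mix,
    validate_kernel,
    vertex_adjacency,
)
from markovagents.polytope import NotFusedError


class TestSummaryAndVertices:
    @pytest.mark.parametrize(
        "n,dim,count", [(1, 0, 1), (2, 2, 4), (3, 6, 27), (4, 12, 256)]
    )
    def test_dimension_and_vertex_count(self, n, dim, count):
        s = polytope_summary(n)
        assert s == {"dimension": dim, "vertex_count": count}

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            polytope_summary(0)

    def test_vertices_are_deterministic_kernels(self):
        verts = polytope_vertices(2)
        assert len(verts) == 4
        mats = [v.matrix.tolist() for v in verts]
        assert [[1, 0], [1, 0]] in mats  # constant map to 1
        assert [[1, 0], [0, 1]] in mats  # identity
        assert [[0, 1], [1, 0]] in mats  # NOT
        assert len(polytope_vertices(3)) == 27

    def test_vertex_guard(self):
        with pytest.raises(ValueError, match="guard"):
            polytope_vertices(9)


class TestAdjacency:
    def test_square_is_four_cycle(self):
        g = vertex_adjacency(2)
        assert g.number_of_nodes() == 4
        assert all(d == 2 for _, d in g.degree())
        # identity (0,1) and NOT (1,0) differ in both rows: not adjacent
        assert not g.has_edge((0, 1), (1, 0))

    def test_m3_regular_degree_six(self):
        g = vertex_adjacency(3)
        assert g.number_of_nodes() == 27
        assert all(d == 6 for _, d in g.degree())

    def test_degree_is_n_times_n_minus_one(self):
        for n in (2, 3, 4):
            g = vertex_adjacency(n)
            assert all(d == n * (n - 1) for _, d in g.degree())


class TestCells:
    def test_m2_corner_cells(self, identity2, not2):
        assert str(cell_of(identity2)) == "[3,4]"
        assert str(cell_of(not2)) == "[2,3]"
        assert str(cell_of(m2_kernel(0.4, 0.7))) == "[2,3]"  # interior

    def test_absorbing_transient_cell(self):
        q = validate_kernel([[1.0, 0.0], [0.5, 0.5]])
        assert str(cell_of(q)) == "[3,2]"

    def test_m2_census_is_the_four_cells(self):
        cells = enumerate_support_cells(2)
        assert {str(c) for c in cells} == {"[3,4]", "[2,3]", "[3,2]", "[1,4]"}

    def test_n1_census(self):
        assert {str(c) for c in enumerate_support_cells(1)} == {"[2]"}

    def test_m3_census_regression_locked(self):
        # exhaustive over the 343 support patterns of M3
        cells = enumerate_support_cells(3)
        assert len(cells) == 14

    def test_m3_vertex_census_regression_locked(self):
        sigmas = {cell_of(v).images for v in polytope_vertices(3)}
        assert len(sigmas) == 14


class TestFusion:
    def test_fusion_kernel_rows_equal_weights(self):
        fk = fusion_kernel(FusionPoint((1, 2), (0.7, 0.3)))
        assert fk.matrix == pytest.approx(np.array([[0.7, 0.3], [0.7, 0.3]]))
        assert is_idempotent(fk)
        (mu,) = invariant_measures(fk)
        assert mu == pytest.approx([0.7, 0.3])

    def test_simplex_vertex_is_constant_map(self):
        fk = fusion_kernel(FusionPoint((1, 2, 3), (1.0, 0.0, 0.0)))
        assert fk.matrix[:, 0] == pytest.approx(np.ones(3))

    def test_cesaro_flow_of_not_is_barycenter(self, not2):
        fk = fusion_kernel(FusionPoint((1, 2), (0.5, 0.5)))
        assert flow(not2, mode="cesaro").allclose(fk)

    def test_fuse_reads_common_row(self):
        point = fuse(validate_kernel([[0.7, 0.3], [0.7, 0.3]]))
        assert point.weights == pytest.approx((0.7, 0.3))

    def test_fuse_rejects_identity_as_rank_two(self, identity2):
        with pytest.raises(NotFusedError, match="rank"):
            fuse(identity2)

    def test_fuse_rejects_non_idempotent(self, not2):
        with pytest.raises(NotFusedError, match="idempotent"):
            fuse(not2)

    def test_roundtrip_fusion_kernel_fuse(self):
        for w in [(0.5, 0.5), (0.2, 0.8), (Fraction(1, 3), Fraction(2, 3))]:
            point = FusionPoint((1, 2), w)
            assert fuse(fusion_kernel(point)).weights == pytest.approx(
                tuple(float(v) for v in w)
            )

    def test_flow_of_interior_kernel_fuses_at_invariant_measure(self):
        for x, y in [(0.5, 0.25), (0.1, 0.9), (0.33, 0.44)]:
            q = m2_kernel(x, y)
            point = fuse(flow(q))
            (mu,) = invariant_measures(q)
            assert point.weights == pytest.approx(tuple(mu))
            # the flow lands on the fusion line y = 1 - x
            fm = flow(q).matrix
            assert fm[0, 1] + fm[1, 0] == pytest.approx(1.0)


class TestInvariantLines:
    @pytest.mark.parametrize("alpha,slope", [(1 / 3, 0.5), (0.5, 1.0), (2 / 3, 2.0)])
    def test_slope(self, alpha, slope):
        assert invariant_line_slope(alpha) == pytest.approx(slope)

    def test_domain(self):
        for bad in (0, 1, -0.2, 1.5):
            with pytest.raises(ValueError):
                invariant_line_slope(bad)

    def test_kernels_on_line_share_invariant_measure(self):
        for alpha in np.linspace(0.1, 0.9, 9):
            slope = invariant_line_slope(alpha)
            for x in np.linspace(0.05, min(1.0, 1 / max(slope, 1e-9)) * 0.9, 5):
                y = slope * x
                (mu,) = invariant_measures(m2_kernel(x, y))
                assert mu == pytest.approx([alpha, 1 - alpha], abs=1e-9)


class TestFlowField:
    def test_sources_and_sinks(self):
        f = flow_field_m2(11)
        # identity corner (0,0): zero vector
        assert f.dx[0, 0] == 0 and f.dy[0, 0] == 0
        # (0.5, 0.5) lies on the fusion line
        assert f.dx[5, 5] == pytest.approx(0.0, abs=1e-12)

    def test_interior_vector_value(self):
        f = flow_field_m2(6)  # grid step 0.2 -> (0.2, 0.2) at index (1, 1)
        assert f.dx[1, 1] == pytest.approx(0.12)
        assert f.dy[1, 1] == pytest.approx(0.12)

    def test_vanishing_locus(self):
        f = flow_field_m2(21)
        mag = np.hypot(f.dx, f.dy)
        on_locus = ((f.x == 0) & (f.y == 0)) | (np.abs(f.x + f.y - 1) < 1e-12)
        assert np.all((mag < 1e-12) == on_locus)

    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            flow_field_m2(1)


class TestQualiaMix:
    RED, GREEN, BLUE = (1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)

    def test_pure_and_even_mix(self):
        pal = {1: self.RED, 2: self.GREEN}
        assert qualia_mix(FusionPoint((1, 2), (1.0, 0.0)), pal) == self.RED
        assert qualia_mix(FusionPoint((1, 2), (0.5, 0.5)), pal) == (0.5, 0.5, 0.0)

    def test_barycenter_of_three(self):
        pal = {1: self.RED, 2: self.GREEN, 3: self.BLUE}
        mix = qualia_mix(FusionPoint((1, 2, 3), (1 / 3, 1 / 3, 1 / 3)), pal)
        assert mix == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_missing_palette_entry(self):
        with pytest.raises(KeyError):
            qualia_mix(FusionPoint((1, 2), (0.5, 0.5)), {1: self.RED})

    def test_fusion_points_live_on_simplex(self):
        with pytest.raises(ValueError):
            FusionPoint((1, 2), (0.7, 0.7))
        with pytest.raises(ValueError):
            FusionPoint((1, 2), (-0.1, 1.1))
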