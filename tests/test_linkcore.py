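import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skeinpath import fixtures as fx
from skeinpath import linkcore as lc


SQUARE = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])


def brute_force_crossings(link):
    """Independent oracle: pure-python all-pairs 2D segment intersection."""
    es = link.edges()
    pts = link.points
    found = []
    for i in range(len(es)):
        for j in range(i + 1, len(es)):
            a, b = es[i], es[j]
            if {a.from_idx, a.to_idx} & {b.from_idx, b.to_idx}:
                continue
            p1, p2 = pts[a.from_idx][:2], pts[a.to_idx][:2]
            p3, p4 = pts[b.from_idx][:2], pts[b.to_idx][:2]
            d1 = p2 - p1
            d2 = p4 - p3
            den = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(den) < 1e-12:
                continue
            t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / den
            u = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / den
            if 0 < t < 1 and 0 < u < 1:
                z1 = pts[a.from_idx][2] + t * (pts[a.to_idx][2] - pts[a.from_idx][2])
                z2 = pts[b.from_idx][2] + u * (pts[b.to_idx][2] - pts[b.from_idx][2])
                found.append((i, j, z1 < z2))
    return found


class TestBuildLink:
    def test_square_unknot(self):
        link = lc.build_link(SQUARE, [0], [True])
        assert link.n_components == 1
        assert len(link.edges()) == 4
        assert lc.find_crossings(link) == []

    def test_two_separated_squares(self):
        pts = np.vstack([SQUARE, SQUARE + np.array([3.0, 0, 0])])
        link = lc.build_link(pts, [0, 4], [True, True])
        assert link.n_components == 2
        assert link.separators == [0, 4]

    def test_zero_length_edge_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 0, 0]])
        with pytest.raises(lc.NonSimpleLinkError, match="zero-length"):
            lc.build_link(pts, [0], [False])

    def test_non_simple_rejected_with_pair(self):
        # two open segments crossing through each other in 3D
        pts = np.array(
            [[0.0, 0, 0], [2, 0, 0], [1, -1, 0], [1, 1, 0]]
        )
        with pytest.raises(lc.NonSimpleLinkError) as exc:
            lc.build_link(pts, [0, 2], [False, False])
        assert exc.value.edge_pair is not None

    def test_undersized_component(self):
        with pytest.raises(ValueError):
            lc.build_link(np.array([[0.0, 0, 0]]), [0], [False])


class TestGeneralPosition:
    def test_overlapping_projection_gets_rotated(self):
        pts = np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 0, 1], [1, 0, 1]]
        )
        link = lc.PolygonalLink(pts, [0, 2], [False, False])
        assert not lc.is_regular(link)
        fixed = lc.ensure_general_position(link, seed=1)
        assert lc.is_regular(fixed)
        # rigid rotation preserves all pairwise distances
        d0 = np.linalg.norm(pts[0] - pts[3])
        d1 = np.linalg.norm(fixed.points[0] - fixed.points[3])
        assert d1 == pytest.approx(d0)

    def test_regular_input_returned_unchanged(self):
        link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
        out = lc.ensure_general_position(link, seed=5)
        assert out is link

    def test_deterministic(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 0, 1], [1, 0, 1]])
        link = lc.PolygonalLink(pts, [0, 2], [False, False])
        a = lc.ensure_general_position(link, seed=42)
        b = lc.ensure_general_position(link, seed=42)
        np.testing.assert_array_equal(a.points, b.points)


class TestFindCrossings:
    def test_planar_square_empty(self):
        link = lc.build_link(SQUARE, [0], [True])
        assert lc.find_crossings(link) == []

    def test_trefoil_three_equal_signs(self):
        link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
        crossings = lc.find_crossings(link)
        assert len(crossings) == 3
        assert {c.oriented_sign for c in crossings} == {1}
        brute = brute_force_crossings(link)
        assert len(brute) == 3

    def test_figure_eight_writhe_zero(self):
        link = fx.make_fixture(fx.FixtureSpec("figure_eight", 100))
        crossings = lc.find_crossings(link)
        assert len(crossings) == 4
        assert sum(c.oriented_sign for c in crossings) == 0
        assert len(brute_force_crossings(link)) == 4

    def test_matches_brute_force_on_braid(self):
        link = fx.braid_link(*fx.BRAID_WORDS["6_1"])
        crossings = lc.find_crossings(link)
        brute = brute_force_crossings(link)
        assert len(crossings) == len(brute) == 7
        mine = {(min(c.under_edge, c.over_edge), max(c.under_edge, c.over_edge)) for c in crossings}
        theirs = {(i, j) for i, j, _ in brute}
        assert mine == theirs


class TestMirror:
    def test_signs_negated(self):
        link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
        m = lc.mirror_link(link)
        assert [c.oriented_sign for c in lc.find_crossings(m)] == [-1, -1, -1]

    def test_involution(self):
        link = fx.make_fixture(fx.FixtureSpec("figure_eight", 100))
        mm = lc.mirror_link(lc.mirror_link(link))
        a = lc.find_crossings(link)
        b = lc.find_crossings(mm)
        assert [(c.under_edge, c.over_edge, c.oriented_sign) for c in a] == [
            (c.under_edge, c.over_edge, c.oriented_sign) for c in b
        ]

    def test_mirror_duality_crossing_by_crossing(self):
        link = fx.braid_link(*fx.BRAID_WORDS["5_2"])
        a = sorted(
            (c.under_edge, c.over_edge, c.oriented_sign) for c in lc.find_crossings(link)
        )
        b = sorted(
            (c.over_edge, c.under_edge, -c.oriented_sign)
            for c in lc.find_crossings(lc.mirror_link(link))
        )
        assert a == b

    def test_planar_unknot_still_no_crossings(self):
        link = lc.build_link(SQUARE, [0], [True])
        assert lc.find_crossings(lc.mirror_link(link)) == []


class TestIntersectionMatrix:
    def test_planar_zero(self):
        link = lc.build_link(SQUARE, [0], [True])
        m = lc.intersection_matrix(link)
        assert not m.any()

    def test_trefoil_antisymmetric_six_entries(self):
        link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
        m = lc.intersection_matrix(link)
        assert (m != 0).sum() == 6
        np.testing.assert_array_equal(m, -m.T)
        assert not m.diagonal().any()

    def test_hopf_cross_component_block(self):
        link = fx.braid_link(*fx.BRAID_WORDS["hopf+"])
        es = link.edges()
        e1 = [e.edge_id for e in es if e.component == 0]
        e2 = [e.edge_id for e in es if e.component == 1]
        block = lc.intersection_matrix(link, e1, e2)
        assert (block != 0).sum() == 2

    def test_antisymmetry_on_random_chain(self):
        link = lc.ensure_general_position(fx.random_chain(60, seed=3), 1)
        m = lc.intersection_matrix(link)
        np.testing.assert_array_equal(m, -m.T)


class TestDiagramGaussCode:
    def test_pass_counts(self):
        link = fx.make_fixture(fx.FixtureSpec("figure_eight", 100))
        code = lc.diagram_gauss_code(link)
        assert len(code) == 1
        assert len(code[0]) == 8  # 4 crossings, two passes each
        from collections import Counter

        counts = Counter(cid for cid, _, _ in code[0])
        assert all(v == 2 for v in counts.values())


class TestCoordsIO:
    def test_round_trip(self, tmp_path):
        link = fx.braid_link(*fx.BRAID_WORDS["hopf+"])
        path = tmp_path / "hopf.coords"
        lc.write_coords(link, path)
        back = lc.read_coords(path)
        assert back.separators == link.separators
        assert back.closed_flags == link.closed_flags
        np.testing.assert_allclose(back.points, link.points, rtol=1e-11, atol=1e-14)

    def test_open_flag_round_trip(self):
        link = fx.random_chain(10, seed=1)
        back = lc.loads_coords(lc.dumps_coords(link))
        assert back.closed_flags == [False]

    def test_bad_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            lc.loads_coords("# open\n1 2\n")


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mirror_involution_property(seed):
    link = fx.random_chain(12, seed=seed)
    mm = lc.mirror_link(lc.mirror_link(link))
    np.testing.assert_array_equal(mm.points, link.points)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 5_000))
def test_writhe_invariant_under_general_position_identity(seed):
    link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
    out = lc.ensure_general_position(link, seed=seed)
    assert out is link
    assert lc.writhe(out) == 3
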