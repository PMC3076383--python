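import numpy as np
import pytest

from skeinpath import fixtures as fx
from skeinpath import linkcore as lc
from skeinpath import skein
from skeinpath.homfly import KNOT_TABLE, ONE, homfly_of_gauss, propagate_weights
from skeinpath.msr import msr_reduce


@pytest.fixture(scope="module")
def reduced_trefoil():
    link = fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
    reduced, _ = msr_reduce(link)
    return reduced


@pytest.fixture(scope="module")
def reduced_fig8():
    link = fx.make_fixture(fx.FixtureSpec("figure_eight", 100))
    reduced, _ = msr_reduce(link)
    return reduced


def classify(link):
    return KNOT_TABLE.get(homfly_of_gauss(lc.diagram_gauss_code(link)))


def brute_quad_clean(link, quad, crossing, shrink=1.0):
    """Oracle: quadrilateral sides tested against every edge pair-wise."""
    poly = np.array([quad.vertex(i, shrink) for i in quad.order])
    skip = {crossing.under_edge, crossing.over_edge}
    for s in range(4):
        ok, hits = lc.segment_hits(link, poly[s], poly[(s + 1) % 4], skip)
        if not ok or hits:
            return False
    return not skein._vertex_inside_poly(link, poly[:, :2], [])


class TestCleanQuadrilateral:
    def test_sparse_crossing_accepts_full_cuts(self):
        # two skew segments only: nothing to collide with
        pts = np.array(
            [[-1.0, 0, 0], [1, 0, 0], [0.1, -1, 1], [-0.1, 1, 1]]
        )
        link = lc.build_link(pts, [0, 2], [False, False])
        c = lc.find_crossings(link)[0]
        quad = skein.build_clean_quadrilateral(link, c)
        np.testing.assert_array_equal(quad.t, np.ones(4))

    def test_third_edge_forces_halving(self):
        # a distant third edge crossing one cut edge's neighbourhood
        pts = np.array(
            [
                [-1.0, 0, 0],
                [1, 0, 0],
                [0.1, -1, 1],
                [-0.1, 1, 1],
                [-0.9, 0.5, 2],
                [0.9, 0.5, 2],
            ]
        )
        link = lc.build_link(pts, [0, 2, 4], [False, False, False])
        c = [x for x in lc.find_crossings(link) if {x.under_edge, x.over_edge} == {0, 1}][0]
        quad = skein.build_clean_quadrilateral(link, c)
        assert (quad.t < 1).any()
        assert brute_quad_clean(link, quad, c)

    def test_figure_eight_all_crossings_clean(self, reduced_fig8):
        for c in lc.find_crossings(reduced_fig8):
            quad = skein.build_clean_quadrilateral(reduced_fig8, c)
            assert brute_quad_clean(reduced_fig8, quad, c)
            assert (quad.t > 0).all()


class TestXclean:
    def _quad_and_crossing(self, link):
        c = lc.find_crossings(link)[0]
        quad = skein.build_clean_quadrilateral(link, c)
        return quad, c

    def test_isolated_quadrilateral_clean(self):
        pts = np.array([[-1.0, 0, 0], [1, 0, 0], [0.1, -1, 1], [-0.1, 1, 1]])
        link = lc.build_link(pts, [0, 2], [False, False])
        quad, c = self._quad_and_crossing(link)
        poly = quad.vertices_cyclic()
        skip = frozenset({c.under_edge, c.over_edge})
        clean, table = skein.xclean(
            poly, link, skein.StatusTable(np.zeros((4, 2), dtype=int)), range(4), skip
        )
        assert clean
        assert not table.rows.any()

    def test_shared_side_bookkeeping(self, reduced_fig8):
        c = lc.find_crossings(reduced_fig8)[0]
        quad = skein.build_clean_quadrilateral(reduced_fig8, c)
        # inflate one vertex far out so a side collides with the diagram
        big = quad.vertices_cyclic()
        big[0] = big[0] + 50 * (big[0] - np.array([*c.xy, 0.0]))
        skip = frozenset({c.under_edge, c.over_edge})
        clean, table = skein.xclean(
            big, reduced_fig8, skein.StatusTable(np.zeros((4, 2), dtype=int)), range(4), skip
        )
        if not clean:
            # each dirty side must be recorded twice: leaving one vertex
            # and entering the next
            for s in range(4):
                assert table.rows[s, 1] == table.rows[(s + 1) % 4, 0]

    def test_incremental_equals_full(self, reduced_fig8):
        rng = np.random.default_rng(5)
        c = lc.find_crossings(reduced_fig8)[0]
        quad = skein.build_clean_quadrilateral(reduced_fig8, c)
        skip = frozenset({c.under_edge, c.over_edge})
        poly = quad.vertices_cyclic()
        _, full0 = skein.xclean(
            poly, reduced_fig8, skein.StatusTable(np.zeros((4, 2), dtype=int)), range(4), skip
        )
        for _ in range(5):
            v = int(rng.integers(0, 4))
            poly2 = poly.copy()
            poly2[v] = poly2[v] + rng.normal(scale=0.3, size=3)
            _, incr = skein.xclean(poly2, reduced_fig8, full0, [v], skip)
            _, full = skein.xclean(
                poly2,
                reduced_fig8,
                skein.StatusTable(np.zeros((4, 2), dtype=int)),
                range(4),
                skip,
            )
            np.testing.assert_array_equal(incr.rows, full.rows)


class TestRotateQuadrilateral:
    def test_rotated_sides_not_parallel_to_edges(self, reduced_trefoil):
        for c in lc.find_crossings(reduced_trefoil):
            quad = skein.build_clean_quadrilateral(reduced_trefoil, c)
            rot, theta = skein.rotate_quadrilateral(reduced_trefoil, quad, c)
            assert theta != 0
            p0s, p1s, _, _ = reduced_trefoil.edge_arrays()
            du = (p1s - p0s)[c.under_edge][:2]
            do = (p1s - p0s)[c.over_edge][:2]
            poly = rot[list(quad.order)]
            for i in range(4):
                sd = poly[(i + 1) % 4, :2] - poly[i, :2]
                for dref in (du, do):
                    cross = abs(sd[0] * dref[1] - sd[1] * dref[0])
                    assert cross > 1e-9 * np.linalg.norm(sd) * np.linalg.norm(dref)

    def test_initial_angle_is_min_angle(self):
        pts = np.array([[-1.0, 0, 0], [1, 0, 0], [0.1, -1, 1], [-0.1, 1, 1]])
        link = lc.build_link(pts, [0, 2], [False, False])
        c = lc.find_crossings(link)[0]
        quad = skein.build_clean_quadrilateral(link, c)
        rot, theta = skein.rotate_quadrilateral(link, quad, c)
        p0s, p1s, _, _ = link.edge_arrays()
        du = (p1s - p0s)[c.under_edge][:2]
        do = (p1s - p0s)[c.over_edge][:2]
        ang = np.arccos(
            abs(du @ do) / (np.linalg.norm(du) * np.linalg.norm(do))
        )
        assert abs(theta) == pytest.approx(ang)

    def test_rotated_quad_clean_by_brute_force(self, reduced_fig8):
        for c in lc.find_crossings(reduced_fig8):
            quad = skein.build_clean_quadrilateral(reduced_fig8, c)
            rot, _ = skein.rotate_quadrilateral(reduced_fig8, quad, c)
            skip = {c.under_edge, c.over_edge}
            poly = rot[list(quad.order)]
            for s in range(4):
                ok, hits = lc.segment_hits(reduced_fig8, poly[s], poly[(s + 1) % 4], skip)
                assert ok and not hits


class TestTwoSideReplacement:
    def test_clean_region_passes(self):
        pts = np.array([[-1.0, 0, 0], [1, 0, 0], [0.1, -1, 1], [-0.1, 1, 1]])
        link = lc.build_link(pts, [0, 2], [False, False])
        ok = skein.two_side_replacement_check(
            link,
            [(np.array([5.0, 5, 0]), np.array([6.0, 5, 0]))],
            [np.array([5.0, 5, 0]), np.array([5.5, 5.4, 0]), np.array([6.0, 5, 0])],
            (np.array([5.0, 5.2, 0]), np.array([6.0, 5.2, 0])),
        )
        assert ok

    def test_new_distant_crossing_fails(self, reduced_trefoil):
        # replacement that sweeps across the whole diagram
        lo = reduced_trefoil.points.min(axis=0) - 1
        hi = reduced_trefoil.points.max(axis=0) + 1
        ok = skein.two_side_replacement_check(
            reduced_trefoil,
            [(lo, lo + np.array([0.1, 0, 0]))],
            [lo, hi],
            (lo, lo + np.array([0.1, 0, 0])),
        )
        assert not ok


class TestSwitchConfig:
    def test_trefoil_any_switch_unknots(self, reduced_trefoil):
        for c in lc.find_crossings(reduced_trefoil):
            switched = skein.make_switch_config(reduced_trefoil, c)
            reduced, _ = msr_reduce(switched)
            assert homfly_of_gauss(lc.diagram_gauss_code(reduced)) == ONE

    def test_double_switch_restores_type(self, reduced_fig8):
        c = lc.find_crossings(reduced_fig8)[0]
        once = skein.make_switch_config(reduced_fig8, c)
        # find the same crossing in the new link (same projected location)
        key = skein._crossing_key(c, reduced_fig8.bbox_diag())
        again = [
            x
            for x in lc.find_crossings(once)
            if skein._crossing_key(x, reduced_fig8.bbox_diag()) == key
        ][0]
        twice = skein.make_switch_config(once, again)
        assert classify(twice).name == "4_1"

    def test_alpha_sequence_contract(self, reduced_trefoil):
        with skein.audit_capture() as audit:
            c = lc.find_crossings(reduced_trefoil)[0]
            skein.make_switch_config(reduced_trefoil, c)
        assert audit.alpha_sequences
        for seq in audit.alpha_sequences:
            assert seq[0] == pytest.approx(0.9)
            assert all(b > a for a, b in zip(seq, seq[1:]))
            assert all(a < 1 for a in seq)

    def test_exactly_one_crossing_changes(self, reduced_fig8):
        c = lc.find_crossings(reduced_fig8)[0]
        switched = skein.make_switch_config(reduced_fig8, c)
        scale = reduced_fig8.bbox_diag()
        before = {
            skein._crossing_key(x, scale): x.oriented_sign
            for x in lc.find_crossings(reduced_fig8)
        }
        after = {
            skein._crossing_key(x, scale): x.oriented_sign
            for x in lc.find_crossings(switched)
        }
        assert set(before) == set(after)
        flipped = [k for k in before if before[k] != after[k]]
        assert len(flipped) == 1
        assert flipped[0] == skein._crossing_key(c, scale)


class TestZeroConfig:
    def test_self_crossing_splits(self, reduced_trefoil):
        c = lc.find_crossings(reduced_trefoil)[0]
        z = skein.make_zero_config(reduced_trefoil, c)
        assert z.n_components == 2

    def test_trefoil_smoothing_is_hopf(self, reduced_trefoil):
        for c in lc.find_crossings(reduced_trefoil):
            z = skein.make_zero_config(reduced_trefoil, c)
            zr, _ = msr_reduce(z)
            rec = classify(zr)
            assert rec is not None and rec.name.startswith("Hopf")

    def test_hopf_smoothing_merges(self):
        link, _ = msr_reduce(fx.braid_link(*fx.BRAID_WORDS["hopf+"]))
        c = lc.find_crossings(link)[0]
        z = skein.make_zero_config(link, c)
        assert z.n_components == 1

    def test_removes_exactly_one_crossing(self, reduced_fig8):
        c = lc.find_crossings(reduced_fig8)[0]
        z = skein.make_zero_config(reduced_fig8, c)
        assert len(lc.find_crossings(z)) == len(lc.find_crossings(reduced_fig8)) - 1


class TestSelectCrossing:
    def test_descending_diagram_returns_none(self):
        square = lc.build_link(
            np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), [0], [True]
        )
        assert skein.select_crossing(square, "greedy") is None
        assert skein.select_crossing(square, "fixed") is None

    @pytest.mark.parametrize("strategy", ["greedy", "fixed"])
    def test_trefoil_selection_unknots(self, reduced_trefoil, strategy):
        c = skein.select_crossing(reduced_trefoil, strategy)
        assert c is not None
        switched = skein.make_switch_config(reduced_trefoil, c)
        reduced, _ = msr_reduce(switched)
        assert homfly_of_gauss(lc.diagram_gauss_code(reduced)) == ONE

    def test_deterministic(self, reduced_fig8):
        a = skein.select_crossing(reduced_fig8, "greedy")
        b = skein.select_crossing(reduced_fig8, "greedy")
        assert (a.under_edge, a.over_edge) == (b.under_edge, b.over_edge)

    def test_candidates_are_first_met_under(self, reduced_fig8):
        cands = skein._first_under_candidates(reduced_fig8)
        code = lc.diagram_gauss_code(reduced_fig8)
        met_over = set()
        expected = []
        for comp in code:
            for cid, ou, _ in comp:
                if ou == "o":
                    met_over.add(cid)
                elif cid not in met_over:
                    expected.append(cid)
        assert [cid for cid, _ in cands] == expected


class TestSkeinTree:
    def test_unknot_single_node(self):
        square = lc.build_link(
            np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), [0], [True]
        )
        tree = skein.build_skein_tree(square)
        assert (tree.g, tree.nu) == (0, 1)
        assert tree.root.children is None
        assert tree.root.n_components == 1

    def test_minimal_trefoil_tree_shape(self, reduced_trefoil):
        tree = skein.build_skein_tree(reduced_trefoil)
        assert tree.nu == 5
        assert tree.g == 2

    def test_strategies_agree_on_figure_eight(self, reduced_fig8):
        pg = propagate_weights(skein.build_skein_tree(reduced_fig8, "greedy"))
        pf = propagate_weights(skein.build_skein_tree(reduced_fig8, "fixed"))
        assert pg == pf

    def test_json_export(self, reduced_trefoil):
        import json

        tree = skein.build_skein_tree(reduced_trefoil)
        payload = json.loads(tree.to_json())
        assert payload["nu"] == 5
        assert payload["g"] == 2
        assert len(payload["nodes"]) == 5
        inner = [n for n in payload["nodes"] if n["children"]]
        assert all(n["epsilon"] in (-1, 1) for n in inner)
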