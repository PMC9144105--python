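"""Per-segment geometry: lengths, tortuosity, lumen area, ordering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coromorph.geometry import rotate_deg
from coromorph.model import Segment, VascularNetwork
from coromorph.segments import (
    assign_branch_orders,
    compute_segment_metrics,
    direct_length,
    flow_length,
    lumen_area,
    summarize_segment,
    tortuosity_pct,
)

from conftest import make_segment


class TestLengths:
    def test_straight_flow_length(self):
        assert flow_length(make_segment([(0, 0), (100, 0)])) == pytest.approx(100.0)

    def test_three_four_five(self, bent_345):
        assert flow_length(bent_345) == pytest.approx(700.0)
        assert direct_length(bent_345) == pytest.approx(500.0)

    def test_noisy_polyline_matches_pairwise_sum_oracle(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(0, 10, size=(1000, 2)), axis=0)
        seg = make_segment(pts)
        oracle = sum(
            math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)
        )
        assert flow_length(seg) == pytest.approx(oracle, rel=1e-9)

    def test_closed_loop_warns_and_returns_zero(self):
        seg = make_segment([(0, 0), (100, 0), (100, 100), (0, 0)])
        with pytest.warns(UserWarning, match="closed loop"):
            assert direct_length(seg) == 0.0


class TestTortuosity:
    def test_straight_segment_is_zero(self, straight_500):
        assert tortuosity_pct(straight_500) == pytest.approx(0.0)

    def test_three_four_five_closed_form(self, bent_345):
        # T = 100 - 500*100/700
        assert tortuosity_pct(bent_345) == pytest.approx(100 - 500 * 100 / 700, abs=1e-9)
        assert tortuosity_pct(bent_345) == pytest.approx(28.5714, abs=1e-4)

    def test_semicircular_arc_closed_form(self):
        t = np.linspace(0, np.pi, 20001)
        r = 1000.0
        arc = make_segment(np.column_stack([r * np.cos(t), r * np.sin(t)]))
        # direct 2r, flow pi*r -> T = 100 - 200/pi
        assert tortuosity_pct(arc) == pytest.approx(100 - 200 / np.pi, abs=1e-3)
        assert tortuosity_pct(arc) == pytest.approx(36.338, abs=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        ang=st.floats(-180, 180),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
        scale=st.floats(0.1, 100),
    )
    def test_invariant_under_rigid_motion_and_scaling(self, ang, dx, dy, scale):
        base = make_segment([(0, 0), (300, 0), (300, 400), (500, 500)])
        t0 = tortuosity_pct(base)
        moved = make_segment(scale * rotate_deg(base.axis, ang) + np.array([dx, dy]))
        assert tortuosity_pct(moved) == pytest.approx(t0, abs=1e-8)

    def test_flow_at_least_direct_on_generated_tree(self, baseline_network):
        for seg in baseline_network.segments.values():
            assert flow_length(seg) >= direct_length(seg) - 1e-9


class TestLumenArea:
    def test_formula(self):
        assert lumen_area(100.0) == pytest.approx(31415.93, abs=0.01)
        assert lumen_area(0.0) == 0.0

    def test_doubling_radius_quadruples_area(self):
        assert lumen_area(84.0) == pytest.approx(4 * lumen_area(42.0))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            lumen_area(-1.0)


def _chain_network(n=4, length=1000.0):
    segs = {}
    for i in range(1, n + 1):
        x0 = (i - 1) * length
        segs[i] = make_segment(
            [(x0, 0.0), (x0 + length, 0.0)], sid=i, parent=None if i == 1 else i - 1
        )
    return VascularNetwork(segments=segs)


def _binary_tree(depth=3, length=500.0):
    segs = {}
    counter = [0]

    def grow(parent, order, start, heading):
        counter[0] += 1
        sid = counter[0]
        t = math.radians(heading)
        end = (start[0] + length * math.cos(t), start[1] + length * math.sin(t))
        d = 250.0 * 0.8 ** (order - 1)
        segs[sid] = make_segment([start, end], outer=(d,) * 3, inner=(0.8 * d,) * 3,
                                 sid=sid, parent=parent)
        if order < depth:
            grow(sid, order + 1, end, heading - 30.0)
            grow(sid, order + 1, end, heading + 30.0)

    grow(None, 1, (0.0, 0.0), 0.0)
    return VascularNetwork(segments=segs)


class TestBranchOrders:
    def test_unbranched_trunk_is_all_order_one(self):
        net = _chain_network()
        assign_branch_orders(net, "trunk-following")
        assert {s.branch_order for s in net.segments.values()} == {1}

    def test_generation_scheme_on_perfect_binary_tree(self):
        net = _binary_tree(depth=3)
        assign_branch_orders(net, "generation")
        orders = [s.branch_order for s in net.segments.values()]
        assert sorted(set(orders)) == [1, 2, 3]
        assert [orders.count(o) for o in (1, 2, 3)] == [1, 2, 4]

    def test_trunk_following_keeps_trunk_at_order_one(self):
        # trunk straight along +X; side branches at 50 degrees
        segs = {
            1: make_segment([(0, 0), (1000, 0)], outer=(300,) * 3, inner=(240,) * 3, sid=1),
            2: make_segment([(1000, 0), (2000, 0)], outer=(280,) * 3, inner=(224,) * 3,
                            sid=2, parent=1),
            3: make_segment([(1000, 0), (1600, 700)], outer=(150,) * 3, inner=(120,) * 3,
                            sid=3, parent=1),
            4: make_segment([(2000, 0), (3000, 0)], outer=(260,) * 3, inner=(208,) * 3,
                            sid=4, parent=2),
            5: make_segment([(2000, 0), (2600, -700)], outer=(140,) * 3, inner=(112,) * 3,
                            sid=5, parent=2),
        }
        net = VascularNetwork(segments=segs)
        assign_branch_orders(net, "trunk-following")
        assert [net.segments[s].branch_order for s in (1, 2, 4)] == [1, 1, 1]
        assert [net.segments[s].branch_order for s in (3, 5)] == [2, 2]
        # generation scheme increments along the trunk instead
        assign_branch_orders(net, "generation")
        assert [net.segments[s].branch_order for s in (1, 2, 4)] == [1, 2, 3]

    def test_generation_max_order_equals_tree_depth(self, baseline_network):
        m = compute_segment_metrics(baseline_network)
        adj = baseline_network.adjacency

        def depth(sid):
            kids = adj[sid]
            return 1 + (max(depth(k) for k in kids) if kids else 0)

        assert m.branch_order.max() == depth(baseline_network.root_id)

    def test_unknown_scheme_rejected(self, y_network):
        with pytest.raises(ValueError):
            assign_branch_orders(y_network, "strahler")


class TestSummaries:
    def test_three_point_means_and_wall(self):
        seg = make_segment([(0, 0), (1000, 0)], outer=(200, 210, 190),
                           inner=(160, 170, 150))
        m = summarize_segment(seg)
        assert m.mean_outer_diam == pytest.approx(200.0)
        assert m.mean_inner_diam == pytest.approx(160.0)
        assert m.wall_thickness == pytest.approx(20.0)
        assert m.lumen_area == pytest.approx(np.pi * 80.0**2)

    def test_root_flow_distance_is_own_length(self, straight_500):
        m = summarize_segment(straight_500, upstream_flow_distance=0.0)
        assert m.flow_distance_from_orifice == pytest.approx(500.0)

    def test_flow_distance_matches_ancestor_path_sum_oracle(self, baseline_network):
        m = compute_segment_metrics(baseline_network).set_index("segment_id")
        segs = baseline_network.segments
        for sid, seg in segs.items():
            path, cur = 0.0, sid
            while cur is not None:
                path += flow_length(segs[cur])
                cur = segs[cur].parent
            assert m.loc[sid, "flow_distance_um"] == pytest.approx(path, rel=1e-9)

    def test_total_length_matches_edge_sum_oracle(self, baseline_network):
        m = compute_segment_metrics(baseline_network)
        oracle = sum(
            np.hypot(*np.diff(seg.axis, axis=0).T).sum()
            for seg in baseline_network.segments.values()
        )
        assert m.flow_length_um.sum() == pytest.approx(oracle, rel=1e-12)

    def test_direct_anchor_endpoint_mode(self, bent_345):
        mid = summarize_segment(bent_345, direct_anchor="midpoint")
        end = summarize_segment(bent_345, direct_anchor="endpoint")
        # midpoint of the arc sits at (300, 50); endpoint at (300, 400)
        assert mid.direct_distance_from_orifice == pytest.approx(math.hypot(300, 50))
        assert end.direct_distance_from_orifice == pytest.approx(500.0)

    def test_median_aggregation_mode(self):
        seg = make_segment([(0, 0), (1000, 0)], outer=(200, 400, 190),
                           inner=(160, 170, 150))
        m = summarize_segment(seg, diam_agg="median")
        assert m.mean_outer_diam == pytest.approx(200.0)
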