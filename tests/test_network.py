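import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coromorph import (
    AxisConvention,
    CenterlinePoint,
    CoronaryNetwork,
    GeneratorConfig,
    StructuralError,
    ValidationError,
    VesselSegment,
    arc_length,
    direction_at,
    generate_network,
    read_network,
    write_network,
)
from coromorph.io import network_to_frame

from conftest import build_network, straight_segment


class TestPointInvariants:
    def test_rejects_nonpositive_outer(self):
        with pytest.raises(ValidationError):
            CenterlinePoint(0, 0, -5.0, 1.0)

    def test_rejects_inner_not_below_outer(self):
        with pytest.raises(ValidationError):
            CenterlinePoint(0, 0, 100.0, 100.0)
        with pytest.raises(ValidationError):
            CenterlinePoint(0, 0, 100.0, 0.0)

    def test_rejects_nonfinite_coordinates(self):
        with pytest.raises(ValidationError):
            CenterlinePoint(float("nan"), 0, 100.0, 80.0)

    def test_axis_convention_must_be_orthonormal(self):
        AxisConvention()  # default frame is valid
        with pytest.raises(ValidationError):
            AxisConvention(x_axis=(1.0, 1.0))


class TestStructure:
    def test_segment_needs_two_distinct_points(self):
        p = CenterlinePoint(0, 0, 100, 80)
        with pytest.raises(ValidationError):
            VesselSegment("1", None, [p])
        with pytest.raises(ValidationError):
            VesselSegment("1", None, [p, CenterlinePoint(0, 0, 100, 80)])

    def test_orphan_parent_is_structural_error(self, two_segment_network):
        net = two_segment_network
        bad = straight_segment("3", "99", start=(500.0, 0.0),
                               direction=(0, 1), length=200.0)
        net.segments["3"] = bad
        with pytest.raises(StructuralError, match="3"):
            net.validate()

    def test_cycle_is_structural_error(self):
        root = straight_segment("1", None, length=500.0)
        a = straight_segment("2", "3", start=(500.0, 0.0), direction=(0, 1),
                             length=200.0)
        b = straight_segment("3", "2", start=(500.0, 0.0), direction=(0, -1),
                             length=200.0)
        with pytest.raises(StructuralError, match="cycle"):
            build_network(root, a, b).validate()

    def test_detached_child_fails_attachment_tolerance(self):
        root = straight_segment("1", None, length=500.0)
        far = straight_segment("2", "1", start=(480.0, 50.0), direction=(0, 1),
                               length=200.0)
        with pytest.raises(StructuralError, match="tolerance"):
            build_network(root, far).validate()

    def test_tree_property_on_generated_network(self):
        net = generate_network(GeneratorConfig(seed=4))
        n_links = sum(1 for s in net.segments.values() if s.parent_id is not None)
        assert len(net.segments) == n_links + 1
        visited = [s.segment_id for s in net.traverse()]
        assert sorted(visited) == sorted(net.segments)
        assert len(set(visited)) == len(visited)


class TestGeometry:
    def test_arc_length_straight(self):
        assert arc_length(straight_segment(length=500.0)) == pytest.approx(500.0)

    def test_arc_length_right_angle(self):
        pts = [CenterlinePoint(0, 0, 100, 80), CenterlinePoint(300, 0, 100, 80),
               CenterlinePoint(300, 400, 100, 80)]
        assert arc_length(VesselSegment("1", None, pts)) == pytest.approx(700.0)

    def test_arc_length_matches_brute_force_sum(self):
        rng = np.random.default_rng(42)
        xy = np.cumsum(rng.normal(0, 30, size=(100, 2)), axis=0)
        pts = [CenterlinePoint(x, y, 100, 80) for x, y in xy]
        seg = VesselSegment("1", None, pts)
        expected = sum(
            math.hypot(xy[i + 1, 0] - xy[i, 0], xy[i + 1, 1] - xy[i, 1])
            for i in range(len(xy) - 1)
        )
        assert arc_length(seg) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("direction,expected", [
        ((1, 0), (1.0, 0.0)),
        ((0, 1), (0.0, 1.0)),
    ])
    def test_direction_straight(self, direction, expected):
        seg = straight_segment(direction=direction, length=400.0, n_points=5)
        for s in (0.0, 123.0, 400.0):
            assert direction_at(seg, s, window=50.0) == pytest.approx(expected)

    def test_direction_quarter_circle_tangent(self):
        # radius-1000 quarter circle; tangent at the midpoint is analytic
        theta = np.linspace(0, np.pi / 2, 200)
        pts = [CenterlinePoint(1000 * np.sin(t), 1000 * (1 - np.cos(t)), 100, 80)
               for t in theta]
        seg = VesselSegment("1", None, pts)
        mid = arc_length(seg) / 2.0
        u = direction_at(seg, mid, window=20.0)
        t_mid = np.pi / 4
        analytic = np.array([np.cos(t_mid), np.sin(t_mid)])
        angle_err = math.degrees(math.acos(np.clip(u @ analytic, -1, 1)))
        assert angle_err < 1.0

    def test_degenerate_window_raises(self):
        seg = straight_segment(length=400.0)
        with pytest.raises(ValidationError):
            direction_at(seg, 0.0, window=-1.0)


class TestIO:
    def test_round_trip_identity(self, two_segment_network, tmp_path):
        path = tmp_path / "net.csv"
        write_network(two_segment_network, path)
        again = read_network(path)
        assert again == two_segment_network

    def test_round_trip_generated_network(self, tmp_path):
        net = generate_network(GeneratorConfig(seed=9))
        path = tmp_path / "net.csv"
        write_network(net, path)
        assert read_network(path) == net

    def test_missing_parent_in_table_is_structural_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "segment_id,parent_id,point_index,x_um,y_um,outer_d_um,inner_d_um\n"
            "1,,0,0,0,300,240\n1,,1,500,0,300,240\n"
            "2,7,0,500,0,200,160\n2,7,1,500,300,200,160\n"
        )
        with pytest.raises(StructuralError, match="7"):
            read_network(path)

    def test_empty_network_refuses_to_write(self, tmp_path):
        with pytest.raises(ValidationError):
            write_network(CoronaryNetwork({}), tmp_path / "x.csv")

    def test_row_count_equals_total_points(self, tmp_path):
        net = generate_network(GeneratorConfig(seed=2))
        path = tmp_path / "net.csv"
        write_network(net, path)
        n_rows = sum(1 for _ in open(path)) - 1  # header
        assert n_rows == sum(len(s.points) for s in net.segments.values())

    def test_load_translates_orifice_to_origin(self, tmp_path):
        # same tree shifted away from the origin: normalization restores it
        root = straight_segment("1", None, start=(1000.0, -250.0), length=500.0)
        child = straight_segment("2", "1", start=(1500.0, -250.0),
                                 direction=(0, 1), length=200.0)
        shifted = build_network(root, child)
        path = tmp_path / "shifted.csv"
        write_network(shifted, path)
        net = read_network(path)
        assert (net.orifice.x, net.orifice.y) == (0.0, 0.0)
        # pairwise distances are translation-invariant
        orig = network_to_frame(shifted)[["x_um", "y_um"]].to_numpy()
        moved = network_to_frame(net)[["x_um", "y_um"]].to_numpy()
        d0 = np.linalg.norm(orig[None] - orig[:, None], axis=-1)
        d1 = np.linalg.norm(moved[None] - moved[:, None], axis=-1)
        assert np.allclose(d0, d1)


class TestSWC:
    def _write_swc(self, path, lines):
        path.write_text("# synthetic SWC fixture\n" + "\n".join(lines) + "\n")

    def test_wall_model_inner_diameter(self, tmp_path):
        # radius 200 um -> outer 400; inner = 400 - 2*(10 + 0.05*400) = 340
        path = tmp_path / "t.swc"
        self._write_swc(path, [
            "1 2 0 0 0 200 -1",
            "2 2 500 0 0 200 1",
            "3 2 1000 0 0 200 2",
        ])
        net = read_network(path, format="swc", wall_model=(10.0, 0.05))
        assert all(
            p.inner_d == pytest.approx(340.0)
            for seg in net.segments.values() for p in seg.points
        )

    def test_swc_requires_wall_model(self, tmp_path):
        path = tmp_path / "t.swc"
        self._write_swc(path, ["1 2 0 0 0 200 -1", "2 2 500 0 0 200 1"])
        with pytest.raises(ValidationError):
            read_network(path, format="swc")

    def test_swc_branching_becomes_segments(self, tmp_path):
        path = tmp_path / "y.swc"
        self._write_swc(path, [
            "1 2 0 0 0 200 -1",
            "2 2 500 0 0 200 1",
            "3 2 1000 0 0 180 2",
            "4 2 1400 300 0 120 3",
            "5 2 1400 -300 0 120 3",
        ])
        net = read_network(path, format="swc", wall_model=(10.0, 0.05))
        net.validate()
        assert len(net.segments) == 3
        root = net.root
        assert len(net.children_of(root.segment_id)) == 2
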