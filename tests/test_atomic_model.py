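import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxwire import generate_fixture, scale_mesh
from dxwire.atomic_model import (
    AtomicStructure,
    BezierSpan,
    Nucleotide,
    Strand,
    base_frame,
    build_atoms,
    detect_clashes,
    interpolate_ssdna,
    place_helices,
)
from dxwire.constants import CONSTANTS
from dxwire.errors import BoundsError
from dxwire.geometry_core import Mesh
from dxwire.templates import (
    HEAVY_ATOM_COUNTS,
    STRAND_II_FLIP,
    get_template,
)

from conftest import routed_design

vectors = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=3, max_size=3
).map(np.array)


class TestPlaceHelices:
    def test_interaxis_distance_constant(self, tetra_scaled):
        frames = place_helices(tetra_scaled)
        for ei in range(tetra_scaled.mesh.num_edges):
            d = np.linalg.norm(frames[(ei, 0)].origin - frames[(ei, 1)].origin)
            assert d == pytest.approx(CONSTANTS.interhelix_spacing, abs=1e-9)

    def test_axis_length_42bp(self, tetra_scaled):
        frames = place_helices(tetra_scaled)
        for (ei, h), frame in frames.items():
            length = frame.edge_bp * CONSTANTS.rise_per_bp
            assert round(length, 2) == 13.94

    def test_antiparallel_polarity(self, tetra_scaled):
        frames = place_helices(tetra_scaled)
        for ei in range(tetra_scaled.mesh.num_edges):
            assert frames[(ei, 0)].polarity == -frames[(ei, 1)].polarity
            np.testing.assert_allclose(frames[(ei, 0)].direction,
                                       frames[(ei, 1)].direction)

    def test_mirror_equivariance_of_origins(self):
        mesh = generate_fixture("asymmetric_octahedron", 63, seed=1)
        mirrored = Mesh(mesh.vertices * np.array([-1.0, 1.0, 1.0]),
                        [list(f) for f in mesh.faces])
        f1 = place_helices(scale_mesh(mesh, 63))
        f2 = place_helices(scale_mesh(mirrored, 63))
        origins_mirrored = np.array(
            [f1[k].origin * np.array([-1.0, 1.0, 1.0]) for k in sorted(f1)])
        origins_direct = np.array([f2[k].origin for k in sorted(f2)])
        # reflection flips which duplex sits on which side of each edge:
        # compare as per-edge unordered pairs
        for ei in range(mesh.num_edges):
            a = {tuple(np.round(origins_mirrored[2 * ei + h], 6)) for h in (0, 1)}
            b = {tuple(np.round(origins_direct[2 * ei + h], 6)) for h in (0, 1)}
            assert a == b

    def test_degenerate_edge_rejected(self):
        from dxwire.errors import GeometryError, MeshValidationError

        verts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        faces = [[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]]
        with pytest.raises((GeometryError, MeshValidationError)):
            scaled = scale_mesh(Mesh(verts, faces), 42)
            place_helices(scaled)


class TestBaseFrame:
    def test_index_zero_is_reference_twist(self, tetra_scaled):
        frame = place_helices(tetra_scaled)[(0, 0)]
        r0, o0 = base_frame(frame, 0)
        np.testing.assert_allclose(o0, frame.origin)
        np.testing.assert_allclose(r0[:, 0], frame.ref_x, atol=1e-12)

    def test_index_21_is_two_full_turns(self, tetra_scaled):
        frame = place_helices(tetra_scaled)[(0, 0)]
        r0, _ = base_frame(frame, 0)
        r21, o21 = base_frame(frame, 21)
        np.testing.assert_allclose(r21, r0, atol=1e-9)
        np.testing.assert_allclose(
            o21, frame.origin + 21 * CONSTANTS.rise_per_bp * frame.direction)

    def test_index_one_rotates_by_helical_twist(self, tetra_scaled):
        frame = place_helices(tetra_scaled)[(2, 1)]
        r0, _ = base_frame(frame, 0)
        r1, _ = base_frame(frame, 1)
        rel = r0.T @ r1
        angle = np.rad2deg(np.arccos((np.trace(rel) - 1) / 2))
        assert angle == pytest.approx(360.0 / 10.5, abs=1e-9)

    def test_out_of_range_rejected(self, tetra_scaled):
        frame = place_helices(tetra_scaled)[(0, 0)]
        with pytest.raises(BoundsError):
            base_frame(frame, 42)
        with pytest.raises(BoundsError):
            base_frame(frame, -1)


class TestBezier:
    def test_endpoints_exact(self):
        span = BezierSpan.from_tangents(np.zeros(3), np.array([3.0, 1.0, -2.0]),
                                        np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                                        n=5)
        ends = span.evaluate(np.array([0.0, 1.0]))
        np.testing.assert_array_equal(ends[0], span.p0)
        np.testing.assert_array_equal(ends[1], span.p3)

    def test_collinear_tangents_reduce_to_segment(self):
        p0, p3 = np.zeros(3), np.array([4.2, 0, 0])
        t = np.array([1.0, 0, 0])
        span = BezierSpan.from_tangents(p0, p3, t, t, n=9)
        anchors = interpolate_ssdna(span)
        expected = np.outer(np.arange(1, 10) / 10.0, p3)
        np.testing.assert_allclose(anchors, expected, atol=1e-12)

    def test_elbow_midpoint_closed_form(self):
        # symmetric 90-degree elbow, unit chord: B(1/2) = (P0+P3)/2
        # + (3/8) * h * (t_up - t_down) with h = |P3-P0|/3
        p0, p3 = np.zeros(3), np.array([1.0, 0, 0])
        t_up, t_down = np.array([0, 1.0, 0]), np.array([0, -1.0, 0])
        span = BezierSpan.from_tangents(p0, p3, t_up, t_down, n=1)
        mid = interpolate_ssdna(span)[0]
        expected = (p0 + p3) / 2 + (3 / 8) * (1 / 3) * (t_up - t_down)
        np.testing.assert_allclose(mid, expected, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(p0=vectors, p3=vectors, t=st.floats(0, 1))
    def test_matches_independent_bernstein_evaluation(self, p0, p3, t):
        span = BezierSpan.from_tangents(p0, p3, np.array([0, 0, 1.0]),
                                        np.array([1.0, 0, 0]), n=1)
        ours = span.evaluate(np.array([t]))[0]
        # independent oracle: explicit Bernstein basis polynomials
        b = [(1 - t) ** 3, 3 * t * (1 - t) ** 2, 3 * t ** 2 * (1 - t), t ** 3]
        oracle = (b[0] * span.p0 + b[1] * span.p1 + b[2] * span.p2 + b[3] * span.p3)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_anchors_monotone_and_in_control_hull(self):
        p0, p3 = np.zeros(3), np.array([10.0, 0, 0])
        span = BezierSpan.from_tangents(p0, p3, np.array([0, 1.0, 0]),
                                        np.array([0, -1.0, 0]), n=12)
        anchors = interpolate_ssdna(span)
        chord = (span.p3 - span.p0) / np.linalg.norm(span.p3 - span.p0)
        proj = anchors @ chord
        assert np.all(np.diff(proj) > 0)
        ctrl = np.stack([span.p0, span.p1, span.p2, span.p3])
        assert np.all(anchors >= ctrl.min(axis=0) - 1e-12)
        assert np.all(anchors <= ctrl.max(axis=0) + 1e-12)

    def test_degenerate_coincident_endpoints(self):
        p = np.array([1.0, 2.0, 3.0])
        span = BezierSpan.from_tangents(p, p, np.array([1.0, 0, 0]),
                                        np.array([1.0, 0, 0]), n=3)
        anchors = interpolate_ssdna(span)
        np.testing.assert_allclose(anchors, np.tile(p, (3, 1)))


def duplex_toy(n_bp: int = 12) -> AtomicStructure:
    """Straight B-form duplex built directly from the bundled templates."""
    rise, twist = 3.32, 360.0 / 10.5

    def rotz(deg):
        t = np.deg2rad(deg)
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    strand_i, strand_ii = [], []
    for i in range(n_bp):
        r = rotz(i * twist)
        shift = np.array([0, 0, i * rise])
        for strand, residue, flip in ((strand_i, "DA", np.eye(3)),
                                      (strand_ii, "DT", STRAND_II_FLIP)):
            tpl = get_template(residue)
            strand.append(Nucleotide(
                node_id=-1, residue=residue, atom_names=tpl.atom_names,
                elements=tpl.elements,
                coords=(r @ (flip @ tpl.coords.T)).T + shift,
                residence=("edge", 0, 0, i),
            ))
    return AtomicStructure(strands=[
        Strand(role="scaffold", nucleotides=strand_i),
        Strand(role="staple", nucleotides=list(reversed(strand_ii))),
    ])


class TestBuildAtoms:
    def test_strand_count(self, tetra_routed):
        structure = build_atoms(tetra_routed["route"], tetra_routed["staples"],
                                tetra_routed["frames"], tetra_routed["scaled"])
        assert len(structure.strands) == 1 + len(tetra_routed["staples"])

    def test_atom_count_matches_manifest(self, tetra_routed):
        structure = build_atoms(tetra_routed["route"], tetra_routed["staples"],
                                tetra_routed["frames"], tetra_routed["scaled"])
        expected = sum(HEAVY_ATOM_COUNTS[nt.residue]
                       for s in structure.strands for nt in s.nucleotides)
        assert structure.n_atoms == expected

    def test_pair_c1_distance_in_duplex_regions(self, tetra_routed):
        structure = build_atoms(tetra_routed["route"], tetra_routed["staples"],
                                tetra_routed["frames"], tetra_routed["scaled"])
        store = tetra_routed["route"].store
        scaffold = structure.strands[0]
        by_node = {}
        for s in structure.strands:
            for nt in s.nucleotides:
                by_node[nt.node_id] = nt
        checked = 0
        for nt in scaffold.nucleotides[:200]:
            node = store[nt.node_id]
            if node.paired is None:
                continue
            partner = by_node[node.paired]
            c1 = nt.coords[nt.atom_names.index("C1'")]
            c1p = partner.coords[partner.atom_names.index("C1'")]
            d = np.linalg.norm(c1 - c1p)
            assert abs(d - 10.85) <= 1.5
            checked += 1
        assert checked > 50

    def test_single_pair_transform_round_trip(self, tetra_scaled):
        frames = place_helices(tetra_scaled)
        frame = frames[(0, 0)]
        r, o = base_frame(frame, 17)
        tpl = get_template("DA")
        placed = (r @ tpl.coords.T).T + o * 10.0
        recovered = (r.T @ (placed - o * 10.0).T).T
        np.testing.assert_allclose(recovered, tpl.coords, atol=1e-10)

    def test_rigid_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31, -52, 117], degrees=True).as_matrix()
        base = routed_design("tetrahedron", 42, seed=6)
        mesh_r = Mesh(base["mesh"].vertices @ rot.T,
                      [list(f) for f in base["mesh"].faces])
        coords_a = build_atoms(base["route"], base["staples"], base["frames"],
                               base["scaled"]).all_coords()

        from dxwire import scale_mesh as _scale
        from dxwire.atomic_model import assign_edge_positions, place_unpaired_nodes
        from dxwire.routing import (
            ScaffoldSequence,
            assign_sequence,
            build_graph,
            insert_vertex_gaps,
            random_scaffold,
            route_scaffold,
            spanning_tree,
        )
        from dxwire.staples import generate_staples

        scaled = _scale(mesh_r, 42)
        graph = build_graph(scaled)
        tree = spanning_tree(graph)
        route = route_scaffold(graph, tree, scaled)
        frames = place_helices(scaled)
        assign_edge_positions(route.store, frames)
        insert_vertex_gaps(route, scaled)
        scaffold = ScaffoldSequence(
            name="random",
            sequence=random_scaffold(route.required_scaffold_nt, 6))
        assign_sequence(route, scaffold)
        place_unpaired_nodes(route, scaled, frames)
        staples = generate_staples(route, tree, scaled)
        coords_b = build_atoms(route, staples, frames, scaled).all_coords()

        assert coords_a.shape == coords_b.shape
        rmsd = np.sqrt(np.mean(np.sum((coords_a @ rot.T - coords_b) ** 2, axis=1)))
        assert rmsd < 1e-6


class TestDetectClashes:
    def test_duplex_toy_is_clean(self):
        report = detect_clashes(duplex_toy(), cutoff=2.0)
        assert report.n_clashes == 0

    def test_close_pair_reported_once(self):
        toy = duplex_toy(4)
        # shove a far nucleotide onto the first one (non-adjacent strands)
        toy.strands[1].nucleotides[0].coords = (
            toy.strands[0].nucleotides[0].coords + np.array([0.5, 0, 0]))
        report = detect_clashes(toy, cutoff=2.0)
        assert report.n_clashes > 0
        assert len({frozenset((a, b)) for a, b, _ in report.pairs}) == len(report.pairs)

    def test_adjacent_nucleotides_excluded(self):
        report = detect_clashes(duplex_toy(2), cutoff=2.0)
        assert report.n_clashes == 0

    def test_bad_cutoff_rejected(self):
        with pytest.raises(BoundsError):
            detect_clashes(duplex_toy(2), cutoff=0.0)

    def test_full_design_reports_only_vertex_region_interiors_clean(self, aso_design):
        resid = {}
        for si, s in enumerate(aso_design.structure.strands):
            for ri, nt in enumerate(s.nucleotides):
                resid[(si, ri)] = nt
        for a, b, _ in aso_design.clashes.pairs:
            ra = resid[(a[0], a[1])].residence
            rb = resid[(b[0], b[1])].residence
            if ra[0] != "edge" or rb[0] != "edge":
                continue  # single-stranded regions may clash (reported)
            if ra[1] == rb[1]:
                m = aso_design.scaled.edge_bp[ra[1]]
                near_end = (min(ra[3], m - 1 - ra[3]) < 12
                            or min(rb[3], m - 1 - rb[3]) < 12)
                assert near_end, (a, b)
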