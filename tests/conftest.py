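"""Shared fixtures.

Expensive end-to-end runs are session-scoped; everything else is built
fresh and small.  All inputs are generated programmatically.
"""

from __future__ import annotations

import numpy as np
import pytest

from dxwire import DesignConfig, generate_fixture, run_design, scale_mesh
from dxwire.atomic_model import assign_edge_positions, place_helices, place_unpaired_nodes
from dxwire.routing import (
    assign_sequence,
    build_graph,
    insert_vertex_gaps,
    random_scaffold,
    route_scaffold,
    spanning_tree,
)
from dxwire.routing import ScaffoldSequence
from dxwire.staples import generate_staples

ALL_FIXTURES = ("tetrahedron", "cube", "octahedron", "icosahedron",
                "pentagonal_bipyramid", "asymmetric_octahedron")


@pytest.fixture(scope="session")
def tetra_mesh():
    return generate_fixture("tetrahedron")


@pytest.fixture(scope="session")
def tetra_scaled(tetra_mesh):
    return scale_mesh(tetra_mesh, 42)


def routed_design(name: str, min_edge_bp: int, seed: int = 1,
                  sequence: bool = True):
    """Run the routing stages (no atoms, no files) and return a bundle."""
    mesh = generate_fixture(name, min_edge_bp, seed)
    scaled = scale_mesh(mesh, min_edge_bp)
    graph = build_graph(scaled)
    tree = spanning_tree(graph)
    route = route_scaffold(graph, tree, scaled)
    frames = place_helices(scaled)
    assign_edge_positions(route.store, frames)
    insert_vertex_gaps(route, scaled)
    staples = None
    if sequence:
        scaffold = ScaffoldSequence(
            name="random",
            sequence=random_scaffold(route.required_scaffold_nt, seed),
        )
        assign_sequence(route, scaffold)
        place_unpaired_nodes(route, scaled, frames)
        staples = generate_staples(route, tree, scaled)
        assign_edge_positions(route.store, frames)
    return {
        "mesh": mesh, "scaled": scaled, "graph": graph, "tree": tree,
        "route": route, "frames": frames, "staples": staples,
    }


@pytest.fixture(scope="session")
def tetra_routed():
    return routed_design("tetrahedron", 42)


@pytest.fixture(scope="session")
def aso_routed():
    return routed_design("asymmetric_octahedron", 63, seed=1)


@pytest.fixture(scope="session")
def tetra_design(tmp_path_factory):
    """Full pipeline on the tetrahedron with the automatic (M13) scaffold."""
    outdir = tmp_path_factory.mktemp("tetra_design")
    return run_design(DesignConfig(
        geometry="tetrahedron", min_edge_bp=42, seed=7, outdir=str(outdir),
    ))


@pytest.fixture(scope="session")
def aso_design(tmp_path_factory):
    """Full pipeline on the seeded asymmetric octahedron, random scaffold."""
    outdir = tmp_path_factory.mktemp("aso_design")
    return run_design(DesignConfig(
        geometry="asymmetric_octahedron", min_edge_bp=63, seed=1,
        scaffold="random", outdir=str(outdir),
    ))


def box_mesh(lx=1.0, ly=1.0, lz=1.0):
    """Axis-aligned closed box with quad faces (edge ratios under control)."""
    from dxwire.geometry_core import Mesh

    verts = np.array([[x, y, z]
                      for x in (0, lx) for y in (0, ly) for z in (0, lz)],
                     dtype=float)
    faces = [
        [0, 1, 3, 2], [4, 6, 7, 5], [0, 4, 5, 1],
        [2, 3, 7, 6], [0, 2, 6, 4], [1, 5, 7, 3],
    ]
    return Mesh(verts, faces)
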