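"""All-atom model construction from base-level nodes.

Helix axes are placed per edge, paired bases are posed by rigid transforms
of reference B-form templates, unpaired runs are interpolated with cubic
Bezier curves, and steric clashes are detected (not repaired - energy
minimization is downstream of this tool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import CONSTANTS, TWIST_PER_BP_DEG, DesignConstants
from .errors import BoundsError, GeometryError, TopologyError
from .geometry_core import ScaledMesh
from .routing import HELIX_FWD, HELIX_REV, SCAFFOLD, NodeStore, ScaffoldRoute
from .templates import RESIDUE_OF_BASE, STRAND_II_FLIP, get_template

__all__ = [
    "HelixFrame",
    "BezierSpan",
    "Nucleotide",
    "Strand",
    "AtomicStructure",
    "ClashReport",
    "place_helices",
    "base_frame",
    "assign_edge_positions",
    "place_unpaired_nodes",
    "interpolate_ssdna",
    "build_atoms",
    "detect_clashes",
]

NM_TO_ANG = 10.0

#: Twist register of the second duplex relative to the first.  At 2.25 nm
#: axis spacing the facing backbones of an in-phase pair interpenetrate;
#: this phase maximizes the inter-duplex atomic clearance (~2.6 A).
INTERDUPLEX_PHASE_DEG = 74.0


# ---------------------------------------------------------------------------
# Helix frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixFrame:
    """Geometric realization of one duplex of a DX edge.

    ``origin`` sits at the low-vertex end of the axis; ``direction`` is the
    unit vector toward the high vertex.  ``polarity`` is +1 when the
    scaffold strand of this duplex runs 5'->3' along ``direction`` and -1
    when against it.  ``ref_x`` seeds the twist reference (the pair-frame
    x-axis at index 0, before the twist offset).
    """

    edge: int
    helix: int
    origin: np.ndarray
    direction: np.ndarray
    ref_x: np.ndarray
    twist_offset_deg: float
    polarity: int
    edge_bp: int


def _rotation_about(axis: np.ndarray, deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis."""
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0.0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer(axis, axis)


def place_helices(scaled: ScaledMesh,
                  constants: DesignConstants = CONSTANTS) -> dict[tuple[int, int], HelixFrame]:
    """Two antiparallel axes per edge, split across the dihedral bisector.

    Each helix is pushed ``interhelix_spacing / 2`` toward its adjacent
    face, inside the plane bisecting the two incident faces, so the
    inter-axis distance is exactly ``interhelix_spacing``.
    """
    mesh = scaled.mesh
    verts = scaled.vertices_nm
    frames: dict[tuple[int, int], HelixFrame] = {}
    for ei, (a, b) in enumerate(mesh.edges):
        va, vb = verts[a], verts[b]
        axis_vec = vb - va
        length = np.linalg.norm(axis_vec)
        if length <= 0:
            raise GeometryError(f"edge {ei} has zero length")
        e_hat = axis_vec / length
        mid = 0.5 * (va + vb)

        f_left, f_right = mesh.edge_faces[ei]
        def lateral(fi: int) -> np.ndarray:
            c = mesh.face_centroid(fi) * scaled.scale_factor
            d = c - mid
            d = d - np.dot(d, e_hat) * e_hat
            n = np.linalg.norm(d)
            if n == 0:
                raise GeometryError(f"face {fi} centroid lies on edge {ei}")
            return d / n

        t_left = lateral(f_left)
        t_right = lateral(f_right)
        split = t_left - t_right
        n = np.linalg.norm(split)
        if n < 1e-9:
            raise GeometryError(f"incident faces of edge {ei} are coincident")
        d_hat = split / n

        m = scaled.edge_bp[ei]
        axis_len = m * constants.rise_per_bp
        start = mid - 0.5 * axis_len * e_hat
        half = 0.5 * constants.interhelix_spacing
        for h, sign, polarity, offset in (
            (HELIX_FWD, +1.0, +1, 0.0),
            (HELIX_REV, -1.0, -1, INTERDUPLEX_PHASE_DEG),
        ):
            frames[(ei, h)] = HelixFrame(
                edge=ei,
                helix=h,
                origin=start + sign * half * d_hat,
                direction=e_hat,
                ref_x=sign * d_hat,
                twist_offset_deg=offset,
                polarity=polarity,
                edge_bp=m,
            )
    return frames


def base_frame(frame: HelixFrame, index: int,
               constants: DesignConstants = CONSTANTS) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, origin_nm) of the pair frame at one axial index.

    Origin advances ``index * rise_per_bp`` along the axis; the twist is
    ``index * 360/bp_per_turn`` degrees (plus the helix offset), wound
    right-handed about the scaffold 5'->3' stacking direction.
    """
    if not 0 <= index < frame.edge_bp:
        raise BoundsError(f"base index {index} outside [0, {frame.edge_bp})")
    origin = frame.origin + index * constants.rise_per_bp * frame.direction
    z = frame.polarity * frame.direction
    x0 = frame.ref_x
    y0 = np.cross(z, x0)
    base = np.column_stack([x0, y0, z])
    # winding about the shared edge axis keeps both antiparallel duplexes
    # right-handed about their own 5'->3' stacking directions
    theta = index * (360.0 / constants.bp_per_turn) + frame.twist_offset_deg
    r = _rotation_about(frame.direction, theta) @ base
    return r, origin


def assign_edge_positions(store: NodeStore,
                          frames: dict[tuple[int, int], HelixFrame],
                          constants: DesignConstants = CONSTANTS) -> None:
    """Set every edge-resident node's position to its pair-frame origin (nm)."""
    for node in store.nodes.values():
        if node.residence and node.residence[0] == "edge":
            _, ei, h, phys = node.residence
            frame = frames[(ei, h)]
            node.position = frame.origin + phys * constants.rise_per_bp * frame.direction


# ---------------------------------------------------------------------------
# Single-stranded interpolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BezierSpan:
    """Cubic Bezier control points (nm) with n interior anchor nucleotides."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    n: int

    @classmethod
    def from_tangents(cls, p0, p3, tangent_up, tangent_down, n: int) -> "BezierSpan":
        """Handles of length |p3-p0|/3 along the flanking helix tangents."""
        p0 = np.asarray(p0, dtype=float)
        p3 = np.asarray(p3, dtype=float)
        chord = np.linalg.norm(p3 - p0)
        h = chord / 3.0
        return cls(
            p0=p0,
            p1=p0 + h * np.asarray(tangent_up, dtype=float),
            p2=p3 - h * np.asarray(tangent_down, dtype=float),
            p3=p3,
            n=int(n),
        )

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)[:, None]
        return ((1 - t) ** 3 * self.p0 + 3 * (1 - t) ** 2 * t * self.p1
                + 3 * (1 - t) * t ** 2 * self.p2 + t ** 3 * self.p3)


def interpolate_ssdna(span: BezierSpan) -> np.ndarray:
    """Anchor positions for the n unpaired nucleotides of a span.

    Nucleotide k (1..n) sits at B(k / (n+1)): uniform in curve parameter,
    strictly between the flanking paired bases.
    """
    if span.n < 1:
        return np.zeros((0, 3))
    t = np.arange(1, span.n + 1) / (span.n + 1)
    return span.evaluate(t)


def _travel_direction(node_residence: tuple,
                      frames: dict[tuple[int, int], HelixFrame]) -> np.ndarray:
    _, ei, h, _ = node_residence
    frame = frames[(ei, h)]
    return frame.polarity * frame.direction


def place_unpaired_nodes(route: ScaffoldRoute, scaled: ScaledMesh,
                         frames: dict[tuple[int, int], HelixFrame],
                         constants: DesignConstants = CONSTANTS) -> None:
    """Position vertex-gap nucleotides on Bezier spans and the excess loop
    (if any) on a coil anchored at the seam vertex."""
    store = route.store
    for tr in route.transitions:
        if not tr.unpaired:
            continue
        head = store[tr.head]
        tail = store[tr.tail]
        span = BezierSpan.from_tangents(
            head.position, tail.position,
            _travel_direction(head.residence, frames),
            _travel_direction(tail.residence, frames),
            len(tr.unpaired),
        )
        for nid, pos in zip(tr.unpaired, interpolate_ssdna(span)):
            store[nid].position = pos

    seam_nodes = [n for n in store.nodes.values()
                  if n.residence and n.residence[0] == "seam"]
    if seam_nodes:
        _place_seam_coil(route, scaled, seam_nodes, constants)


def _place_seam_coil(route: ScaffoldRoute, scaled: ScaledMesh, seam_nodes,
                     constants: DesignConstants) -> None:
    """Park the excess-scaffold loop on compact spherical shells.

    The loop is unstructured by design; it only needs deterministic,
    finite, reasonably packed coordinates.  Nodes fill golden-angle spirals
    on concentric shells centred outside the seam vertex along its outward
    normal, so the construction uses only mesh-derived vectors and is
    equivariant under rigid motions of the input.
    """
    mesh = scaled.mesh
    w = seam_nodes[0].residence[1]
    normal = np.zeros(3)
    for fi, face in enumerate(mesh.faces):
        if w in face:
            normal += mesh.face_normal(fi)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise GeometryError(f"cannot derive outward normal at vertex {w}")
    normal /= nn
    # local frame from the lowest-index edge at the vertex
    ei = min(i for i, e in enumerate(mesh.edges) if w in e)
    a, b = mesh.edges[ei]
    edge_dir = scaled.vertices_nm[b] - scaled.vertices_nm[a]
    u = _perpendicular(normal, edge_dir)
    v = np.cross(normal, u)
    frame = np.column_stack([u, v, normal])

    n = len(seam_nodes)
    spacing = 1.4                       # nm between anchors on a shell
    r0 = 4.0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ordered = sorted(seam_nodes, key=lambda nd: nd.id)
    k = 0
    shell = 0
    while k < n:
        radius = r0 + spacing * shell
        capacity = max(8, int(4 * np.pi * radius ** 2 / spacing ** 2))
        m = min(capacity, n - k)
        for i in range(m):
            z = 1.0 - 2.0 * (i + 0.5) / m
            rho = np.sqrt(max(0.0, 1.0 - z * z))
            phi = i * golden
            local = radius * np.array([rho * np.cos(phi), rho * np.sin(phi), z])
            ordered[k + i].position = (
                scaled.vertices_nm[w] + (r0 + 2.0) * normal + frame @ local
            )
        k += m
        shell += 1


# ---------------------------------------------------------------------------
# Atom building
# ---------------------------------------------------------------------------

@dataclass
class Nucleotide:
    node_id: int
    residue: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray              # (n, 3) Angstroms
    residence: tuple


@dataclass
class Strand:
    role: str                       # scaffold | staple
    nucleotides: list[Nucleotide]
    circular: bool = False

    @property
    def n_atoms(self) -> int:
        return sum(n.coords.shape[0] for n in self.nucleotides)


@dataclass
class AtomicStructure:
    strands: list[Strand]

    @property
    def n_atoms(self) -> int:
        return sum(s.n_atoms for s in self.strands)

    @property
    def n_residues(self) -> int:
        return sum(len(s.nucleotides) for s in self.strands)

    def all_coords(self) -> np.ndarray:
        return np.vstack([n.coords for s in self.strands for n in s.nucleotides])


def _perpendicular(z: np.ndarray, hint: np.ndarray) -> np.ndarray:
    x = np.cross(z, hint)
    n = np.linalg.norm(x)
    if n < 1e-9:
        # hint parallel to z: rotate the hint deterministically and retry
        x = np.cross(z, hint + np.array([0.0371, 0.0573, 0.0779]))
        n = np.linalg.norm(x)
    return x / n


def _unpaired_frame(store: NodeStore, node, mesh_centroid: np.ndarray) -> np.ndarray:
    prev = store[node.up].position if node.up is not None else node.position
    nxt = store[node.down].position if node.down is not None else node.position
    tangent = np.asarray(nxt) - np.asarray(prev)
    tn = np.linalg.norm(tangent)
    z = tangent / tn if tn > 1e-9 else np.array([0.0, 0.0, 1.0])
    radial = np.asarray(node.position) - mesh_centroid
    x = _perpendicular(z, radial)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def build_atoms(route: ScaffoldRoute, staples,
                frames: dict[tuple[int, int], HelixFrame],
                scaled: ScaledMesh,
                hydrogens: bool = False,
                constants: DesignConstants = CONSTANTS) -> AtomicStructure:
    """Reconstruct strands from base-node links and pose template atoms.

    The scaffold strand is walked from the seam; each staple from its 5'
    terminus.  Paired nucleotides take the pair frame of their duplex
    position (scaffold = strand I, staple = strand II); unpaired ones use
    a tangent frame at their interpolated anchor.  Coordinates are emitted
    in Angstroms.
    """
    store = route.store
    centroid = scaled.vertices_nm.mean(axis=0)

    def pose(node) -> Nucleotide:
        if node.base is None:
            raise TopologyError(f"node {node.id} has no assigned base letter")
        residue = RESIDUE_OF_BASE[node.base]
        tpl = get_template(residue, hydrogens=hydrogens)
        if node.residence and node.residence[0] == "edge":
            _, ei, h, phys = node.residence
            r, origin = base_frame(frames[(ei, h)], phys, constants)
            flip = np.eye(3) if node.role == SCAFFOLD else STRAND_II_FLIP
            coords = (r @ (flip @ tpl.coords.T)).T + origin * NM_TO_ANG
        else:
            if node.position is None:
                raise TopologyError(f"unpaired node {node.id} has no position")
            r = _unpaired_frame(store, node, centroid)
            coords = (r @ tpl.coords.T).T + np.asarray(node.position) * NM_TO_ANG
        return Nucleotide(
            node_id=node.id,
            residue=residue,
            atom_names=tpl.atom_names,
            elements=tpl.elements,
            coords=coords,
            residence=node.residence,
        )

    scaffold_nt = [pose(store[nid]) for nid in route.walk()]
    strands = [Strand(role=SCAFFOLD, nucleotides=scaffold_nt, circular=True)]

    for staple in staples:
        seen: set[int] = set()
        nts = []
        for nid in staple.node_ids:
            if nid in seen:
                raise TopologyError(f"staple {staple.id} revisits node {nid}")
            seen.add(nid)
            nts.append(pose(store[nid]))
        strands.append(Strand(role="staple", nucleotides=nts))
    return AtomicStructure(strands=strands)


# ---------------------------------------------------------------------------
# Clash detection
# ---------------------------------------------------------------------------

@dataclass
class ClashReport:
    cutoff: float
    pairs: list[tuple[tuple[int, int, str], tuple[int, int, str], float]]
    per_vertex: dict[int, int] = field(default_factory=dict)

    @property
    def n_clashes(self) -> int:
        return len(self.pairs)


def detect_clashes(structure: AtomicStructure, cutoff: float = 2.0) -> ClashReport:
    """All-pairs contacts below ``cutoff`` between non-bonded atoms.

    Pairs within one nucleotide are skipped, as are all pairs between
    backbone-adjacent nucleotides of the same strand (they are covalently
    linked and their junction geometry is deliberately not idealized here).
    Each offending pair is listed once, keyed
    ``(strand index, residue index, atom name)``.
    """
    if cutoff <= 0:
        raise BoundsError("cutoff must be positive")
    names: list[str] = []
    keys: list[tuple[int, int]] = []
    residences: list[tuple] = []
    coords_list = []
    for si, strand in enumerate(structure.strands):
        for ri, nt in enumerate(strand.nucleotides):
            coords_list.append(nt.coords)
            names.extend(nt.atom_names)
            keys.extend([(si, ri)] * nt.coords.shape[0])
            residences.extend([nt.residence] * nt.coords.shape[0])
    if not coords_list:
        return ClashReport(cutoff=cutoff, pairs=[])
    coords = np.vstack(coords_list)

    adjacency: set[frozenset[tuple[int, int]]] = set()
    for si, strand in enumerate(structure.strands):
        n = len(strand.nucleotides)
        for ri in range(n - 1):
            adjacency.add(frozenset({(si, ri), (si, ri + 1)}))
        if strand.circular and n > 1:
            adjacency.add(frozenset({(si, n - 1), (si, 0)}))

    tree = cKDTree(coords)
    report: list[tuple[tuple[int, int, str], tuple[int, int, str], float]] = []
    per_vertex: dict[int, int] = {}
    for i, j in sorted(tree.query_pairs(cutoff)):
        ki, kj = keys[i], keys[j]
        if ki == kj:
            continue
        if frozenset({ki, kj}) in adjacency:
            continue  # covalently linked neighbours

        dist = float(np.linalg.norm(coords[i] - coords[j]))
        report.append(((ki[0], ki[1], names[i]), (kj[0], kj[1], names[j]), dist))
        regions = {res[1] for res in (residences[i], residences[j])
                   if res and res[0] in ("vertex", "seam")}
        for region in regions:
            per_vertex[region] = per_vertex.get(region, 0) + 1
    return ClashReport(cutoff=cutoff, pairs=report, per_vertex=per_vertex)
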