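"""Scaffold routing for DX-edge wireframe designs.

Every mesh edge is realized as two antiparallel duplexes.  The scaffold
occupies one strand of each duplex and is routed as a single closed loop:
edges *off* the spanning tree receive a scaffold double crossover at their
midpoint (which merges the boundary loops of the two adjacent faces), while
tree edges are traversed crossover-free.  Because the non-tree edges of a
spanning tree of a closed genus-0 mesh form a spanning tree of the dual
graph, the merge sequence provably terminates in one loop; the invariant is
nevertheless re-checked at run time and a violation raises, never emits.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .constants import CONSTANTS, DesignConstants
from .errors import AlphabetError, RoutingError, ScaffoldLengthError
from .geometry_core import ScaledMesh

__all__ = [
    "BaseNode",
    "NodeStore",
    "DesignGraph",
    "SpanningTree",
    "ScaffoldRoute",
    "ScaffoldSequence",
    "build_graph",
    "spanning_tree",
    "route_scaffold",
    "insert_vertex_gaps",
    "select_scaffold",
    "assign_sequence",
    "load_bundled_scaffold",
]

SCAFFOLD = "scaffold"
STAPLE = "staple"


@dataclass
class BaseNode:
    """Per-nucleotide record: links, identity, and 3D position.

    ``residence`` is ``("edge", edge_id, helix, phys)`` for paired bases,
    ``("vertex", vertex_id)`` for unpaired vertex-gap bases and
    ``("seam", vertex_id)`` for excess-scaffold loop bases.
    """

    id: int
    role: str                       # SCAFFOLD or STAPLE
    base: str | None = None
    up: int | None = None           # 5' neighbour
    down: int | None = None         # 3' neighbour
    paired: int | None = None
    position: np.ndarray | None = None
    residence: tuple = ()


class NodeStore:
    """Id-indexed base-node collection shared across pipeline stages."""

    def __init__(self) -> None:
        self.nodes: dict[int, BaseNode] = {}
        self._next = 0

    def new(self, role: str, **kw) -> BaseNode:
        node = BaseNode(id=self._next, role=role, **kw)
        self.nodes[node.id] = node
        self._next += 1
        return node

    def __getitem__(self, nid: int) -> BaseNode:
        return self.nodes[nid]

    def __len__(self) -> int:
        return len(self.nodes)

    def link(self, a: int, b: int) -> None:
        """Make ``b`` the 3' (downstream) neighbour of ``a``."""
        self.nodes[a].down = b
        self.nodes[b].up = a

    def pair(self, a: int, b: int) -> None:
        if self.nodes[a].paired is not None or self.nodes[b].paired is not None:
            raise RoutingError(f"node {a} or {b} already paired")
        self.nodes[a].paired = b
        self.nodes[b].paired = a

    def check_symmetry(self) -> None:
        for node in self.nodes.values():
            if node.paired is not None and self.nodes[node.paired].paired != node.id:
                raise RoutingError(f"pairing not involutive at node {node.id}")
            if node.down is not None and self.nodes[node.down].up != node.id:
                raise RoutingError(f"up/down links not inverse at node {node.id}")


# ---------------------------------------------------------------------------
# Design graph
# ---------------------------------------------------------------------------

@dataclass
class DesignGraph:
    """Mesh combinatorics annotated for routing.

    ``corners`` maps ``(vertex, incoming_edge)`` to
    ``(face, outgoing_edge)`` following each face's winding through the
    vertex; its orbit at a vertex is the cyclic order of incident edges.
    """

    scaled: ScaledMesh
    corners: dict[tuple[int, int], tuple[int, int]]
    cyclic_order: dict[int, list[int]]

    @property
    def num_vertices(self) -> int:
        return self.scaled.mesh.num_vertices

    @property
    def num_edges(self) -> int:
        return self.scaled.mesh.num_edges


def build_graph(scaled: ScaledMesh) -> DesignGraph:
    """Derive corner maps and per-vertex cyclic edge order from face loops."""
    mesh = scaled.mesh
    corners: dict[tuple[int, int], tuple[int, int]] = {}
    for fi, face in enumerate(mesh.faces):
        k = len(face)
        for j, w in enumerate(face):
            p = face[(j - 1) % k]
            s = face[(j + 1) % k]
            e_in = mesh.edge_index[(min(p, w), max(p, w))]
            e_out = mesh.edge_index[(min(w, s), max(w, s))]
            corners[(w, e_in)] = (fi, e_out)

    cyclic: dict[int, list[int]] = {}
    for w in range(mesh.num_vertices):
        incident = [ei for (v, ei) in corners if v == w]
        if not incident:
            raise RoutingError(f"vertex {w} has no incident edges")
        start = min(incident)
        order = [start]
        while True:
            _, nxt = corners[(w, order[-1])]
            if nxt == start:
                break
            if len(order) > len(incident):
                raise RoutingError(f"corner fan at vertex {w} does not close")
            order.append(nxt)
        if len(order) != len(set(incident)):
            raise RoutingError(f"vertex {w} is non-manifold (split corner fan)")
        cyclic[w] = order

    # connectivity
    adj: dict[int, set[int]] = {}
    for a, b in mesh.edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj.get(stack.pop(), ()):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != mesh.num_vertices:
        raise RoutingError(
            f"design graph is disconnected ({len(seen)} of {mesh.num_vertices} "
            "vertices reachable)"
        )
    return DesignGraph(scaled=scaled, corners=corners, cyclic_order=cyclic)


@dataclass(frozen=True)
class SpanningTree:
    arcs: frozenset[int]            # edge ids in the tree
    root: int

    def __contains__(self, edge_id: int) -> bool:
        return edge_id in self.arcs


def spanning_tree(graph: DesignGraph) -> SpanningTree:
    """Deterministic Prim growth from vertex 0.

    Ties are broken by (edge_bp, far-vertex index, edge id), so repeated
    invocations return the identical tree.
    """
    mesh = graph.scaled.mesh
    bp = graph.scaled.edge_bp
    incident: dict[int, list[int]] = {}
    for ei, (a, b) in enumerate(mesh.edges):
        incident.setdefault(a, []).append(ei)
        incident.setdefault(b, []).append(ei)

    in_tree: set[int] = {0}
    arcs: set[int] = set()
    heap: list[tuple[int, int, int]] = []

    def push_frontier(v: int) -> None:
        for ei in incident[v]:
            a, b = mesh.edges[ei]
            far = b if a == v else a
            if far not in in_tree:
                heapq.heappush(heap, (bp[ei], far, ei))

    push_frontier(0)
    while len(in_tree) < mesh.num_vertices:
        if not heap:
            raise RoutingError("graph is disconnected; no spanning tree exists")
        _, far, ei = heapq.heappop(heap)
        if far in in_tree:
            continue
        in_tree.add(far)
        arcs.add(ei)
        push_frontier(far)
    return SpanningTree(arcs=frozenset(arcs), root=0)


# ---------------------------------------------------------------------------
# Scaffold route
# ---------------------------------------------------------------------------

@dataclass
class VertexTransition:
    """Record of one vertex passage: the joined edge ends and gap bases."""

    vertex: int
    face: int
    edge_in: int
    edge_out: int
    head: int                       # last paired node before the vertex
    tail: int                       # first paired node after the vertex
    unpaired: list[int] = field(default_factory=list)


@dataclass
class ScaffoldRoute:
    store: NodeStore
    start: int                                    # seam node id
    node_at: dict[tuple[int, int, int], int]      # (edge, helix, phys) -> id
    transitions: list[VertexTransition]
    crossover_edges: frozenset[int]               # non-tree edges
    total_paired_nt: int
    total_unpaired_nt: int = 0
    excess_nt: int = 0

    @property
    def required_scaffold_nt(self) -> int:
        return self.total_paired_nt + self.total_unpaired_nt

    def walk(self, start: int | None = None):
        """Yield node ids following downstream links once around the loop."""
        first = self.start if start is None else start
        nid = first
        for _ in range(len(self.store) + 1):
            yield nid
            nid = self.store[nid].down
            if nid is None:
                raise RoutingError("scaffold walk fell off a broken link")
            if nid == first:
                return
        raise RoutingError("scaffold walk did not close")

    def cycle_length(self) -> int:
        return sum(1 for _ in self.walk())


# helix index 0 runs low->high vertex (adjacent to the face traversing the
# edge in that direction); helix 1 is antiparallel.
HELIX_FWD = 0
HELIX_REV = 1


def _edge_end_nodes(node_at, ei: int, m: int, endpoint_is_low: bool):
    """(head, tail) node ids of edge ``ei`` at one endpoint.

    head = last scaffold base before leaving into the vertex;
    tail = first scaffold base when entering the edge from the vertex.
    """
    if endpoint_is_low:
        tail = node_at[(ei, HELIX_FWD, 0)]
        head = node_at[(ei, HELIX_REV, 0)]
    else:
        tail = node_at[(ei, HELIX_REV, m - 1)]
        head = node_at[(ei, HELIX_FWD, m - 1)]
    return head, tail


def route_scaffold(graph: DesignGraph, tree: SpanningTree,
                   scaled: ScaledMesh) -> ScaffoldRoute:
    """Emit scaffold base nodes and close them into a single loop.

    Raises :class:`RoutingError` if the construction does not yield exactly
    one cycle covering every duplex position (it always should; the check is
    enforced, not trusted).
    """
    mesh = scaled.mesh
    store = NodeStore()
    node_at: dict[tuple[int, int, int], int] = {}

    for ei, m in enumerate(scaled.edge_bp):
        for h in (HELIX_FWD, HELIX_REV):
            for phys in range(m):
                node = store.new(SCAFFOLD, residence=("edge", ei, h, phys))
                node_at[(ei, h, phys)] = node.id

    # intra-edge wiring
    for ei, m in enumerate(scaled.edge_bp):
        fwd = [node_at[(ei, HELIX_FWD, p)] for p in range(m)]
        rev = [node_at[(ei, HELIX_REV, p)] for p in range(m)]
        if ei in tree:
            for p in range(m - 1):
                store.link(fwd[p], fwd[p + 1])
                store.link(rev[p + 1], rev[p])
        else:
            k = m // 2
            # low-vertex side: fwd 0..k-1, cross, rev k-1..0
            for p in range(k - 1):
                store.link(fwd[p], fwd[p + 1])
                store.link(rev[p + 1], rev[p])
            store.link(fwd[k - 1], rev[k - 1])
            # high-vertex side: rev m-1..k, cross, fwd k..m-1
            for p in range(k, m - 1):
                store.link(rev[p + 1], rev[p])
                store.link(fwd[p], fwd[p + 1])
            store.link(rev[k], fwd[k])

    # vertex joins follow each face's winding through its corners
    transitions: list[VertexTransition] = []
    for fi, face in enumerate(mesh.faces):
        k = len(face)
        for j, w in enumerate(face):
            p = face[(j - 1) % k]
            s = face[(j + 1) % k]
            e_in = mesh.edge_index[(min(p, w), max(p, w))]
            e_out = mesh.edge_index[(min(w, s), max(w, s))]
            head, _ = _edge_end_nodes(node_at, e_in, scaled.edge_bp[e_in],
                                      endpoint_is_low=(w == min(p, w)))
            _, tail = _edge_end_nodes(node_at, e_out, scaled.edge_bp[e_out],
                                      endpoint_is_low=(w == min(w, s)))
            store.link(head, tail)
            transitions.append(VertexTransition(
                vertex=w, face=fi, edge_in=e_in, edge_out=e_out,
                head=head, tail=tail,
            ))

    total_paired = 2 * scaled.total_bp()
    route = ScaffoldRoute(
        store=store,
        start=node_at[(0, HELIX_FWD, 0)],
        node_at=node_at,
        transitions=transitions,
        crossover_edges=frozenset(range(mesh.num_edges)) - tree.arcs,
        total_paired_nt=total_paired,
    )
    store.check_symmetry()
    if route.cycle_length() != total_paired:
        raise RoutingError(
            f"scaffold did not close into a single loop covering all "
            f"{total_paired} paired bases"
        )
    return route


def insert_vertex_gaps(route: ScaffoldRoute, scaled: ScaledMesh,
                       constants: DesignConstants = CONSTANTS) -> ScaffoldRoute:
    """Insert unpaired scaffold bases at every vertex transition.

    The gap between the 3' end of the incoming duplex and the 5' start of
    the outgoing duplex is measured from the already-placed node positions;
    ``round(gap / ssdna_len_per_nt)`` unpaired nucleotides are spliced in.
    """
    store = route.store
    added = 0
    for tr in route.transitions:
        head = store[tr.head]
        tail = store[tr.tail]
        if head.position is None or tail.position is None:
            raise RoutingError(
                "helix positions must be assigned before inserting vertex gaps"
            )
        gap = float(np.linalg.norm(tail.position - head.position))
        n = int(round(gap / constants.ssdna_len_per_nt))
        prev = tr.head
        for _ in range(n):
            node = store.new(SCAFFOLD, residence=("vertex", tr.vertex))
            store.link(prev, node.id)
            prev = node.id
            tr.unpaired.append(node.id)
        store.link(prev, tr.tail)
        added += n
    route.total_unpaired_nt = added
    if route.cycle_length() != route.required_scaffold_nt:
        raise RoutingError("vertex-gap insertion broke the scaffold loop")
    return route


# ---------------------------------------------------------------------------
# Scaffold sequence selection
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldSequence:
    name: str                       # M13mp18 | Lambda | random | user
    sequence: str
    circular: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


def _validate_alphabet(seq: str, what: str) -> str:
    seq = seq.strip().upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"{what} contains non-ACGT letters: {sorted(bad)}")
    return seq


def load_bundled_scaffold(name: str) -> str:
    """Read a bundled scaffold sequence (plain text, one sequence)."""
    from importlib.resources import files

    fname = {"M13mp18": "m13mp18.txt", "Lambda": "lambda_phage.txt"}[name]
    raw = files("dxwire.data").joinpath(fname).read_text()
    seq = "".join(ln.strip() for ln in raw.splitlines() if not ln.startswith(("#", ">")))
    return _validate_alphabet(seq, name)


def random_scaffold(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def select_scaffold(required_nt: int, user_seq: str | None = None,
                    seed: int = 0,
                    constants: DesignConstants = CONSTANTS) -> ScaffoldSequence:
    """Pick a scaffold for the required length.

    M13mp18 up to 7,249 nt, Lambda up to 48,502 nt, seeded random above
    that.  A user sequence always overrides the automatic choice and must
    be long enough.  Required lengths of exactly 7,250 and 48,503 nt fall
    in documented gaps of the published rule; they resolve to Lambda and
    random respectively (closing each gap downward).
    """
    if required_nt < 1:
        raise ScaffoldLengthError(f"required_nt must be >= 1, got {required_nt}")
    if user_seq is not None:
        seq = _validate_alphabet(user_seq, "user scaffold")
        if len(seq) < required_nt:
            raise ScaffoldLengthError(
                f"user scaffold is {len(seq)} nt but the design requires {required_nt} nt"
            )
        return ScaffoldSequence(name="user", sequence=seq)
    if required_nt <= constants.m13_len:
        return ScaffoldSequence(name="M13mp18", sequence=load_bundled_scaffold("M13mp18"))
    if required_nt <= constants.lambda_len:
        return ScaffoldSequence(name="Lambda", sequence=load_bundled_scaffold("Lambda"))
    return ScaffoldSequence(name="random",
                            sequence=random_scaffold(required_nt, seed))


def assign_sequence(route: ScaffoldRoute, scaffold: ScaffoldSequence,
                    start_vertex: int | None = None) -> int:
    """Write scaffold letters onto route nodes in downstream order.

    The seam (sequence start) is the first node of the lowest-index edge
    unless ``start_vertex`` names a vertex, in which case the route node
    entering its lowest-index incident edge is used.  Excess scaffold is
    kept as a single unpaired loop spliced in at the seam.  Returns the
    excess length.
    """
    if scaffold.length < route.required_scaffold_nt:
        raise ScaffoldLengthError(
            f"scaffold {scaffold.name} is {scaffold.length} nt; design requires "
            f"{route.required_scaffold_nt} nt"
        )
    store = route.store
    start = route.start
    if start_vertex is not None:
        best = None
        for tr in route.transitions:
            if tr.vertex == start_vertex:
                if best is None or tr.edge_out < best[0]:
                    best = (tr.edge_out, tr.tail)
        if best is None:
            raise RoutingError(f"start vertex {start_vertex} not on the route")
        start = best[1]

    excess = scaffold.length - route.required_scaffold_nt
    if excess > 0:
        seam_vertex = _seam_vertex(route, start)
        prev = store[start].up
        for _ in range(excess):
            node = store.new(SCAFFOLD, residence=("seam", seam_vertex))
            store.link(prev, node.id)
            prev = node.id
        store.link(prev, start)
    route.excess_nt = excess
    route.start = start

    for letter, nid in zip(scaffold.sequence, route.walk(start)):
        store[nid].base = letter
    return excess


def _seam_vertex(route: ScaffoldRoute, start: int) -> int:
    """Vertex anchoring the excess loop: the transition feeding the seam."""
    for tr in route.transitions:
        if tr.tail == start:
            return tr.vertex
    return 0
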