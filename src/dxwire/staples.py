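"""Staple strand generation for DX edges.

Partition rules (declared parameterization of the standard DX-wireframe
motif): per duplex, the terminal 10 bp at the low-vertex end and 11 bp at
the high-vertex end belong to vertex staples, which cross their vertex to
the adjacent edge following the same face sector as the scaffold (in the
opposite direction).  The interior is tiled by edge staples that cover
matching windows on both duplexes of the edge with one antiparallel
crossover each; interior windows target 21 bp (two helical turns), and
remainders widen the window sizes rather than the crossover spacing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import COMPLEMENT
from .errors import StapleDesignError
from .geometry_core import ScaledMesh
from .routing import (
    HELIX_FWD,
    HELIX_REV,
    STAPLE,
    ScaffoldRoute,
    SpanningTree,
)

__all__ = [
    "Staple",
    "StapleSet",
    "generate_staples",
    "staple_statistics",
    "VERTEX_DOMAIN_LOW",
    "VERTEX_DOMAIN_HIGH",
    "CROSSOVER_SPACING",
    "STAPLE_LEN_MIN",
    "STAPLE_LEN_MAX",
    "interior_window_sizes",
]

VERTEX_DOMAIN_LOW = 10      # nt claimed by a vertex staple at the low-vertex end
VERTEX_DOMAIN_HIGH = 11     # nt claimed at the high-vertex end
CROSSOVER_SPACING = 21      # target bp between interior staple crossovers
STAPLE_LEN_MIN = 20
STAPLE_LEN_MAX = 60

#: display palette (caDNAno-style), cycled deterministically
PALETTE = (
    "#b8056f", "#0066cc", "#cc0000", "#f74308", "#f7931e", "#aaaa00",
    "#57bb00", "#007200", "#03b6a2", "#1700de", "#7300de", "#888888",
)


@dataclass
class Staple:
    id: int
    node_ids: list[int]             # 5' -> 3'
    sequence: str
    cls: str                        # "edge" | "vertex"
    residence: tuple                # ("edge", ei) or ("vertex", vi)
    color: str

    @property
    def length(self) -> int:
        return len(self.node_ids)


@dataclass
class StapleSet:
    staples: list[Staple]
    nicks: list[tuple[int, int, int]] = field(default_factory=list)       # (edge, helix, phys) of each 5' end
    crossovers: list[tuple[int, int]] = field(default_factory=list)       # (edge, phys) of inter-duplex staple crossovers

    def __iter__(self):
        return iter(self.staples)

    def __len__(self) -> int:
        return len(self.staples)

    def total_nt(self) -> int:
        return sum(s.length for s in self.staples)


def interior_window_sizes(interior_len: int) -> list[int]:
    """Split an interior span into near-21 windows within [10, 30]."""
    lo = -(-interior_len // 30)                 # ceil
    hi = interior_len // 10
    if hi < 1 or lo > hi:
        raise StapleDesignError(f"interior span of {interior_len} bp cannot be tiled")
    n = min(max(int(round(interior_len / CROSSOVER_SPACING)), lo, 1), hi)
    base, rem = divmod(interior_len, n)
    return [base + 1] * rem + [base] * (n - rem)


def generate_staples(route: ScaffoldRoute, tree: SpanningTree,
                     scaled: ScaledMesh) -> StapleSet:
    """Create staple base nodes, tile all paired scaffold bases, and
    assign Watson-Crick complementary sequences.

    Deterministic: edges are processed in index order and vertex staples in
    route-transition order.
    """
    store = route.store
    node_at = route.node_at
    staple_node: dict[tuple[int, int, int], int] = {}

    # one staple node opposite every paired scaffold node
    for (ei, h, phys), scaffold_id in sorted(node_at.items()):
        node = store.new(STAPLE, residence=("edge", ei, h, phys))
        store.pair(node.id, scaffold_id)
        staple_node[(ei, h, phys)] = node.id

    staples: list[Staple] = []
    nicks: list[tuple[int, int, int]] = []
    crossovers: list[tuple[int, int]] = []

    def finish(node_ids: list[int], cls: str, residence: tuple) -> None:
        for a, b in zip(node_ids, node_ids[1:]):
            store.link(a, b)
        seq = []
        for nid in node_ids:
            scaffold_base = store[store[nid].paired].base
            if scaffold_base is None:
                raise StapleDesignError("scaffold sequence must be assigned first")
            letter = COMPLEMENT[scaffold_base]
            store[nid].base = letter
            seq.append(letter)
        sid = len(staples)
        staples.append(Staple(
            id=sid,
            node_ids=node_ids,
            sequence="".join(seq),
            cls=cls,
            residence=residence,
            color=PALETTE[sid % len(PALETTE)],
        ))
        res = store[node_ids[0]].residence
        nicks.append((res[1], res[2], res[3]))

    # --- edge (interior) staples -----------------------------------------
    for ei, m in enumerate(scaled.edge_bp):
        interior = m - VERTEX_DOMAIN_LOW - VERTEX_DOMAIN_HIGH
        if interior < 10:
            raise StapleDesignError(
                f"edge {ei} ({m} bp) too short for vertex domains plus a "
                f"minimum 10-bp interior window"
            )
        p = VERTEX_DOMAIN_LOW
        for width in interior_window_sizes(interior):
            q = p + width
            path = [staple_node[(ei, HELIX_FWD, phys)] for phys in range(q - 1, p - 1, -1)]
            path += [staple_node[(ei, HELIX_REV, phys)] for phys in range(p, q)]
            finish(path, "edge", ("edge", ei))
            crossovers.append((ei, p))
            p = q

    # --- vertex staples ---------------------------------------------------
    # One staple per face corner: it runs along the scaffold-tail duplex of
    # the outgoing edge toward the vertex, crosses the vertex, and leaves
    # along the scaffold-head duplex of the incoming edge.
    mesh = scaled.mesh
    for tr in route.transitions:
        w = tr.vertex
        # arriving segment: duplex holding the scaffold tail of edge_out
        eo, mo = tr.edge_out, scaled.edge_bp[tr.edge_out]
        if w == min(mesh.edges[eo]):
            arrive = [staple_node[(eo, HELIX_FWD, phys)]
                      for phys in range(VERTEX_DOMAIN_LOW - 1, -1, -1)]
        else:
            arrive = [staple_node[(eo, HELIX_REV, phys)]
                      for phys in range(mo - VERTEX_DOMAIN_HIGH, mo)]
        # departing segment: duplex holding the scaffold head of edge_in
        en, mn = tr.edge_in, scaled.edge_bp[tr.edge_in]
        if w == min(mesh.edges[en]):
            depart = [staple_node[(en, HELIX_REV, phys)]
                      for phys in range(0, VERTEX_DOMAIN_LOW)]
        else:
            depart = [staple_node[(en, HELIX_FWD, phys)]
                      for phys in range(mn - 1, mn - VERTEX_DOMAIN_HIGH - 1, -1)]
        finish(arrive + depart, "vertex", ("vertex", w))

    staple_set = StapleSet(staples=staples, nicks=nicks, crossovers=crossovers)
    _check_invariants(staple_set, route)
    return staple_set


def _check_invariants(staple_set: StapleSet, route: ScaffoldRoute) -> None:
    store = route.store
    covered: set[int] = set()
    for staple in staple_set:
        if not STAPLE_LEN_MIN <= staple.length <= STAPLE_LEN_MAX:
            raise StapleDesignError(
                f"staple {staple.id} length {staple.length} outside "
                f"[{STAPLE_LEN_MIN}, {STAPLE_LEN_MAX}]"
            )
        for nid in staple.node_ids:
            if nid in covered:
                raise StapleDesignError(f"staple base {nid} used twice")
            covered.add(nid)
    n_scaffold_paired = sum(
        1 for n in store.nodes.values()
        if n.role != STAPLE and n.paired is not None
    )
    if len(covered) != n_scaffold_paired or len(covered) != route.total_paired_nt:
        raise StapleDesignError(
            f"staples cover {len(covered)} bases; expected {route.total_paired_nt}"
        )


def staple_statistics(staple_set: StapleSet) -> dict:
    """Per-staple rows plus totals (lengths, class, residence, GC fraction)."""
    rows = []
    for s in staple_set:
        gc = sum(1 for b in s.sequence if b in "GC") / len(s.sequence)
        rows.append({
            "staple_id": s.id,
            "class": s.cls,
            "residence": f"{s.residence[0]}:{s.residence[1]}",
            "length_nt": s.length,
            "gc_fraction": round(gc, 4),
            "sequence_5to3": s.sequence,
        })
    total_nt = sum(r["length_nt"] for r in rows)
    return {
        "staples": rows,
        "totals": {
            "count": len(rows),
            "total_nt": total_nt,
            "mean_length": total_nt / len(rows) if rows else 0.0,
            "min_length": min((r["length_nt"] for r in rows), default=0),
            "max_length": max((r["length_nt"] for r in rows), default=0),
        },
    }
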