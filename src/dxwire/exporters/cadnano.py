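"""caDNAno JSON export.

Each duplex of a DX edge maps to one virtual helix on a honeycomb index
grid: the forward duplex of edge ``i`` becomes helix ``2i`` (even: scaffold
5'->3' left-to-right) and the antiparallel duplex helix ``2i+1``, placed at
grid rows 0/1 and column ``2i`` so helix-number parity matches grid parity.
Scaffold and staple paths are stored in the 4-tuple linked-list convention;
unpaired scaffold runs (vertex gaps, excess loop) become loop insertions on
the last paired base before the run.  The edge <-> helix cross-section map
is emitted as a sidecar CSV.
"""

from __future__ import annotations

import csv
import json

from ..geometry_core import ScaledMesh
from ..routing import HELIX_FWD, ScaffoldRoute
from ..staples import StapleSet

__all__ = ["write_cadnano", "read_cadnano", "GRID_PADDING"]

GRID_PADDING = 21       # leading empty positions; total width padded to x21


def _layout(scaled: ScaledMesh):
    width = GRID_PADDING + max(scaled.edge_bp) + 1
    width = -(-width // 21) * 21
    return width


def _position_of(residence: tuple) -> tuple[int, int]:
    _, ei, h, phys = residence
    helix_num = 2 * ei + (0 if h == HELIX_FWD else 1)
    return helix_num, GRID_PADDING + phys


def write_cadnano(scaled: ScaledMesh, route: ScaffoldRoute, staple_set: StapleSet,
                  path, xsection_path=None, name: str = "dxwire design") -> dict:
    """Write the caDNAno document; returns the document dict."""
    store = route.store
    width = _layout(scaled)
    empty = [-1, -1, -1, -1]

    helices = []
    index_of_num = {}
    for ei in range(scaled.mesh.num_edges):
        for k in range(2):
            num = 2 * ei + k
            index_of_num[num] = len(helices)
            helices.append({
                "row": k,
                "col": 2 * ei,
                "num": num,
                "scaf": [list(empty) for _ in range(width)],
                "stap": [list(empty) for _ in range(width)],
                "loop": [0] * width,
                "skip": [0] * width,
                "scafLoop": [],
                "stapLoop": [],
                "stap_colors": [],
            })

    def cell(kind: str, helix_num: int, pos: int):
        return helices[index_of_num[helix_num]][kind][pos]

    # scaffold: walk the closed route, skipping unpaired nodes into loops
    order = list(route.walk())
    paired = [(nid, store[nid].residence) for nid in order
              if store[nid].residence and store[nid].residence[0] == "edge"]
    n = len(paired)
    # unpaired run following each paired node
    idx_in_order = {nid: i for i, nid in enumerate(order)}
    for i, (nid, res) in enumerate(paired):
        nxt_nid, nxt_res = paired[(i + 1) % n]
        h_here, p_here = _position_of(res)
        h_next, p_next = _position_of(nxt_res)
        cell("scaf", h_here, p_here)[2:4] = [h_next, p_next]
        cell("scaf", h_next, p_next)[0:2] = [h_here, p_here]
        run = (idx_in_order[nxt_nid] - idx_in_order[nid]) % len(order) - 1
        if run:
            helices[index_of_num[h_here]]["loop"][p_here] += run

    # staples
    for staple in staple_set:
        locs = [_position_of(store[nid].residence) for nid in staple.node_ids]
        for (h0, p0), (h1, p1) in zip(locs, locs[1:]):
            cell("stap", h0, p0)[2:4] = [h1, p1]
            cell("stap", h1, p1)[0:2] = [h0, p0]
        h5, p5 = locs[0]
        helices[index_of_num[h5]]["stap_colors"].append(
            [p5, int(staple.color.lstrip("#"), 16)]
        )
    for h in helices:
        h["stap_colors"].sort()

    doc = {"name": name, "vstrands": helices}
    with open(path, "w") as fh:
        json.dump(doc, fh)

    if xsection_path is not None:
        with open(xsection_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["edge_id", "vertex_low", "vertex_high",
                             "helix_fwd", "helix_rev", "edge_bp"])
            for ei, (a, b) in enumerate(scaled.mesh.edges):
                writer.writerow([ei, a, b, 2 * ei, 2 * ei + 1, scaled.edge_bp[ei]])
    return doc


def read_cadnano(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
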