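"""Routing-model and pseudo-atomic-model exports (JSON).

The routing model approximates every strand by its ordered base positions
(a polyline per strand); the pseudo-atomic model records one sphere per
nucleotide with its base letter and display colour.  Both are plain JSON
for consumption by external viewers or notebooks.
"""

from __future__ import annotations

import json

from ..routing import ScaffoldRoute
from ..staples import StapleSet

__all__ = ["write_routing_model", "write_pseudo_atomic_model"]

SCAFFOLD_COLOR = "#2c6fbb"


def _points(store, node_ids) -> list[list[float]]:
    pts = []
    for nid in node_ids:
        p = store[nid].position
        pts.append([round(float(x), 4) for x in p])
    return pts


def write_routing_model(route: ScaffoldRoute, staple_set: StapleSet, path,
                        provenance: dict | None = None) -> dict:
    store = route.store
    doc = {
        "provenance": provenance or {},
        "scaffold": {
            "color": SCAFFOLD_COLOR,
            "closed": True,
            "points": _points(store, route.walk()),
        },
        "staples": [
            {"id": s.id, "color": s.color, "points": _points(store, s.node_ids)}
            for s in staple_set
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return doc


def write_pseudo_atomic_model(route: ScaffoldRoute, staple_set: StapleSet, path,
                              provenance: dict | None = None) -> dict:
    store = route.store

    def residues(node_ids, color):
        out = []
        for nid in node_ids:
            node = store[nid]
            out.append({
                "base": node.base,
                "paired": node.paired is not None,
                "position": [round(float(x), 4) for x in node.position],
                "color": color,
            })
        return out

    doc = {
        "provenance": provenance or {},
        "strands": (
            [{"role": "scaffold", "residues": residues(route.walk(), SCAFFOLD_COLOR)}]
            + [{"role": "staple", "id": s.id,
                "residues": residues(s.node_ids, s.color)} for s in staple_set]
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return doc
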