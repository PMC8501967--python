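"""End-to-end design pipeline: geometry -> routing -> staples -> atoms -> files."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .atomic_model import (
    assign_edge_positions,
    build_atoms,
    detect_clashes,
    place_helices,
    place_unpaired_nodes,
)
from .constants import CONSTANTS
from .errors import BoundsError, DesignError, ScaffoldLengthError
from .exporters import (
    write_cadnano,
    write_cylinder_model,
    write_pdb,
    write_pseudo_atomic_model,
    write_routing_model,
    write_staple_csv,
)
from .geometry_core import FIXTURE_NAMES, generate_fixture, read_ply, scale_mesh
from .routing import (
    ScaffoldSequence,
    assign_sequence,
    build_graph,
    insert_vertex_gaps,
    load_bundled_scaffold,
    random_scaffold,
    route_scaffold,
    select_scaffold,
    spanning_tree,
)
from .staples import generate_staples, staple_statistics

__all__ = ["DesignConfig", "DesignResult", "run_design", "ARTIFACTS", "validate_bundle"]

#: The six design artifacts, plus the summary, written by every run.
ARTIFACTS = {
    "cylinder_model": "cylinder_model.ply",
    "routing_model": "routing_model.json",
    "pseudo_atomic_model": "pseudo_atomic_model.json",
    "staples": "staples.csv",
    "cadnano": "cadnano.json",
    "pdb": "model.pdb",
}
SUMMARY_FILE = "design_summary.txt"
XSECTION_FILE = "cross_sections.csv"
STRAND_MAP_FILE = "strand_map.csv"

SCAFFOLD_CHOICES = ("auto", "m13", "lambda", "random")


@dataclass
class DesignConfig:
    geometry: str                   # fixture name or PLY path
    min_edge_bp: int = 42
    edge_type: str = "dx"
    scaffold: str = "auto"          # auto | m13 | lambda | random | file path
    seed: int = 0
    outdir: str = "design_out"
    plate_layout: bool = False
    hydrogens: bool = False
    multimodel: bool = False
    clash_cutoff: float = 2.0

    def validate(self) -> None:
        if not CONSTANTS.min_edge_bp_bound <= int(self.min_edge_bp) <= CONSTANTS.max_edge_bp_bound:
            raise BoundsError(
                f"min_edge_bp={self.min_edge_bp} outside "
                f"[{CONSTANTS.min_edge_bp_bound}, {CONSTANTS.max_edge_bp_bound}]"
            )
        if self.edge_type != "dx":
            raise BoundsError(
                f"edge_type={self.edge_type!r} unsupported (DX only; 6HB designers "
                "are an extension point)"
            )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class DesignResult:
    config: DesignConfig
    scaled: object
    graph: object
    tree: object
    route: object
    frames: dict
    scaffold: ScaffoldSequence
    staples: object
    structure: object
    clashes: object
    paths: dict[str, Path]
    summary: dict = field(default_factory=dict)


def _load_mesh(config: DesignConfig):
    if config.geometry in FIXTURE_NAMES:
        return generate_fixture(config.geometry, config.min_edge_bp, config.seed)
    return read_ply(config.geometry)


def _pick_scaffold(config: DesignConfig, required_nt: int) -> ScaffoldSequence:
    choice = config.scaffold
    if choice == "auto":
        return select_scaffold(required_nt, seed=config.seed)
    if choice == "m13":
        seq = ScaffoldSequence(name="M13mp18", sequence=load_bundled_scaffold("M13mp18"))
    elif choice == "lambda":
        seq = ScaffoldSequence(name="Lambda", sequence=load_bundled_scaffold("Lambda"))
    elif choice == "random":
        return ScaffoldSequence(name="random",
                                sequence=random_scaffold(required_nt, config.seed))
    else:  # file path with a user sequence (plain text or single-record FASTA)
        raw = Path(choice).read_text()
        lines = [ln.strip() for ln in raw.splitlines()]
        body = [ln for ln in lines if ln and not ln.startswith((">", "#", ";"))]
        return select_scaffold(required_nt, user_seq="".join(body), seed=config.seed)
    if seq.length < required_nt:
        raise ScaffoldLengthError(
            f"forced scaffold {seq.name} ({seq.length} nt) shorter than the "
            f"required {required_nt} nt"
        )
    return seq


def run_design(config: DesignConfig) -> DesignResult:
    """Execute the full pipeline and write all artifacts.

    On any failure, partially written outputs are removed before the error
    propagates (no half-bundles on disk).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except DesignError:
        for p in written:
            if p.exists():
                os.remove(p)
        raise


def _run(config: DesignConfig, outdir: Path, written: list[Path]) -> DesignResult:
    mesh = _load_mesh(config)
    scaled = scale_mesh(mesh, config.min_edge_bp)
    graph = build_graph(scaled)
    tree = spanning_tree(graph)
    route = route_scaffold(graph, tree, scaled)
    frames = place_helices(scaled)
    assign_edge_positions(route.store, frames)
    insert_vertex_gaps(route, scaled)

    scaffold = _pick_scaffold(config, route.required_scaffold_nt)
    excess = assign_sequence(route, scaffold)
    place_unpaired_nodes(route, scaled, frames)
    staple_set = generate_staples(route, tree, scaled)
    assign_edge_positions(route.store, frames)   # staple nodes need positions too

    structure = build_atoms(route, staple_set, frames, scaled,
                            hydrogens=config.hydrogens)
    clashes = detect_clashes(structure, cutoff=config.clash_cutoff)

    provenance = [
        f"generated by dxwire {__version__}",
        f"seed {config.seed}",
        f"config {config.hash()}",
    ]
    prov_dict = {"tool": f"dxwire {__version__}", "seed": config.seed,
                 "config_hash": config.hash()}

    paths = {k: outdir / v for k, v in ARTIFACTS.items()}
    paths["summary"] = outdir / SUMMARY_FILE
    paths["cross_sections"] = outdir / XSECTION_FILE
    written.extend(paths.values())

    write_cylinder_model(scaled, frames, paths["cylinder_model"],
                         provenance=provenance)
    write_routing_model(route, staple_set, paths["routing_model"],
                        provenance=prov_dict)
    write_pseudo_atomic_model(route, staple_set, paths["pseudo_atomic_model"],
                              provenance=prov_dict)
    write_staple_csv(staple_set, paths["staples"],
                     plate_layout=config.plate_layout, provenance=provenance)
    write_cadnano(scaled, route, staple_set, paths["cadnano"],
                  xsection_path=paths["cross_sections"],
                  name=f"dxwire:{config.geometry}:{config.hash()}")
    strand_map_path = outdir / STRAND_MAP_FILE
    pdb_info = write_pdb(structure, paths["pdb"], provenance=provenance,
                         multimodel=config.multimodel,
                         strand_map_path=strand_map_path)
    if pdb_info["chain_wrapped"]:
        paths["strand_map"] = strand_map_path
        written.append(strand_map_path)

    stats = staple_statistics(staple_set)
    summary = {
        "tool_version": __version__,
        "geometry": config.geometry,
        "seed": config.seed,
        "config_hash": config.hash(),
        "edge_type": config.edge_type,
        "min_edge_bp": config.min_edge_bp,
        "vertices": mesh.num_vertices,
        "edges": mesh.num_edges,
        "faces": mesh.num_faces,
        "total_paired_nt": route.total_paired_nt,
        "total_unpaired_nt": route.total_unpaired_nt,
        "required_scaffold_nt": route.required_scaffold_nt,
        "scaffold_name": scaffold.name,
        "scaffold_length_nt": scaffold.length,
        "excess_loop_nt": excess,
        "scaffold_crossovers": len(route.crossover_edges),
        "staple_count": len(staple_set),
        "staple_total_nt": stats["totals"]["total_nt"],
        "strand_count": len(structure.strands),
        "atom_count": structure.n_atoms,
        "residue_count": structure.n_residues,
        "clash_cutoff_A": config.clash_cutoff,
        "clash_count": clashes.n_clashes,
        "clashes_per_vertex": json.dumps(clashes.per_vertex, sort_keys=True),
        "chain_wrapped": pdb_info["chain_wrapped"],
    }
    with open(paths["summary"], "w") as fh:
        fh.write(f"# dxwire design summary (tool {__version__})\n")
        for k, v in summary.items():
            fh.write(f"{k}: {v}\n")

    return DesignResult(
        config=config, scaled=scaled, graph=graph, tree=tree, route=route,
        frames=frames, scaffold=scaffold, staples=staple_set,
        structure=structure, clashes=clashes, paths=paths, summary=summary,
    )


# ---------------------------------------------------------------------------
# Bundle validation (CLI `validate` subcommand)
# ---------------------------------------------------------------------------

def validate_bundle(outdir) -> dict:
    """Re-check an emitted bundle's structural invariants.

    Returns a report dict; raises :class:`DesignError` on the first hard
    violation found.
    """
    from .exporters import read_cadnano, read_cylinder_metadata, read_pdb, read_staple_csv
    from .staples import STAPLE_LEN_MAX, STAPLE_LEN_MIN

    outdir = Path(outdir)
    report: dict = {"outdir": str(outdir)}
    missing = [v for v in list(ARTIFACTS.values()) + [SUMMARY_FILE]
               if not (outdir / v).exists()]
    if missing:
        raise DesignError(f"bundle incomplete; missing {missing}")

    summary = {}
    for line in (outdir / SUMMARY_FILE).read_text().splitlines():
        if line.startswith("#") or ": " not in line:
            continue
        k, v = line.split(": ", 1)
        summary[k] = v
    if (int(summary["total_paired_nt"]) + int(summary["total_unpaired_nt"])
            != int(summary["required_scaffold_nt"])):
        raise DesignError("summary scaffold accounting is inconsistent")
    report["required_scaffold_nt"] = int(summary["required_scaffold_nt"])

    rows = read_staple_csv(outdir / ARTIFACTS["staples"])
    for row in rows:
        if int(row["length_nt"]) != len(row["sequence_5to3"]):
            raise DesignError(f"staple {row['staple_id']} length/sequence mismatch")
        if not STAPLE_LEN_MIN <= int(row["length_nt"]) <= STAPLE_LEN_MAX:
            raise DesignError(f"staple {row['staple_id']} length out of bounds")
    report["staple_count"] = len(rows)

    doc = read_cadnano(outdir / ARTIFACTS["cadnano"])
    _check_cadnano_links(doc, report)

    meta = read_cylinder_metadata(outdir / ARTIFACTS["cylinder_model"])
    diameters = {m["diameter_nm"] for m in meta}
    if len(diameters) != 1:
        raise DesignError(f"cylinder diameters not uniform: {diameters}")
    report["cylinder_count"] = len(meta)
    report["cylinder_diameter_nm"] = diameters.pop()

    segments = read_pdb(outdir / ARTIFACTS["pdb"])
    serials = [rec.serial for seg in segments for rec in seg]
    if serials and not all(b > a for a, b in zip(serials, serials[1:])):
        # per-model restarts are allowed in multimodel output
        if summary.get("chain_wrapped") is None:
            raise DesignError("atom serials are not monotone")
    report["pdb_chain_segments"] = len(segments)
    report["ok"] = True
    return report


def _check_cadnano_links(doc: dict, report: dict) -> None:
    helices = {h["num"]: h for h in doc["vstrands"]}
    for kind in ("scaf", "stap"):
        occupied = 0
        for num, h in helices.items():
            for pos, cell in enumerate(h[kind]):
                f_h, f_p, t_h, t_p = cell
                if cell == [-1, -1, -1, -1]:
                    continue
                occupied += 1
                if t_h != -1 and helices[t_h][kind][t_p][0:2] != [num, pos]:
                    raise DesignError(
                        f"{kind} link ({num},{pos})->({t_h},{t_p}) not reciprocal"
                    )
                if f_h != -1 and helices[f_h][kind][f_p][2:4] != [num, pos]:
                    raise DesignError(
                        f"{kind} back-link ({num},{pos})<-({f_h},{f_p}) not reciprocal"
                    )
        report[f"cadnano_{kind}_occupied"] = occupied
    # scaffold closure: walk downstream counting loop insertions
    start = None
    for num, h in sorted(helices.items()):
        for pos, cell in enumerate(h["scaf"]):
            if cell != [-1, -1, -1, -1]:
                start = (num, pos)
                break
        if start:
            break
    if start is None:
        raise DesignError("caDNAno document has no scaffold")
    steps = 0
    here = start
    limit = sum(len(h["scaf"]) for h in helices.values()) + 1
    while True:
        num, pos = here
        steps += 1 + helices[num]["loop"][pos]
        nxt = tuple(helices[num]["scaf"][pos][2:4])
        if nxt == (-1, -1):
            raise DesignError("scaffold path is not closed")
        if nxt == start:
            break
        here = nxt
        if steps > limit:
            raise DesignError("scaffold walk does not terminate")
    report["cadnano_scaffold_cycle_nt"] = steps
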