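# dxwire

Fully automatic top-down sequence design of 3D wireframe DNA origami with
two-helix-bundle (DX) edges, supporting continuous edge lengths and
arbitrary vertex angles.

From a closed polygonal mesh (ASCII PLY, or a built-in fixture), dxwire:

1. validates and quantizes the mesh — the requested minimum edge length
   (42–210 bp) is assigned to the shortest edge and all other edges are
   scaled and rounded to integer base pairs (0.332 nm/bp);
2. routes one circular single-stranded scaffold through every edge as two
   antiparallel duplexes: a deterministic spanning tree decides crossover
   placement (scaffold double crossovers at the midpoints of non-tree
   edges) so the scaffold provably closes into a single loop, which is
   re-verified at run time;
3. inserts unpaired scaffold nucleotides at each vertex to span the gap
   between incoming and outgoing duplex ends (0.42 nm per nucleotide);
4. picks a scaffold sequence automatically — M13mp18 for required lengths
   ≤ 7,249 nt, Lambda for ≤ 48,502 nt, a seeded random sequence above
   that — or takes a user sequence file;
5. tiles the complementary strand space with staples (21-bp interior
   crossover spacing, 10–11 bp vertex domains, 20–60 nt lengths) with
   sequences assigned by Watson–Crick complementarity;
6. builds an all-atom model from per-base reference B-form templates,
   interpolating single-stranded runs with cubic Bézier curves, and
   reports (does not repair) steric clashes;
7. exports six artifacts: a cylinder model (PLY, 2-nm cylinders), a
   routing model (JSON polylines), a pseudo-atomic model (JSON), a staple
   CSV (optional 96-well plate layout), a caDNAno JSON document with an
   edge↔helix cross-section sidecar, and a fixed-column PDB that encodes
   atom serials above 99,999 and residue numbers above 9,999 with a hybrid
   base-36 scheme (one case-sensitive letter + base-36 digits), cycling
   chains through the 62 case-sensitive alphanumeric IDs.

The bundled M13mp18 (7,249 nt) and Lambda (48,502 nt) files are
deterministic, length-faithful surrogate sequences; substitute the
authentic sequences before ordering strands for the wet lab.

## CLI

```sh
# built-in geometries
dxwire fixtures

# full design: six artifacts + design_summary.txt in ./out
dxwire design -g asymmetric_octahedron --min-edge-bp 63 --seed 1 -o out

# design from a PLY file with a user scaffold
dxwire design -g shape.ply --scaffold my_scaffold.txt -o out

# re-check an emitted bundle's invariants
dxwire validate out

# hybrid PDB field encoders
dxwire encode --kind atom 99999 100000
```

`design` also accepts `--config cfg.yaml` (same keys as the flags),
`--plate-layout`, `--hydrogens`, and `--multimodel` (one PDB MODEL per
strand, for converters that expect multi-model input).

## Layout

- `src/dxwire/geometry_core.py` — PLY I/O, mesh validation/repair, fixture
  catalogue, base-pair scaling
- `src/dxwire/routing.py` — design graph, spanning tree, scaffold routing,
  vertex gaps, scaffold selection and sequence assignment
- `src/dxwire/staples.py` — staple partitioning and sequences
- `src/dxwire/atomic_model.py` + `templates.py` — helix frames, base
  posing, Bézier interpolation, clash detection
- `src/dxwire/exporters/` — PDB, caDNAno, cylinder, CSV, model writers and
  the hybrid field encoders
- `src/dxwire/cli.py`, `pipeline.py` — command line and pipeline driver

Out of scope by design: 6HB-edge motifs (the `edge_type` flag is the
extension point), GUI rendering, mmCIF output, oxDNA file generation, and
any energy minimization of clashing single-stranded regions.
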