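import json
import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxwire.atomic_model import AtomicStructure, Nucleotide, Strand, build_atoms
from dxwire.errors import CapacityError, PdbBoundsError
from dxwire.exporters import (
    ATOM_SERIAL_CAPACITY,
    CHAIN_IDS,
    RESIDUE_NUMBER_CAPACITY,
    decode_atom_serial,
    decode_residue_number,
    encode_atom_serial,
    encode_residue_number,
    read_cadnano,
    read_cylinder_metadata,
    read_pdb,
    read_staple_csv,
    well_name,
    write_cadnano,
    write_cylinder_model,
    write_pdb,
    write_staple_csv,
)
from dxwire.templates import get_template


def oracle_encode(index: int, decimal_max: int, width: int) -> str:
    """Independent re-implementation of the hybrid field scheme."""
    if index <= decimal_max:
        return str(index).rjust(width)
    alpha = string.ascii_uppercase + string.ascii_lowercase
    b36 = string.digits + string.ascii_uppercase
    o = index - decimal_max - 1
    tail = ""
    for _ in range(width - 1):
        tail = b36[o % 36] + tail
        o //= 36
    return alpha[o] + tail


class TestEncoders:
    def test_atom_serial_boundary_values(self):
        assert encode_atom_serial(1) == "    1"
        assert encode_atom_serial(99999) == "99999"
        assert encode_atom_serial(100000) == "A0000"
        assert encode_atom_serial(100001) == "A0001"

    def test_residue_boundary_values(self):
        assert encode_residue_number(9999) == "9999"
        assert encode_residue_number(10000) == "A000"

    def test_capacities(self):
        assert ATOM_SERIAL_CAPACITY == 99999 + 52 * 36 ** 4
        assert 52 * 36 ** 4 == 87_340_032          # ">87 million total atoms"
        assert RESIDUE_NUMBER_CAPACITY == 9999 + 52 * 36 ** 3
        assert 52 * 36 ** 3 == 2_426_112           # ">2.4 million residues"
        encode_atom_serial(ATOM_SERIAL_CAPACITY)
        encode_residue_number(RESIDUE_NUMBER_CAPACITY)
        with pytest.raises(CapacityError):
            encode_atom_serial(ATOM_SERIAL_CAPACITY + 1)
        with pytest.raises(CapacityError):
            encode_residue_number(RESIDUE_NUMBER_CAPACITY + 1)
        with pytest.raises(CapacityError):
            encode_atom_serial(0)

    def test_matches_enumeration_oracle_at_boundary(self):
        for i in range(99990, 100200):
            assert encode_atom_serial(i) == oracle_encode(i, 99999, 5)
        for i in range(9990, 10200):
            assert encode_residue_number(i) == oracle_encode(i, 9999, 4)

    def test_round_trip_fixed_and_sampled(self):
        rng = np.random.default_rng(0)
        sample = {1, 99999, 100000, ATOM_SERIAL_CAPACITY}
        sample.update(int(x) for x in
                      rng.integers(1, ATOM_SERIAL_CAPACITY, size=10_000))
        for i in sample:
            assert decode_atom_serial(encode_atom_serial(i)) == i
        res_sample = {1, 9999, 10000, RESIDUE_NUMBER_CAPACITY}
        res_sample.update(int(x) for x in
                          rng.integers(1, RESIDUE_NUMBER_CAPACITY, size=10_000))
        for i in res_sample:
            assert decode_residue_number(encode_residue_number(i)) == i

    @settings(max_examples=300, deadline=None)
    @given(st.integers(min_value=1, max_value=ATOM_SERIAL_CAPACITY - 1))
    def test_strictly_monotone_lexicographic(self, i):
        assert encode_atom_serial(i) < encode_atom_serial(i + 1)

    def test_monotone_exhaustive_at_decimal_hybrid_switch(self):
        fields = [encode_atom_serial(i) for i in range(99000, 101000)]
        assert fields == sorted(fields)
        rfields = [encode_residue_number(i) for i in range(9900, 10100)]
        assert rfields == sorted(rfields)

    def test_chain_id_census(self):
        assert len(CHAIN_IDS) == 62
        assert len(set(CHAIN_IDS)) == 62
        assert set(CHAIN_IDS) == set(
            string.ascii_uppercase + string.ascii_lowercase + string.digits)


def tiny_structure(n_strands: int = 2, bases_per_strand: int = 1) -> AtomicStructure:
    tpl = get_template("DA")
    strands = []
    for s in range(n_strands):
        nts = []
        for b in range(bases_per_strand):
            nts.append(Nucleotide(
                node_id=s * 1000 + b, residue="DA",
                atom_names=tpl.atom_names, elements=tpl.elements,
                coords=tpl.coords + np.array([20.0 * s, 5.0 * b, 0.0]),
                residence=("edge", 0, 0, b),
            ))
        strands.append(Strand(role="staple", nucleotides=nts))
    return AtomicStructure(strands=strands)


class TestPdbWriter:
    def test_one_bp_round_trip(self, tmp_path):
        structure = tiny_structure(2, 1)
        path = tmp_path / "toy.pdb"
        write_pdb(structure, path)
        segments = read_pdb(path)
        assert len(segments) == 2
        for seg, strand in zip(segments, structure.strands):
            nt = strand.nucleotides[0]
            assert [r.name for r in seg] == list(nt.atom_names)
            assert {r.res_name for r in seg} == {"DA"}
            got = np.array([[r.x, r.y, r.z] for r in seg])
            np.testing.assert_allclose(got, np.round(nt.coords, 3), atol=5e-4)

    def test_63_strands_wrap_with_sidecar(self, tmp_path):
        structure = tiny_structure(63, 1)
        path = tmp_path / "many.pdb"
        sidecar = tmp_path / "strands.csv"
        info = write_pdb(structure, path, strand_map_path=sidecar)
        assert info["chain_wrapped"] is True
        text = path.read_text()
        assert text.count("\nTER") + text.startswith("TER") == 63
        segments = read_pdb(path)
        assert len(segments) == 63
        chains = [seg[0].chain_id for seg in segments]
        assert chains[0] == "A" and chains[62] == "A"   # cyclic reuse
        assert sidecar.exists()
        assert "strand_index" in sidecar.read_text().splitlines()[0]

    def test_serial_and_residue_numbering_monotone(self, tmp_path):
        structure = tiny_structure(3, 2)
        path = tmp_path / "m.pdb"
        write_pdb(structure, path)
        segments = read_pdb(path)
        serials = [r.serial for seg in segments for r in seg]
        assert serials != sorted(set(serials)) or all(
            b > a for a, b in zip(serials, serials[1:]))

    def test_out_of_bounds_coordinate_rejected(self, tmp_path):
        structure = tiny_structure(1, 1)
        structure.strands[0].nucleotides[0].coords = (
            structure.strands[0].nucleotides[0].coords + 10000.0)
        with pytest.raises(PdbBoundsError, match="recentre"):
            write_pdb(structure, tmp_path / "oob.pdb")

    def test_multimodel_emits_model_records(self, tmp_path):
        structure = tiny_structure(3, 1)
        path = tmp_path / "multi.pdb"
        write_pdb(structure, path, multimodel=True)
        text = path.read_text()
        assert text.count("MODEL ") == 3
        assert text.count("ENDMDL") == 3

    def test_full_design_round_trip_field_preservation(self, tetra_design):
        segments = read_pdb(tetra_design.paths["pdb"])
        n_res = sum(len({r.res_seq for r in seg}) for seg in segments)
        assert n_res == tetra_design.structure.n_residues
        n_atoms = sum(len(seg) for seg in segments)
        assert n_atoms == tetra_design.structure.n_atoms
        assert len(segments) == len(tetra_design.structure.strands)


class TestCadnano:
    def test_helix_count_and_parity(self, aso_design):
        doc = read_cadnano(aso_design.paths["cadnano"])
        assert len(doc["vstrands"]) == 2 * aso_design.scaled.mesh.num_edges
        for h in doc["vstrands"]:
            assert (h["row"] + h["col"]) % 2 == h["num"] % 2
            assert len(h["scaf"]) == len(h["stap"]) == len(h["loop"]) == len(h["skip"])
            assert len(h["scaf"]) % 21 == 0

    def test_linked_lists_reciprocal(self, aso_design):
        doc = read_cadnano(aso_design.paths["cadnano"])
        helices = {h["num"]: h for h in doc["vstrands"]}
        for kind in ("scaf", "stap"):
            for num, h in helices.items():
                for pos, cell in enumerate(h[kind]):
                    if cell == [-1, -1, -1, -1]:
                        continue
                    f_h, f_p, t_h, t_p = cell
                    if t_h != -1:
                        assert helices[t_h][kind][t_p][0:2] == [num, pos]
                    if f_h != -1:
                        assert helices[f_h][kind][f_p][2:4] == [num, pos]

    def test_scaffold_walk_closes_at_required_length(self, aso_design):
        doc = read_cadnano(aso_design.paths["cadnano"])
        helices = {h["num"]: h for h in doc["vstrands"]}
        start = None
        for num in sorted(helices):
            for pos, cell in enumerate(helices[num]["scaf"]):
                if cell != [-1, -1, -1, -1]:
                    start = (num, pos)
                    break
            if start:
                break
        steps = 0
        here = start
        while True:
            num, pos = here
            steps += 1 + helices[num]["loop"][pos]
            nxt = tuple(helices[num]["scaf"][pos][2:4])
            assert nxt != (-1, -1)
            if nxt == start:
                break
            here = nxt
            assert steps <= aso_design.route.required_scaffold_nt
        assert steps == aso_design.route.required_scaffold_nt

    def test_staple_five_prime_colors_recorded(self, aso_design):
        doc = read_cadnano(aso_design.paths["cadnano"])
        n_colors = sum(len(h["stap_colors"]) for h in doc["vstrands"])
        assert n_colors == len(aso_design.staples)


class TestCylinders:
    def test_diameter_and_count(self, tetra_design):
        meta = read_cylinder_metadata(tetra_design.paths["cylinder_model"])
        assert len(meta) == 2 * tetra_design.scaled.mesh.num_edges
        assert {m["diameter_nm"] for m in meta} == {2.0}

    def test_tetra_42bp_lengths(self, tetra_design):
        meta = read_cylinder_metadata(tetra_design.paths["cylinder_model"])
        for m in meta:
            assert round(m["length_nm"], 2) == 13.94

    def test_ply_is_parseable_mesh(self, tetra_design, tmp_path):
        # the cylinder file must be structurally valid ASCII PLY
        text = tetra_design.paths["cylinder_model"].read_text()
        assert text.startswith("ply\nformat ascii 1.0")
        header, _, body = text.partition("end_header\n")
        nv = int([ln for ln in header.splitlines()
                  if ln.startswith("element vertex")][0].split()[-1])
        nf = int([ln for ln in header.splitlines()
                  if ln.startswith("element face")][0].split()[-1])
        lines = body.strip().splitlines()
        assert len(lines) == nv + nf


class TestStapleCsv:
    def test_round_trip_byte_identical_sequences(self, aso_design):
        rows = read_staple_csv(aso_design.paths["staples"])
        assert [r["sequence_5to3"] for r in rows] == [
            s.sequence for s in aso_design.staples]

    def test_column_count_fixed_by_header(self, aso_design):
        raw = [ln for ln in aso_design.paths["staples"].read_text().splitlines()
               if not ln.startswith("#")]
        width = len(raw[0].split(","))
        for ln in raw[1:]:
            assert len(ln.split(",")) == width

    def test_plate_layout_wraps_at_96(self, tmp_path):
        from dxwire.staples import Staple, StapleSet

        staples = StapleSet(staples=[
            Staple(id=i, node_ids=list(range(20)), sequence="A" * 20,
                   cls="edge", residence=("edge", 0), color="#000000")
            for i in range(97)
        ])
        write_staple_csv(staples, tmp_path / "p.csv", plate_layout=True)
        rows = read_staple_csv(tmp_path / "p.csv")
        assert rows[0]["well"] == "A1" and rows[0]["plate"] == "1"
        assert rows[11]["well"] == "A12"
        assert rows[12]["well"] == "B1"
        assert rows[95]["well"] == "H12" and rows[95]["plate"] == "1"
        assert rows[96]["well"] == "A1" and rows[96]["plate"] == "2"

    def test_well_arithmetic(self):
        assert well_name(0) == (1, "A1")
        assert well_name(95) == (1, "H12")
        assert well_name(96) == (2, "A1")


class TestModels:
    def test_routing_model_polyline_lengths(self, aso_design):
        doc = json.loads(aso_design.paths["routing_model"].read_text())
        assert len(doc["scaffold"]["points"]) == aso_design.route.cycle_length()
        assert len(doc["staples"]) == len(aso_design.staples)

    def test_pseudo_atomic_model_counts(self, aso_design):
        doc = json.loads(aso_design.paths["pseudo_atomic_model"].read_text())
        total = sum(len(s["residues"]) for s in doc["strands"])
        assert total == aso_design.structure.n_residues
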