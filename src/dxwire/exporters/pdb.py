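"""Fixed-column PDB v3.3 writer/reader for large DNA structures.

One chain per strand, cycling through the 62 case-sensitive alphanumeric
chain identifiers with TER separation; when the strand count exceeds 62 a
sidecar strand-map CSV disambiguates the reuse.  Atom serials and residue
numbers switch to the hybrid base-36 encoding beyond their decimal
ceilings.  Coordinates are validated against the format's spatial bounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from ..atomic_model import AtomicStructure
from ..errors import PdbBoundsError
from .encoding import (
    CHAIN_IDS,
    decode_atom_serial,
    decode_residue_number,
    encode_atom_serial,
    encode_residue_number,
)

__all__ = ["PdbLimits", "PDB_LIMITS", "write_pdb", "read_pdb", "AtomRecord"]


@dataclass(frozen=True)
class PdbLimits:
    """Hard constants of the fixed-column PDB format."""

    max_chain_ids: int = 62
    max_base10_atoms: int = 99999
    max_base10_residues: int = 9999
    coord_min: float = -999.999
    coord_max: float = 9999.999


PDB_LIMITS = PdbLimits()


@dataclass
class AtomRecord:
    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    x: float
    y: float
    z: float
    element: str


def _atom_name_field(name: str, element: str) -> str:
    # element right-justified in cols 13-14 per the format; 4-char names fill
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _check_coord(v: float) -> float:
    if not PDB_LIMITS.coord_min <= v <= PDB_LIMITS.coord_max:
        raise PdbBoundsError(
            f"coordinate {v:.3f} outside "
            f"[{PDB_LIMITS.coord_min}, {PDB_LIMITS.coord_max}] Angstroms; "
            "recentre the structure (mmCIF output is out of scope)"
        )
    return v


def write_pdb(structure: AtomicStructure, path, provenance: list[str] | None = None,
              multimodel: bool = False, strand_map_path=None) -> dict:
    """Write ATOM/TER records; returns a summary dict.

    ``multimodel=True`` emits one MODEL per strand with numbering restarted
    per model (for converters that expect multi-model input); default is a
    single implicit model with global numbering.
    """
    n_strands = len(structure.strands)
    strand_map = []
    lines: list[str] = []
    for i, remark in enumerate(provenance or [], start=1):
        lines.append(f"REMARK 300 {remark}"[:80])

    serial = 0
    res_num = 0
    for si, strand in enumerate(structure.strands):
        chain = CHAIN_IDS[si % len(CHAIN_IDS)]
        strand_map.append({"strand_index": si, "role": strand.role, "chain_id": chain})
        if multimodel:
            serial = 0
            res_num = 0
            lines.append(f"MODEL {si + 1:>8d}")
        res_field = None
        for nt in strand.nucleotides:
            res_num += 1
            res_field = encode_residue_number(res_num)
            for name, element, (x, y, z) in zip(nt.atom_names, nt.elements, nt.coords):
                serial += 1
                lines.append(
                    "ATOM  {serial} {name} {res:>3} {chain}{resseq}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2}".format(
                        serial=encode_atom_serial(serial),
                        name=_atom_name_field(name, element),
                        res=nt.residue,
                        chain=chain,
                        resseq=encode_residue_number(res_num),
                        x=_check_coord(float(x)),
                        y=_check_coord(float(y)),
                        z=_check_coord(float(z)),
                        occ=1.0,
                        b=0.0,
                        elem=element,
                    )
                )
        serial += 1
        last_res = structure.strands[si].nucleotides[-1].residue if strand.nucleotides else "   "
        lines.append(
            "TER   {serial}      {res:>3} {chain}{resseq}".format(
                serial=encode_atom_serial(serial),
                res=last_res,
                chain=chain,
                resseq=res_field or "    ",
            )
        )
        if multimodel:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if n_strands > len(CHAIN_IDS) and strand_map_path is not None:
        with open(strand_map_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["strand_index", "role", "chain_id"])
            writer.writeheader()
            writer.writerows(strand_map)
    return {
        "n_strands": n_strands,
        "n_atoms": structure.n_atoms,
        "n_residues": structure.n_residues,
        "chain_wrapped": n_strands > len(CHAIN_IDS),
        "strand_map": strand_map,
    }


def read_pdb(path) -> list[list[AtomRecord]]:
    """Parse ATOM records back into per-chain-segment lists.

    Chain segments are split on TER; hybrid serial/residue fields decode to
    integers.  Only the fields this package writes are interpreted.
    """
    segments: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    with open(path) as fh:
        for line in fh:
            tag = line[:6]
            if tag == "ATOM  ":
                current.append(AtomRecord(
                    serial=decode_atom_serial(line[6:11]),
                    name=line[12:16].strip(),
                    res_name=line[17:20].strip(),
                    chain_id=line[21],
                    res_seq=decode_residue_number(line[22:26]),
                    x=float(line[30:38]),
                    y=float(line[38:46]),
                    z=float(line[46:54]),
                    element=line[76:78].strip(),
                ))
            elif tag.startswith("TER"):
                segments.append(current)
                current = []
    if current:
        segments.append(current)
    return segments
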