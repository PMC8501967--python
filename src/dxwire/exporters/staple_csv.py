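"""Staple sequence CSV export with optional 96-well plate layout."""

from __future__ import annotations

import csv
import string

from ..staples import StapleSet

__all__ = ["write_staple_csv", "read_staple_csv", "well_name"]

FIELDNAMES = ["staple_id", "class", "edge_or_vertex", "length_nt",
              "sequence_5to3", "color"]
PLATE_FIELDS = FIELDNAMES + ["plate", "well"]

_ROWS = string.ascii_uppercase[:8]     # A..H
_COLS = 12


def well_name(index: int) -> tuple[int, str]:
    """(plate, well) for a zero-based staple index, row-major A1..H12."""
    plate, within = divmod(index, len(_ROWS) * _COLS)
    row, col = divmod(within, _COLS)
    return plate + 1, f"{_ROWS[row]}{col + 1}"


def write_staple_csv(staple_set: StapleSet, path, plate_layout: bool = False,
                     provenance: list[str] | None = None) -> None:
    fields = PLATE_FIELDS if plate_layout else FIELDNAMES
    with open(path, "w", newline="") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for i, s in enumerate(staple_set):
            row = {
                "staple_id": s.id,
                "class": s.cls,
                "edge_or_vertex": f"{s.residence[0]}:{s.residence[1]}",
                "length_nt": s.length,
                "sequence_5to3": s.sequence,
                "color": s.color,
            }
            if plate_layout:
                plate, well = well_name(i)
                row["plate"] = plate
                row["well"] = well
            writer.writerow(row)


def read_staple_csv(path) -> list[dict]:
    with open(path) as fh:
        rows = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(rows))
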