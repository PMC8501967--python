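"""Hybrid base-36 field encoders for large-structure PDB output.

Indices up to the base-10 ceiling of their fixed-width field are rendered
as right-justified decimal.  Above it, the field switches to a hybrid
code: one case-sensitive alphabetical character (A-Z then a-z, 52 values)
followed by base-36 digits (0-9 then A-Z, uppercase).  The alphabetical
first character is what lets any parser recognize the switch.
"""

from __future__ import annotations

import string

from ..errors import CapacityError

__all__ = [
    "encode_atom_serial",
    "decode_atom_serial",
    "encode_residue_number",
    "decode_residue_number",
    "ATOM_SERIAL_CAPACITY",
    "RESIDUE_NUMBER_CAPACITY",
    "CHAIN_IDS",
]

_ALPHA52 = string.ascii_uppercase + string.ascii_lowercase
_B36 = string.digits + string.ascii_uppercase

#: The 62 case-sensitive alphanumeric single-character chain identifiers.
CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

_ATOM_DECIMAL_MAX = 99999
_RES_DECIMAL_MAX = 9999

ATOM_SERIAL_CAPACITY = _ATOM_DECIMAL_MAX + 52 * 36 ** 4        # 87,440,031
RESIDUE_NUMBER_CAPACITY = _RES_DECIMAL_MAX + 52 * 36 ** 3      # 2,436,111


def _encode(index: int, decimal_max: int, width: int) -> str:
    if index < 1:
        raise CapacityError(f"index must be >= 1, got {index}")
    if index <= decimal_max:
        return f"{index:>{width}d}"
    offset = index - decimal_max - 1
    tail_width = width - 1
    block = 36 ** tail_width
    lead, rest = divmod(offset, block)
    if lead >= len(_ALPHA52):
        raise CapacityError(
            f"index {index} exceeds hybrid capacity {decimal_max + 52 * block}"
        )
    digits = []
    for _ in range(tail_width):
        rest, d = divmod(rest, 36)
        digits.append(_B36[d])
    return _ALPHA52[lead] + "".join(reversed(digits))


def _decode(field: str, decimal_max: int, width: int) -> int:
    field = field.strip() if field[:1] == " " else field
    if field[0].isdigit():
        return int(field)
    lead = _ALPHA52.index(field[0])
    tail_width = width - 1
    rest = 0
    for ch in field[1:]:
        rest = rest * 36 + _B36.index(ch)
    return decimal_max + 1 + lead * 36 ** tail_width + rest


def encode_atom_serial(index: int) -> str:
    """5-character atom serial field; decimal through 99,999, hybrid above."""
    return _encode(index, _ATOM_DECIMAL_MAX, 5)


def decode_atom_serial(field: str) -> int:
    return _decode(field, _ATOM_DECIMAL_MAX, 5)


def encode_residue_number(index: int) -> str:
    """4-character residue number field; decimal through 9,999, hybrid above."""
    return _encode(index, _RES_DECIMAL_MAX, 4)


def decode_residue_number(field: str) -> int:
    return _decode(field, _RES_DECIMAL_MAX, 4)
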