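"""Physical and format constants shared by every stage of the designer."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DesignConstants:
    """B-form DNA geometry and scaffold-catalogue constants.

    ``rise_per_bp`` is fixed at 0.332 nm so that a 42-bp edge measures
    13.94 nm, matching the printed design range (42 bp / 13.94 nm through
    210 bp).  ``ssdna_len_per_nt`` is the contour length budgeted per
    unpaired scaffold nucleotide when spanning vertex gaps.
    """

    rise_per_bp: float = 0.332          # nm per base pair along the helix axis
    bp_per_turn: float = 10.5           # B-form helical repeat
    duplex_diameter: float = 2.0        # nm, cylinder-model diameter
    interhelix_spacing: float = 2.25    # nm between the two DX duplex axes
    ssdna_len_per_nt: float = 0.42      # nm contour length per unpaired nt
    min_edge_bp_bound: int = 42         # smallest accepted minimum edge length
    max_edge_bp_bound: int = 210        # largest accepted minimum edge length
    m13_len: int = 7249                 # nt, M13mp18 scaffold
    lambda_len: int = 48502             # nt, Lambda phage scaffold

    def __post_init__(self) -> None:
        numeric = (
            self.rise_per_bp, self.bp_per_turn, self.duplex_diameter,
            self.interhelix_spacing, self.ssdna_len_per_nt,
            self.min_edge_bp_bound, self.max_edge_bp_bound,
            self.m13_len, self.lambda_len,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all design constants must be positive")
        if self.min_edge_bp_bound >= self.max_edge_bp_bound:
            raise ValueError("min_edge_bp_bound must be < max_edge_bp_bound")


#: Module-wide default constants.  Operations accept an override for testing
#: alternate parameterizations.
CONSTANTS = DesignConstants()

#: Degrees of twist per base pair step.
TWIST_PER_BP_DEG = 360.0 / CONSTANTS.bp_per_turn

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
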