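"""Reference average B-form nucleotide templates.

Base ring atoms (and C1') are pinned to the standard base reference frame
(average B-form base geometry); the sugar-phosphate backbone is taken from
idealized residue geometry (bundled chemical component definitions via
biotite) and rigidly fitted onto the ring.  Heavy atoms only by default;
hydrogens behind a flag.  The strand II partner of a pair is obtained by a
180 degree rotation of its template about the pair frame x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "NucleotideTemplate",
    "get_template",
    "HEAVY_ATOM_COUNTS",
    "STRAND_II_FLIP",
    "RESIDUE_OF_BASE",
]

RESIDUE_OF_BASE = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

#: Heavy atoms per residue (with 5'-phosphate, no OP3, no hydrogens).
HEAVY_ATOM_COUNTS = {"DA": 21, "DC": 19, "DG": 22, "DT": 20}

#: Rotation placing the complementary (strand II) base into the pair frame.
STRAND_II_FLIP = np.diag([1.0, -1.0, -1.0])

# Standard reference frame coordinates (Angstroms) of base ring atoms and
# C1' for the four deoxyribonucleotides; base plane is z = 0, the
# Watson-Crick edge faces the paired strand across the frame origin.
_STANDARD_FRAME: dict[str, dict[str, tuple[float, float, float]]] = {
    "DA": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "DG": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "DC": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "DT": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}


@dataclass(frozen=True)
class NucleotideTemplate:
    """Atom names, elements and coordinates of one nucleotide in the pair frame."""

    residue: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray              # (n, 3) Angstroms

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def index_of(self, name: str) -> int:
        return self.atom_names.index(name)


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with R@m + t ~ target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


_BACKBONE_HEAVY = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                   "C3'", "O3'", "C2'", "C1'")


def _base_fitted(residue: str, hydrogens: bool):
    """CCD residue geometry rigidly fitted onto the standard base frame."""
    import biotite.structure.info as struc_info

    ref = struc_info.residue(residue)
    keep = (ref.atom_name != "OP3") & (ref.atom_name != "HOP3")
    if not hydrogens:
        keep &= ref.element != "H"
    ref = ref[keep]
    frame = _STANDARD_FRAME[residue]
    shared = [n for n in frame if n in set(ref.atom_name)]
    mobile = np.stack([ref.coord[ref.atom_name == n][0] for n in shared])
    target = np.array([frame[n] for n in shared])
    r, t = _kabsch(mobile, target)
    coords = (r @ ref.coord.T).T + t
    for n in shared:
        coords[np.nonzero(ref.atom_name == n)[0][0]] = frame[n]
    return ref.atom_name, ref.element, coords


@lru_cache(maxsize=1)
def _reference_backbone() -> dict[str, np.ndarray]:
    """Shared sugar-phosphate backbone pose (taken from the fitted DA).

    Idealized residue conformers differ per base type; stacking mixed
    sequences with per-residue backbones produces interpenetration.  A
    single backbone pose, compatible with the pinned C1'/glycosidic-N
    positions, is therefore grafted onto all four templates.
    """
    names, _, coords = _base_fitted("DA", hydrogens=False)
    return {str(n): coords[np.nonzero(names == n)[0][0]] for n in _BACKBONE_HEAVY}


@lru_cache(maxsize=8)
def get_template(residue: str, hydrogens: bool = False) -> NucleotideTemplate:
    """Template for one residue (DA/DC/DG/DT) posed in the pair frame.

    Base ring atoms sit exactly on the standard frame; backbone atoms (and
    their hydrogens, if requested) are the shared reference backbone,
    aligned by a rigid fit of the residue's own backbone fragment.
    """
    if residue not in _STANDARD_FRAME:
        raise KeyError(f"no template for residue {residue!r}")
    names, elements, coords = _base_fitted(residue, hydrogens)
    backbone = _reference_backbone()
    fragment = [i for i, n in enumerate(names)
                if str(n) in backbone or str(n).startswith(("H5'", "H4'", "H3'",
                                                            "H2'", "H1'", "HO", "HOP"))]
    heavy_idx = [i for i in fragment if str(names[i]) in backbone]
    mobile = coords[heavy_idx]
    target = np.stack([backbone[str(names[i])] for i in heavy_idx])
    r, t = _kabsch(mobile, target)
    coords[fragment] = (r @ coords[fragment].T).T + t
    for i in heavy_idx:
        coords[i] = backbone[str(names[i])]
    return NucleotideTemplate(
        residue=residue,
        atom_names=tuple(str(n) for n in names),
        elements=tuple(str(e) for e in elements),
        coords=coords,
    )
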