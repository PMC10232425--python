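"""Grantham physicochemical amino-acid distance model.

The distance between residues i and j combines differences in side-chain
composition (c), polarity (p) and molecular volume (v):

    D_ij = rho * sqrt(alpha*(c_i-c_j)**2 + beta*(p_i-p_j)**2 + gamma*(v_i-v_j)**2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and the scale rho = 50.723
chosen so that the mean distance over the 190 unordered residue pairs is 100.
The integer matrix packaged here is the rounded evaluation of that formula; the
recomputation from the property triples lives in the test suite as an
independent oracle. (The historically printed table differs by one unit at a
few cells because of period intermediate rounding; this package uses the
formula-exact values throughout so matrix and formula always agree.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GRANTHAM_PROPERTIES",
    "GRANTHAM_WEIGHTS",
    "GRANTHAM_SCALE",
    "GRANTHAM_MATRIX",
    "GranthamModel",
    "UndefinedResidueError",
    "grantham_distance",
    "default_model",
]

#: The 20 standard residues, one-letter code.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

#: Side-chain property triples (composition, polarity, volume) per residue.
GRANTHAM_PROPERTIES: Mapping[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0), "R": (0.65, 10.5, 124.0), "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61.0), "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0), "G": (0.74, 9.0, 3.0), "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0), "Y": (0.20, 6.2, 136.0), "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0), "Q": (0.89, 10.5, 85.0), "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0), "D": (1.38, 13.0, 54.0), "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0), "W": (0.13, 5.4, 170.0),
}

#: (alpha, beta, gamma) weighting the squared property differences.
GRANTHAM_WEIGHTS: tuple[float, float, float] = (1.833, 0.1018, 0.000399)

#: Normalization constant: mean inter-residue distance = 100.
GRANTHAM_SCALE: float = 50.723

#: Packaged integer distance table, upper triangle (symmetric, zero diagonal).
GRANTHAM_MATRIX: Mapping[tuple[str, str], int] = {
    ("A", "R"): 111, ("A", "N"): 110, ("A", "D"): 126, ("A", "C"): 195, ("A", "Q"): 91,
    ("A", "E"): 107, ("A", "G"): 60, ("A", "H"): 85, ("A", "I"): 94, ("A", "L"): 96,
    ("A", "K"): 106, ("A", "M"): 84, ("A", "F"): 113, ("A", "P"): 27, ("A", "S"): 99,
    ("A", "T"): 58, ("A", "W"): 148, ("A", "Y"): 112, ("A", "V"): 64, ("R", "N"): 85,
    ("R", "D"): 96, ("R", "C"): 180, ("R", "Q"): 43, ("R", "E"): 54, ("R", "G"): 125,
    ("R", "H"): 29, ("R", "I"): 98, ("R", "L"): 102, ("R", "K"): 26, ("R", "M"): 92,
    ("R", "F"): 97, ("R", "P"): 103, ("R", "S"): 109, ("R", "T"): 71, ("R", "W"): 101,
    ("R", "Y"): 77, ("R", "V"): 96, ("N", "D"): 23, ("N", "C"): 139, ("N", "Q"): 46,
    ("N", "E"): 41, ("N", "G"): 79, ("N", "H"): 68, ("N", "I"): 149, ("N", "L"): 152,
    ("N", "K"): 94, ("N", "M"): 141, ("N", "F"): 158, ("N", "P"): 90, ("N", "S"): 46,
    ("N", "T"): 65, ("N", "W"): 174, ("N", "Y"): 142, ("N", "V"): 133, ("D", "C"): 154,
    ("D", "Q"): 61, ("D", "E"): 45, ("D", "G"): 94, ("D", "H"): 81, ("D", "I"): 168,
    ("D", "L"): 172, ("D", "K"): 101, ("D", "M"): 160, ("D", "F"): 177, ("D", "P"): 108,
    ("D", "S"): 65, ("D", "T"): 85, ("D", "W"): 191, ("D", "Y"): 160, ("D", "V"): 152,
    ("C", "Q"): 154, ("C", "E"): 169, ("C", "G"): 158, ("C", "H"): 174, ("C", "I"): 197,
    ("C", "L"): 197, ("C", "K"): 202, ("C", "M"): 196, ("C", "F"): 204, ("C", "P"): 169,
    ("C", "S"): 112, ("C", "T"): 149, ("C", "W"): 214, ("C", "Y"): 194, ("C", "V"): 191,
    ("Q", "E"): 29, ("Q", "G"): 87, ("Q", "H"): 24, ("Q", "I"): 109, ("Q", "L"): 112,
    ("Q", "K"): 53, ("Q", "M"): 101, ("Q", "F"): 116, ("Q", "P"): 75, ("Q", "S"): 68,
    ("Q", "T"): 41, ("Q", "W"): 130, ("Q", "Y"): 99, ("Q", "V"): 96, ("E", "G"): 98,
    ("E", "H"): 41, ("E", "I"): 134, ("E", "L"): 138, ("E", "K"): 57, ("E", "M"): 126,
    ("E", "F"): 140, ("E", "P"): 94, ("E", "S"): 80, ("E", "T"): 66, ("E", "W"): 152,
    ("E", "Y"): 123, ("E", "V"): 121, ("G", "H"): 98, ("G", "I"): 135, ("G", "L"): 138,
    ("G", "K"): 126, ("G", "M"): 127, ("G", "F"): 153, ("G", "P"): 42, ("G", "S"): 55,
    ("G", "T"): 59, ("G", "W"): 184, ("G", "Y"): 147, ("G", "V"): 109, ("H", "I"): 94,
    ("H", "L"): 99, ("H", "K"): 32, ("H", "M"): 86, ("H", "F"): 100, ("H", "P"): 76,
    ("H", "S"): 89, ("H", "T"): 47, ("H", "W"): 115, ("H", "Y"): 83, ("H", "V"): 84,
    ("I", "L"): 5, ("I", "K"): 102, ("I", "M"): 10, ("I", "F"): 21, ("I", "P"): 95,
    ("I", "S"): 142, ("I", "T"): 89, ("I", "W"): 61, ("I", "Y"): 33, ("I", "V"): 30,
    ("L", "K"): 106, ("L", "M"): 14, ("L", "F"): 22, ("L", "P"): 98, ("L", "S"): 144,
    ("L", "T"): 92, ("L", "W"): 61, ("L", "Y"): 36, ("L", "V"): 32, ("K", "M"): 94,
    ("K", "F"): 102, ("K", "P"): 103, ("K", "S"): 121, ("K", "T"): 78, ("K", "W"): 109,
    ("K", "Y"): 85, ("K", "V"): 97, ("M", "F"): 29, ("M", "P"): 87, ("M", "S"): 135,
    ("M", "T"): 81, ("M", "W"): 67, ("M", "Y"): 35, ("M", "V"): 22, ("F", "P"): 114,
    ("F", "S"): 155, ("F", "T"): 103, ("F", "W"): 40, ("F", "Y"): 22, ("F", "V"): 50,
    ("P", "S"): 73, ("P", "T"): 38, ("P", "W"): 147, ("P", "Y"): 110, ("P", "V"): 68,
    ("S", "T"): 58, ("S", "W"): 177, ("S", "Y"): 143, ("S", "V"): 123, ("T", "W"): 128,
    ("T", "Y"): 92, ("T", "V"): 69, ("W", "Y"): 37, ("W", "V"): 88, ("Y", "V"): 55,
}


class UndefinedResidueError(KeyError):
    """Raised for 'X' or any letter outside the 20 standard residues."""


@dataclass(frozen=True)
class GranthamModel:
    """Holds the property triples, weights, scale and the derived 20x20 table."""

    properties: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GRANTHAM_PROPERTIES)
    )
    weights: tuple[float, float, float] = GRANTHAM_WEIGHTS
    scale: float = GRANTHAM_SCALE
    matrix: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(GRANTHAM_MATRIX)
    )

    def __post_init__(self) -> None:
        # dense lookup array indexed by ord(residue); -1 marks undefined letters
        idx = np.full(128, -1, dtype=np.int64)
        for i, aa in enumerate(AMINO_ACIDS):
            idx[ord(aa)] = i
        dense = np.zeros((20, 20), dtype=float)
        for (a, b), d in self.matrix.items():
            ia, ib = idx[ord(a)], idx[ord(b)]
            dense[ia, ib] = dense[ib, ia] = float(d)
        object.__setattr__(self, "_index", idx)
        object.__setattr__(self, "_dense", dense)

    def distance(self, residue_a: str, residue_b: str) -> float:
        """Packaged-table distance between two one-letter residues."""
        ia = self._index[ord(residue_a)] if len(residue_a) == 1 else -1
        ib = self._index[ord(residue_b)] if len(residue_b) == 1 else -1
        if ia < 0 or ib < 0:
            bad = residue_a if ia < 0 else residue_b
            raise UndefinedResidueError(
                f"residue {bad!r} has no defined Grantham distance"
            )
        return float(self._dense[ia, ib])

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to integer residue indices (-1 for unknown/'X')."""
        codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        return self._index[codes]

    @property
    def dense_matrix(self) -> np.ndarray:
        """20x20 float view of the packaged table, ordered by AMINO_ACIDS."""
        return self._dense.copy()


def grantham_distance(residue_a: str, residue_b: str, model: GranthamModel | None = None) -> float:
    """Physicochemical distance between two amino acids (0 iff identical)."""
    return (model or default_model()).distance(residue_a, residue_b)


_DEFAULT: GranthamModel | None = None


def default_model() -> GranthamModel:
    """The shared default model built from the packaged table."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = GranthamModel()
    return _DEFAULT
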