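"""Shared domain objects: sequences, residues and template chains.

These containers are deliberately lightweight — heavyweight parsing and
serialization live in :mod:`mrpilot.formats_io`, numerics in the modules
that own each operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA1 = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = set(AA1) | {"X"}

AA1_TO_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}

#: Average residue masses (Da, water subtracted); X falls back to the mean.
RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
    "X": 110.0,
}
WATER_MASS = 18.02


def sequence_weight(residues: str) -> float:
    """Average molecular weight in Da of a one-letter protein sequence."""
    return sum(RESIDUE_MASS.get(c, RESIDUE_MASS["X"]) for c in residues) + WATER_MASS


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence (one-letter code, ``X`` allowed)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Atom:
    name: str
    pos: np.ndarray  # shape (3,), Å
    element: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.element:
            self.element = self.name[:1]


@dataclass
class Residue:
    """One residue: 3-letter name, source-numbering id and its heavy atoms."""

    name: str
    seqid: int
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def ca(self) -> Atom | None:
        return self.atoms.get("CA")

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def copy(self) -> "Residue":
        return Residue(
            self.name,
            self.seqid,
            {n: Atom(a.name, a.pos.copy(), a.element) for n, a in self.atoms.items()},
        )


@dataclass
class ChainEntry:
    """One template chain of the search-model library.

    ``ca_coords`` is the ordered (L, 3) array of Cα positions; ``residues``
    optionally carries the full heavy-atom records needed for side-chain
    editing. ``resolution`` is in Å and absent (None) when the source header
    does not state it.
    """

    entry_id: str
    sequence: Sequence
    ca_coords: np.ndarray
    resolution: float | None = None
    residues: list[Residue] | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError(
                f"{self.entry_id}: sequence length {len(self.sequence)} != "
                f"{len(self.ca_coords)} CA coordinates"
            )
        if self.residues is not None and len(self.residues) != len(self.sequence):
            raise ValueError(f"{self.entry_id}: residue records do not match sequence")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be positive")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def seqids(self) -> list[int]:
        if self.residues is not None:
            return [r.seqid for r in self.residues]
        return list(range(1, self.length + 1))

    @property
    def structure_id(self) -> str:
        """Source structure (PDB-file) part of the entry id, e.g. 1abc of 1abc_A."""
        return self.entry_id.rsplit("_", 1)[0]
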