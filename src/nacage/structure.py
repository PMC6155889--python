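"""Pseudo-atom structure container shared by the builder and I/O layers.

A :class:`Structure` is a flat list of pseudo-atoms, each identified by
``(strand_id, residue_index, atom_name)``, with Cartesian coordinates in
Angstrom and optional per-residue region annotations ("helix" edge or
"linker" vertex membership) attached by the cage builder.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import InvalidArgumentError

#: canonical atom-name spelling (remediated-PDB primes normalised to ``*``)
CANONICAL_ATOMS = {"P", "O4*", "C4*", "C2"}


def normalize_atom_name(name: str) -> str:
    """Map prime-dialect names (O4', C4') onto the ``*`` spelling."""
    return name.strip().replace("'", "*")


@dataclass(frozen=True)
class Atom:
    strand_id: str
    residue_index: int  # 1-based, chain-scoped
    residue_name: str   # A / C / G / T
    atom_name: str      # P, O4*, C4*, C2, ...
    position: np.ndarray  # (3,) Angstrom

    def key(self) -> tuple:
        return (self.strand_id, self.residue_index, self.atom_name)


@dataclass
class ResidueAnnotation:
    """Region membership of one residue within the cage."""

    region: str            # "helix" | "linker"
    element_index: int     # edge index for helix, vertex index for linker
    duplex_strand: Optional[str] = None  # "A"/"B" within the edge duplex


@dataclass
class Structure:
    """An all-pseudo-atom nucleic-acid model."""

    atoms: list[Atom] = field(default_factory=list)
    #: (strand_id, residue_index) -> ResidueAnnotation
    annotations: dict[tuple[str, int], ResidueAnnotation] = field(default_factory=dict)
    #: optional per-atom scalar written into the PDB B-factor column
    bfactors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        keys = [a.key() for a in self.atoms]
        if len(keys) != len(set(keys)):
            raise InvalidArgumentError(
                "duplicate (strand_id, residue_index, atom_name) triples")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len({(a.strand_id, a.residue_index) for a in self.atoms})

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def strand_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.strand_id, None)
        return list(seen)

    def residues(self) -> Iterator[tuple[tuple[str, int], list[Atom]]]:
        """Yield ((strand_id, residue_index), atoms) in (strand, index) order."""
        groups: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault((a.strand_id, a.residue_index), []).append(a)
        for key in sorted(groups):
            yield key, groups[key]

    def region_of(self, strand_id: str, residue_index: int) -> Optional[str]:
        ann = self.annotations.get((strand_id, residue_index))
        return ann.region if ann is not None else None

    def with_bfactors(self, values: np.ndarray) -> "Structure":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_atoms,):
            raise InvalidArgumentError(
                f"expected {self.n_atoms} per-atom scalars, got {values.shape}")
        return Structure(atoms=self.atoms, annotations=self.annotations,
                         bfactors=values)
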