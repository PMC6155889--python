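"""PDB reading/writing and coarse-grained node selection.

The pseudo-atom structures used here are small enough that plain
fixed-width ATOM records cover every need; both the legacy ``*`` and
remediated ``'`` atom-name dialects are accepted on input and normalised
to ``*`` internally. Node selection implements the three coarse-graining
levels used throughout the analysis: one node (P), two nodes (P, O4*) or
three nodes (P, C4*, C2) per nucleotide.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import (EmptySelectionError, FormatCapacityError,
                     InvalidArgumentError, ParseError)
from .structure import Atom, Structure, normalize_atom_name

#: node roles per representation level, in within-residue order
LEVEL_ROLES = {1: ("P",), 2: ("P", "O4*"), 3: ("P", "C4*", "C2")}

_RESNAME_IN = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
               "A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}
_RESNAME_OUT = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}


@dataclass
class NodeModel:
    """Coarse-grained node set at one representation level."""

    level: int
    positions: np.ndarray                      # (N, 3) Angstrom
    #: per node: (strand_id, residue_index, atom_role, region-or-None)
    node_meta: list[tuple[str, int, str, Optional[str]]]
    source: Optional[Structure] = None
    #: residues skipped because a required role atom was missing
    selection_log: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_meta)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (strand_id, residue_index) keys in node order."""
        out, seen = [], set()
        for sid, resi, _, _ in self.node_meta:
            if (sid, resi) not in seen:
                seen.add((sid, resi))
                out.append((sid, resi))
        return out

    def residue_of_node(self) -> np.ndarray:
        """Index of each node's residue within :meth:`residue_keys`."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array([keys[(sid, resi)]
                         for sid, resi, _, _ in self.node_meta])


def select_nodes(structure: Structure, level: int) -> NodeModel:
    """Pick the coarse-grained nodes of ``structure`` at a representation level.

    Residues missing a required role atom contribute no node for that role;
    each skip is recorded in the returned model's ``selection_log``
    (substituting a different atom would silently rewire the elastic
    network, so it is never done).
    """
    if level not in LEVEL_ROLES:
        raise InvalidArgumentError(f"level must be 1, 2 or 3, got {level!r}")
    roles = LEVEL_ROLES[level]
    positions, meta, log = [], [], []
    for (sid, resi), atoms in structure.residues():
        by_name = {a.atom_name: a for a in atoms}
        region = structure.region_of(sid, resi)
        for role in roles:
            a = by_name.get(role)
            if a is None:
                log.append(f"{sid}:{resi} missing {role}; skipped")
                continue
            positions.append(a.position)
            meta.append((sid, resi, role, region))
    if not meta:
        raise EmptySelectionError(
            f"no nodes selected at level {level} from "
            f"{structure.n_residues}-residue structure")
    return NodeModel(level=level, positions=np.array(positions, dtype=float),
                     node_meta=meta, source=structure, selection_log=log)


# ---------------------------------------------------------------------------
# PDB I/O


def _chain_map(strand_ids: list[str]) -> dict[str, str]:
    """Order-preserving map of strand ids onto single PDB chain characters."""
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    ordered = sorted(strand_ids)
    if len(ordered) > len(alphabet):
        raise FormatCapacityError("more strands than PDB chain identifiers")
    return {sid: alphabet[i] for i, sid in enumerate(ordered)}


def _format_atom_name(name: str) -> str:
    """PDB columns 13-16; prime dialect on output."""
    name = name.replace("*", "'")
    # single-char element names start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(structure: Structure, path) -> None:
    """Write ``structure`` as standard fixed-width PDB ATOM records.

    Chain IDs are assigned from sorted strand ids; occupancy is 1.00 and
    the B-factor column carries ``structure.bfactors`` when attached
    (used to export fluctuation profiles for structure coloring).
    """
    if structure.n_atoms == 0:
        raise InvalidArgumentError("cannot write an empty Structure")
    if structure.n_atoms > 99999:
        raise FormatCapacityError(
            f"{structure.n_atoms} atoms exceed the PDB serial capacity")
    chains = _chain_map(structure.strand_ids())
    bf = structure.bfactors
    role_rank = {"P": 0, "O4*": 1, "C4*": 2, "C2": 3}
    lines = []
    serial = 0
    prev_chain = None
    atoms_sorted = sorted(
        range(len(structure.atoms)),
        key=lambda i: (structure.atoms[i].strand_id,
                       structure.atoms[i].residue_index,
                       role_rank.get(structure.atoms[i].atom_name, 9),
                       structure.atoms[i].atom_name))
    for idx in atoms_sorted:
        a = structure.atoms[idx]
        chain = chains[a.strand_id]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        b = float(bf[idx]) if bf is not None else 0.0
        resname = _RESNAME_OUT.get(a.residue_name, a.residue_name)
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:5d} {_format_atom_name(a.atom_name)} "
            f"{resname:>3s} {chain}{a.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        name = normalize_atom_name(line[12:16])
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resi = int(line[22:26])
        if line[26].strip():
            raise ParseError(
                f"line {lineno}: insertion codes are not supported")
        pos = np.array([float(line[30:38]), float(line[38:46]),
                        float(line[46:54])])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record") from exc
    return Atom(chain, resi, _RESNAME_IN.get(resname, resname), name, pos)


def read_pdb(path) -> Structure:
    """Parse ATOM/HETATM records of a PDB file into a :class:`Structure`.

    Only the first MODEL of a multi-model file is read (use
    :func:`nacage.ensemble.read_ensemble` for trajectories). Atom names in
    the prime dialect are normalised to the ``*`` spelling.
    """
    text = Path(path).read_text()
    atoms: list[Atom] = []
    bfactors: list[float] = []
    in_model = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model += 1
            if in_model > 1:
                break
        elif rec == "ENDMDL" and in_model >= 1:
            break
        elif rec in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
            try:
                bfactors.append(float(line[60:66]))
            except (ValueError, IndexError):
                bfactors.append(0.0)
    if not atoms:
        raise ParseError(f"{path}: no ATOM records found")
    return Structure(atoms=atoms, bfactors=np.array(bfactors))
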