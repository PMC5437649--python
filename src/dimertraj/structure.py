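"""Core domain model: atoms, structures, trajectories and atom selections.

Coordinates are always ångström, stored as ``numpy`` arrays. Residue identity
follows the author numbering of the input file; the analysis configuration maps
chains to the human numbering used in the literature (TWIST1 108–164, E12
548–594), so nothing in this module renumbers anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "StructureError",
    "resolve_selection",
]


class StructureError(ValueError):
    """Raised for inconsistent structures/trajectories (atom-count mismatch...)."""


#: 3-letter codes treated as protein residues (standard set plus common variants).
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP
       TYR VAL MSE SEC PYL HSD HSE HSP CYX HID HIE HIP""".split()
)

#: Residue codes treated as nucleic acids (DNA/RNA, PDB v2 and v3 styles).
NUCLEOTIDES = frozenset(
    """DA DT DG DC DU A T G C U ADE THY GUA CYT URA DA3 DT3 DG3 DC3 DA5 DT5
       DG5 DC5""".split()
)

_ELEMENTS_2 = frozenset(
    "BR CL FE MG MN ZN NA CA CU CO NI SE CD HG".split()
)  # two-letter elements that can start an atom name


def moiety_of(residue_name: str) -> str:
    rn = residue_name.strip().upper()
    if rn in AMINO_ACIDS:
        return "protein"
    if rn in NUCLEOTIDES:
        return "nucleic"
    return "other"


def guess_element(name: str, residue_name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Handles the ``1HZ``/``HZ1`` hydrogen disambiguation: a leading digit always
    denotes a hydrogen naming variant in standard residues.
    """
    n = name.strip().upper()
    if not n:
        return ""
    if n[0].isdigit():
        return n[1] if len(n) > 1 else ""
    if moiety_of(residue_name) in ("protein", "nucleic"):
        # standard residues contain H C N O S P only
        return n[0]
    if n[:2] in _ELEMENTS_2:
        return n[:2].capitalize()
    return n[0]


@dataclass(frozen=True)
class Atom:
    """One atom of the topology. ``residue_seq`` is author numbering."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    is_hydrogen: bool
    moiety: str

    @classmethod
    def make(
        cls,
        serial: int,
        name: str,
        residue_name: str,
        residue_seq: int,
        chain_id: str,
        element: str = "",
    ) -> "Atom":
        elem = element.strip().capitalize() if element.strip() else guess_element(
            name, residue_name
        )
        return cls(
            serial=serial,
            name=name.strip(),
            element=elem,
            residue_name=residue_name.strip(),
            residue_seq=residue_seq,
            chain_id=chain_id,
            is_hydrogen=elem.upper() in ("H", "D"),
            moiety=moiety_of(residue_name),
        )

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Structure:
    """An atom table plus a single coordinate set (n_atoms × 3, Å)."""

    def __init__(self, atoms: Sequence[Atom], coordinates: np.ndarray):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (len(atoms), 3):
            raise StructureError(
                f"coordinate array of shape {coordinates.shape} does not match "
                f"{len(atoms)} atoms"
            )
        seen: set[tuple[str, int, str]] = set()
        for a in atoms:
            key = (a.chain_id, a.residue_seq, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key} in structure")
            seen.add(key)
        self.atoms: list[Atom] = list(atoms)
        self.coordinates = coordinates

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, chain_id: str, residue_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.name == name
            ):
                return i
        raise KeyError(f"no atom {name} in residue {chain_id}{residue_seq}")

    def residue_atoms(self, chain_id: str, residue_seq: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered (chain, seq, residue_name) triples, first-occurrence order."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                out.append((a.chain_id, a.residue_seq, a.residue_name))
        return out


class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3); frame spacing defaults to the
    10-ps sampling conventional for the simulations this package analyses.
    """

    def __init__(
        self,
        structure: Structure,
        frames: np.ndarray,
        frame_interval_ps: float = 10.0,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (structure.n_atoms, 3):
            raise StructureError(
                f"frame array of shape {frames.shape} does not match "
                f"{structure.n_atoms} atoms"
            )
        if frame_interval_ps <= 0:
            raise StructureError("frame_interval_ps must be > 0")
        self.structure = structure
        self.frames = frames
        self.frame_interval_ps = float(frame_interval_ps)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


@dataclass(frozen=True)
class Selection:
    """Declarative atom filter; resolution order follows the atom table.

    ``residue_range`` is inclusive on both ends in author numbering.
    The "NoH" selection of the flexibility analyses is
    ``Selection(exclude_hydrogens=True)``.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    exclude_hydrogens: bool = False

    def __post_init__(self):
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if not (lo <= atom.residue_seq <= hi):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.exclude_hydrogens and atom.is_hydrogen:
            return False
        return True


NO_HYDROGEN = Selection(exclude_hydrogens=True)


def resolve_selection(selection: Selection, structure: Structure) -> np.ndarray:
    """Resolve a Selection to a strictly increasing atom-index array.

    Pure function of its arguments; an empty result is legal (downstream
    metric operations reject it themselves).
    """
    idx = [i for i, a in enumerate(structure.atoms) if selection.matches(a)]
    return np.asarray(idx, dtype=int)
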