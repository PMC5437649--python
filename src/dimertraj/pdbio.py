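"""Fixed-column PDB reading and writing (ATOM/HETATM/MODEL/ENDMDL).

Scope is deliberately narrow: the model-built coordinate files this package
consumes have no insertion codes and at most blank/'A' alternate locations.
Multi-model files become trajectories, single-model files become structures.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np

from .structure import Atom, Structure, StructureError, Trajectory

__all__ = ["read_pdb", "write_pdb", "PdbParseError"]


class PdbParseError(ValueError):
    """Malformed fixed-column record; message names the offending line."""


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip() or line[17:21].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if icode:
        raise PdbParseError(
            f"insertion code {icode!r} at line {lineno}: insertion codes are not supported"
        )
    if altloc not in ("", "A"):
        # alternate conformer B+ — dropped, flagged by returning None upstream
        raise _SkipAtom()
    atom = Atom.make(serial, name, resname, resseq, chain, element)
    return atom, (x, y, z)


class _SkipAtom(Exception):
    pass


def read_pdb(path, frame_interval_ps: float = 10.0) -> Union[Structure, Trajectory]:
    """Read a PDB file into a Structure (≤1 MODEL) or Trajectory (≥2 MODELs).

    Atom order is file order; moiety is assigned from the residue name against
    the canonical amino-acid / nucleotide tables. Atoms with alternate location
    indicators other than blank or 'A' are dropped.
    """
    models: list[tuple[list[Atom], list[tuple[float, float, float]]]] = []
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    in_model = False
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                n_models += 1
                atoms, coords = [], []
            elif rec == "ENDMDL":
                models.append((atoms, coords))
                atoms, coords = [], []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    atom, xyz = _parse_atom_line(line, lineno)
                except _SkipAtom:
                    continue
                atoms.append(atom)
                coords.append(xyz)
    if in_model and atoms:
        models.append((atoms, coords))
    if not models and atoms:
        models.append((atoms, coords))
    if not models or not models[0][0]:
        raise PdbParseError(f"{path}: no ATOM/HETATM records found")

    first_atoms, first_coords = models[0]
    structure = Structure(first_atoms, np.asarray(first_coords))
    if len(models) == 1:
        return structure

    frames = np.empty((len(models), structure.n_atoms, 3))
    for k, (matoms, mcoords) in enumerate(models):
        if len(matoms) != structure.n_atoms:
            raise StructureError(
                f"{path}: MODEL {k + 1} has {len(matoms)} atoms, "
                f"expected {structure.n_atoms}"
            )
        frames[k] = mcoords
    return Trajectory(structure, frames, frame_interval_ps=frame_interval_ps)


def _format_atom_name(atom: Atom) -> str:
    # one-letter elements start in column 14, longer names hug column 13
    name = atom.name
    if len(name) < 4 and len(atom.element) < 2:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: Atom, xyz: np.ndarray, serial: int) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d} {_format_atom_name(atom)} "
        f"{atom.residue_name:<3s} {atom.chain_id:1s}{atom.residue_seq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def write_pdb(obj: Union[Structure, Trajectory], path) -> None:
    """Write a Structure (plain) or Trajectory (MODEL/ENDMDL blocks).

    Coordinates must be finite and fit the fixed 8.3 column (|x| < 10000 Å);
    violations raise before any bytes are written.
    """
    if isinstance(obj, Trajectory):
        structure, frames = obj.structure, obj.frames
    else:
        structure, frames = obj, obj.coordinates[None]
    if not np.all(np.isfinite(frames)):
        raise ValueError("non-finite coordinates cannot be written to PDB")
    if np.any(np.abs(frames) >= 10000.0) or np.any(frames <= -1000.0):
        raise ValueError("coordinates exceed the PDB fixed-column range")

    lines: list[str] = []
    multi = frames.shape[0] > 1
    for k in range(frames.shape[0]):
        if multi:
            lines.append(f"MODEL     {k + 1:>4d}\n")
        for i, atom in enumerate(structure.atoms):
            lines.append(_atom_line(atom, frames[k, i], serial=(i + 1) % 100000))
        if multi:
            lines.append("ENDMDL\n")
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
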