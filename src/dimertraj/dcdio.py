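"""CHARMM/X-PLOR DCD binary trajectory reading and writing.

The DCD container is a sequence of Fortran unformatted records, each framed by
4-byte length markers. Endianness is auto-detected from the first marker
(which must read 84). Fixed-atom compression and the CHARMM 4-D extension are
rejected explicitly rather than mis-read.
"""

from __future__ import annotations

import struct

import numpy as np

from .structure import Structure, StructureError, Trajectory

__all__ = ["read_dcd", "write_dcd", "DcdError"]


class DcdError(IOError):
    pass


def _read_record(fh, endian: str) -> bytes:
    head = fh.read(4)
    if len(head) == 0:
        raise EOFError
    if len(head) < 4:
        raise DcdError("truncated record marker")
    (n,) = struct.unpack(endian + "i", head)
    payload = fh.read(n)
    tail = fh.read(4)
    if len(payload) < n or len(tail) < 4:
        raise DcdError("truncated record payload")
    (n2,) = struct.unpack(endian + "i", tail)
    if n2 != n:
        raise DcdError(f"record marker mismatch ({n} vs {n2})")
    return payload


def _write_record(fh, payload: bytes) -> None:
    marker = struct.pack("<i", len(payload))
    fh.write(marker + payload + marker)


def read_dcd(path, structure: Structure, frame_interval_ps: float = 10.0) -> Trajectory:
    """Read a DCD file against a known topology.

    The DCD natom header field must match the structure's atom count. A
    truncated final frame raises an I/O error naming the last complete frame.
    """
    with open(path, "rb") as fh:
        first = fh.read(4)
        if len(first) < 4:
            raise DcdError(f"{path}: not a DCD file (too short)")
        if struct.unpack("<i", first)[0] == 84:
            endian = "<"
        elif struct.unpack(">i", first)[0] == 84:
            endian = ">"
        else:
            raise DcdError(f"{path}: unrecognized DCD header (bad first marker)")
        fh.seek(0)

        header = _read_record(fh, endian)
        if header[:4] != b"CORD":
            raise DcdError(f"{path}: missing CORD magic")
        icntrl = struct.unpack(endian + "20i", header[4:84])
        charmm_version = icntrl[19]
        n_fixed = icntrl[8]
        has_cell = charmm_version > 0 and icntrl[10] != 0
        is_4d = charmm_version > 0 and icntrl[11] != 0
        if n_fixed > 0:
            raise DcdError(f"{path}: fixed-atom DCD compression is not supported")
        if is_4d:
            raise DcdError(f"{path}: 4-D CHARMM trajectories are not supported")

        _read_record(fh, endian)  # title block
        natom_rec = _read_record(fh, endian)
        (natom,) = struct.unpack(endian + "i", natom_rec[:4])
        if natom != structure.n_atoms:
            raise StructureError(
                f"{path}: DCD holds {natom} atoms but the structure has "
                f"{structure.n_atoms}"
            )

        frames: list[np.ndarray] = []
        while True:
            try:
                if has_cell:
                    _read_record(fh, endian)
                xs = _read_record(fh, endian)
                ys = _read_record(fh, endian)
                zs = _read_record(fh, endian)
            except EOFError:
                break
            except DcdError as exc:
                raise DcdError(
                    f"{path}: truncated frame after {len(frames)} complete "
                    f"frame(s): {exc}"
                ) from exc
            dt = np.dtype(endian + "f4")
            frame = np.empty((natom, 3))
            frame[:, 0] = np.frombuffer(xs, dtype=dt, count=natom)
            frame[:, 1] = np.frombuffer(ys, dtype=dt, count=natom)
            frame[:, 2] = np.frombuffer(zs, dtype=dt, count=natom)
            frames.append(frame)

    arr = (
        np.asarray(frames)
        if frames
        else np.empty((0, structure.n_atoms, 3))
    )
    return Trajectory(structure, arr, frame_interval_ps=frame_interval_ps)


def write_dcd(trajectory: Trajectory, path) -> None:
    """Write a CHARMM-style (version 24) little-endian DCD, no unit cell."""
    frames = trajectory.frames
    if not np.all(np.isfinite(frames)):
        raise ValueError("non-finite coordinates cannot be written to DCD")
    n_frames, natom, _ = frames.shape
    icntrl = [0] * 20
    icntrl[0] = n_frames
    icntrl[1] = 0  # first step
    icntrl[2] = 1  # save interval
    icntrl[3] = n_frames
    icntrl[19] = 24  # CHARMM version → CHARMM header dialect
    header = b"CORD"
    for i, v in enumerate(icntrl):
        if i == 9:  # delta (frame spacing) as float32 in CHARMM dialect
            header += struct.pack("<f", float(trajectory.frame_interval_ps))
        else:
            header += struct.pack("<i", v)
    title = b"* written by dimertraj".ljust(80)
    with open(path, "wb") as fh:
        _write_record(fh, header)
        _write_record(fh, struct.pack("<i", 1) + title)
        _write_record(fh, struct.pack("<i", natom))
        for k in range(n_frames):
            for axis in range(3):
                _write_record(
                    fh, frames[k, :, axis].astype("<f4").tobytes()
                )
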