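"""Superposition and flexibility metrics.

Implements optimal rigid-body superposition (Kabsch, SVD with the proper-
rotation sign correction), the per-frame 1D-RMSD series of a trajectory
against its first frame over a heavy-atom ("NoH") selection, and the windowed
per-residue RMSF profile (window 5 frames, step 1 by default).

No mass weighting anywhere: all atoms in a selection count equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import (
    NO_HYDROGEN,
    Selection,
    Structure,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "GeometryError",
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "kabsch",
    "superpose_frames",
    "rmsd_series",
    "rmsf_profile",
    "intercopy_rmsd",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation minimizing RMSD of mobile onto reference.

    The optimal map is ``x ↦ x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_nondegenerate(coords: np.ndarray, label: str) -> None:
    centered = coords - coords.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(svals[0], 1.0)
    if svals[1] < 1e-10 * scale:
        raise GeometryError(f"{label} point set is collinear or degenerate")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper superposition of ``mobile`` onto ``reference``.

    Both inputs are (n, 3) with n ≥ 3 and must not be collinear. Reflections
    are excluded by flipping the sign of the smallest singular vector when the
    correlation matrix has negative determinant.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("mobile and reference must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 points")
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(reference, "reference")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    aligned = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


@dataclass(frozen=True)
class RmsdSeries:
    """Per-frame RMSD (Å) versus frame 0, after superposition on frame 0."""

    values: np.ndarray
    times_ps: np.ndarray
    selection: Selection

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RmsfProfile:
    """Windowed per-residue RMSF (Å), keyed by (chain_id, residue_seq)."""

    per_residue: dict[tuple[str, int], float]
    residue_names: dict[tuple[str, int], str]
    window_frames: int
    step_frames: int

    def as_array(self, keys=None) -> np.ndarray:
        keys = list(self.per_residue) if keys is None else keys
        return np.array([self.per_residue[k] for k in keys])


def superpose_frames(
    trajectory: Trajectory, selection: Selection = NO_HYDROGEN
) -> np.ndarray:
    """Align every frame on frame 0 over ``selection``; returns (F, n_sel, 3).

    Only the selected atoms are returned, already transformed.
    """
    idx = resolve_selection(selection, trajectory.structure)
    if len(idx) < 3:
        raise GeometryError(
            f"selection resolves to {len(idx)} atoms; at least 3 are required"
        )
    sub = trajectory.frames[:, idx, :]
    ref = sub[0]
    out = np.empty_like(sub)
    out[0] = ref
    for k in range(1, sub.shape[0]):
        out[k] = kabsch(sub[k], ref).apply(sub[k])
    return out


def rmsd_series(
    trajectory: Trajectory, selection: Selection = NO_HYDROGEN
) -> RmsdSeries:
    """1D-RMSD of every frame against frame 0 over ``selection``.

    Each frame is optimally superposed on the first frame over the same
    selection before the deviation is measured (the "align all frames on the
    first frame" convention). The default selection is all non-hydrogen atoms.
    """
    idx = resolve_selection(selection, trajectory.structure)
    if len(idx) < 3:
        raise GeometryError(
            f"selection resolves to {len(idx)} atoms; at least 3 are required"
        )
    sub = trajectory.frames[:, idx, :]
    ref = sub[0]
    values = np.empty(sub.shape[0])
    values[0] = 0.0
    for k in range(1, sub.shape[0]):
        values[k] = kabsch(sub[k], ref).rmsd
    return RmsdSeries(values=values, times_ps=trajectory.times_ps(), selection=selection)


def rmsf_profile(
    trajectory: Trajectory,
    selection: Selection = NO_HYDROGEN,
    window_frames: int = 5,
    step_frames: int = 1,
    align_selection: Selection | None = None,
) -> RmsfProfile:
    """Sliding-window per-residue RMSF.

    The trajectory is first aligned on frame 0 over ``align_selection``
    (default: the same selection as the profile, mirroring an alignment of
    the whole dimer). Then, for every window of ``window_frames`` consecutive
    frames advancing by ``step_frames``:

    * per-atom RMSF = RMS deviation from the window-mean position,
    * per-residue value = mean over the residue's selected atoms,

    and the final profile is the mean over windows.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be ≥ 2")
    if step_frames < 1:
        raise ValueError("step_frames must be ≥ 1")
    if trajectory.n_frames < window_frames:
        raise GeometryError(
            f"trajectory has {trajectory.n_frames} frames, "
            f"window needs {window_frames}"
        )
    structure = trajectory.structure
    idx = resolve_selection(selection, structure)
    if len(idx) == 0:
        raise GeometryError("selection resolves to no atoms")

    align_sel = selection if align_selection is None else align_selection
    aidx = resolve_selection(align_sel, structure)
    if len(aidx) < 3:
        raise GeometryError("alignment selection needs at least 3 atoms")
    # compute alignment on align_sel, apply to the profile atoms
    frames = np.empty((trajectory.n_frames, len(idx), 3))
    frames[0] = trajectory.frames[0, idx, :]
    ref = trajectory.frames[0, aidx, :]
    for k in range(1, trajectory.n_frames):
        sp = kabsch(trajectory.frames[k, aidx, :], ref)
        frames[k] = sp.apply(trajectory.frames[k, idx, :])

    # residue bookkeeping over the selected atoms
    keys: list[tuple[str, int]] = []
    names: dict[tuple[str, int], str] = {}
    groups: dict[tuple[str, int], list[int]] = {}
    for j, i in enumerate(idx):
        a = structure.atoms[i]
        k = a.residue_key
        if k not in groups:
            groups[k] = []
            keys.append(k)
            names[k] = a.residue_name
        groups[k].append(j)

    starts = range(0, trajectory.n_frames - window_frames + 1, step_frames)
    per_res_sum = {k: 0.0 for k in keys}
    n_windows = 0
    for s in starts:
        win = frames[s : s + window_frames]
        mean = win.mean(axis=0)
        atom_rmsf = np.sqrt(np.mean(np.sum((win - mean) ** 2, axis=2), axis=0))
        for k in keys:
            per_res_sum[k] += float(np.mean(atom_rmsf[groups[k]]))
        n_windows += 1
    per_residue = {k: per_res_sum[k] / n_windows for k in keys}
    return RmsfProfile(
        per_residue=per_residue,
        residue_names=names,
        window_frames=window_frames,
        step_frames=step_frames,
    )


def intercopy_rmsd(
    structure: Structure,
    chain_map: dict[str, str],
    atom_names: frozenset[str] | set[str] | None = frozenset({"CA"}),
) -> float:
    """RMSD between two copies of a complex within one structure.

    ``chain_map`` maps each chain of copy 1 to its counterpart in copy 2
    (e.g. ``{"A": "C", "B": "D"}`` for a crystal with two copies in the
    asymmetric unit). Atoms are paired by (mapped chain, residue_seq, name)
    over the intersection of the two copies, restricted to ``atom_names``
    (None = all heavy atoms), then optimally superposed.
    """
    table: dict[tuple[str, int, str], int] = {}
    for i, a in enumerate(structure.atoms):
        table[(a.chain_id, a.residue_seq, a.name)] = i
    ia: list[int] = []
    ib: list[int] = []
    for i, a in enumerate(structure.atoms):
        if a.chain_id not in chain_map or a.is_hydrogen:
            continue
        if atom_names is not None and a.name not in atom_names:
            continue
        j = table.get((chain_map[a.chain_id], a.residue_seq, a.name))
        if j is not None:
            ia.append(i)
            ib.append(j)
    if len(ia) < 3:
        raise GeometryError("fewer than 3 paired atoms between the two copies")
    return kabsch(
        structure.coordinates[ia], structure.coordinates[ib]
    ).rmsd
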