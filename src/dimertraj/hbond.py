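"""Hydrogen-bond persistence scoring.

The statistic at the heart of this package: every candidate donor–H···acceptor
pair is scored per frame with a binary indicator — 1 if the hydrogen-to-
acceptor distance is strictly below the threshold (2.1 Å by default, chosen to
retain only the strongest, shortest H-bonds), 0 otherwise. The sum of scores
over the trajectory is the *cumulated occupancy*; divided by the frame count
it is the *rate of occupancy*, the fraction of simulation time the bond
persists.

Donors and acceptors are restricted to nitrogen and oxygen, giving the four
chemical classes O−H···N, O−H···O, N−H···N and N−H···O. Pairs are classified
residue–residue (R-R) or residue–base (R-base); R-base contacts are further
split by the DNA moiety they touch (nucleobase / phosphate / sugar), and a
contact is *specific* when a protein side-chain atom meets a nucleobase atom.
Backbone-phosphate and sugar contacts are non-specific.

Distance semantics are hydrogen-to-acceptor (not heavy-to-heavy); a heavy-atom
mode with its own default threshold is available through `HBondConfig` for
comparison but is never the default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Atom, Structure, Trajectory

__all__ = [
    "HBondConfig",
    "HBondPair",
    "OccupancyRecord",
    "enumerate_pairs",
    "score_occupancy",
    "score_all",
    "aggregate_occupancy",
    "percent_variation",
    "BaselineError",
    "records_table",
]

PHOSPHATE_NAMES = {"P", "O1P", "OP1", "O2P", "OP2", "O5'", "O3'", "O5*", "O3*"}
PROTEIN_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HT1", "HT2", "HT3"}


class BaselineError(ValueError):
    """Percent variation against a zero wild-type baseline is undefined."""


@dataclass(frozen=True)
class HBondConfig:
    """Scoring parameters.

    threshold_A: strict upper bound on the H···acceptor distance for a frame
        to score 1 (default 2.1 Å).
    candidate_cutoff_A: screening distance for pair enumeration; any frame
        under the threshold is necessarily under the cutoff, so screening
        never changes results (default 4.0 Å).
    heavy_atom_mode: score donor-heavy···acceptor distances instead, with
        heavy_threshold_A (default 3.0 Å). Not the default semantics.
    """

    threshold_A: float = 2.1
    candidate_cutoff_A: float = 4.0
    heavy_atom_mode: bool = False
    heavy_threshold_A: float = 3.0

    def __post_init__(self):
        thr = self.heavy_threshold_A if self.heavy_atom_mode else self.threshold_A
        if not (0 < thr <= self.candidate_cutoff_A):
            raise ValueError("need 0 < threshold ≤ candidate_cutoff")

    @property
    def effective_threshold(self) -> float:
        return self.heavy_threshold_A if self.heavy_atom_mode else self.threshold_A


@dataclass(frozen=True)
class HBondPair:
    """A donor-heavy / hydrogen / acceptor triple with its classification."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    category: str  # "R-R" or "R-base"
    dna_site: str | None = None  # nucleobase | phosphate | sugar (R-base only)
    specific: bool | None = None  # R-base only

    @property
    def label(self) -> str:
        d, h, a = self.donor, self.hydrogen, self.acceptor
        return (
            f"{d.residue_name}{d.residue_seq}.{d.chain_id}:{h.name}"
            f"->{a.residue_name}{a.residue_seq}.{a.chain_id}:{a.name}"
        )


@dataclass(frozen=True)
class OccupancyRecord:
    """Per-frame distances and binary persistence scores for one pair."""

    pair: HBondPair
    distances: np.ndarray
    scores: np.ndarray
    threshold_A: float

    @property
    def cumulated_occupancy(self) -> int:
        return int(self.scores.sum())

    @property
    def rate(self) -> float:
        return float(self.scores.mean()) if len(self.scores) else 0.0


def _normalize_h_name(name: str) -> str:
    # "1HZ" and "HZ1" are the same hydrogen under two PDB conventions
    if name and name[0].isdigit():
        return name[1:] + name[0]
    return name


def dna_site_of(name: str) -> str:
    n = name.replace("*", "'")
    if n in PHOSPHATE_NAMES:
        return "phosphate"
    if "'" in n:
        return "sugar"
    return "nucleobase"


def _is_sidechain(atom: Atom) -> bool:
    return atom.moiety == "protein" and atom.name not in PROTEIN_BACKBONE


def assign_donor_hydrogens(structure: Structure) -> dict[int, int]:
    """Map hydrogen atom index → covalently associated donor-heavy (N/O) index.

    Association is by name within the residue: a hydrogen ``HZ1`` belongs to
    the heavy atom whose name suffix matches (``NZ``); the backbone amide
    ``H``/``HN``/``HT*`` belongs to ``N``. Where names are non-standard, the
    nearest same-residue N/O within 1.3 Å (frame-0 geometry) is used.
    Hydrogens on carbon have no entry.
    """
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        by_residue.setdefault(a.residue_key, []).append(i)

    mapping: dict[int, int] = {}
    for i, h in enumerate(structure.atoms):
        if not h.is_hydrogen:
            continue
        residue = by_residue[h.residue_key]
        heavies = [
            j
            for j in residue
            if structure.atoms[j].element in ("N", "O")
        ]
        if not heavies:
            continue
        hname = _normalize_h_name(h.name)
        match = None
        if hname in ("H", "HN") or hname.startswith("HT"):
            for j in heavies:
                if structure.atoms[j].name == "N":
                    match = j
                    break
        if match is None:
            # HZ1 → NZ, HG → OG, HD21 → ND2: heavy-name suffix is a prefix of
            # the hydrogen-name suffix with only digits left over
            suffix = hname[1:]
            best_len = -1
            for j in heavies:
                hsuf = structure.atoms[j].name[1:]
                if suffix.startswith(hsuf) and suffix[len(hsuf):].isdigit() or suffix == hsuf:
                    if len(hsuf) > best_len:
                        match, best_len = j, len(hsuf)
        if match is None:
            # geometric fallback on the reference coordinates
            d = np.linalg.norm(
                structure.coordinates[heavies] - structure.coordinates[i], axis=1
            )
            k = int(np.argmin(d))
            if d[k] <= 1.3:
                match = heavies[k]
        if match is not None:
            mapping[i] = match
    return mapping


def _classify(donor: Atom, hydrogen: Atom, acceptor: Atom) -> HBondPair | None:
    moieties = {donor.moiety, acceptor.moiety}
    if moieties == {"protein"}:
        category, dna_site, specific = "R-R", None, None
    elif moieties == {"protein", "nucleic"}:
        category = "R-base"
        dna_atom = acceptor if acceptor.moiety == "nucleic" else donor
        protein_atom = donor if acceptor.moiety == "nucleic" else acceptor
        dna_site = dna_site_of(dna_atom.name)
        specific = _is_sidechain(protein_atom) and dna_site == "nucleobase"
    else:
        return None  # DNA-DNA base pairing and non-biopolymer contacts: out of scope
    return HBondPair(
        donor_index=-1,
        hydrogen_index=-1,
        acceptor_index=-1,
        donor=donor,
        hydrogen=hydrogen,
        acceptor=acceptor,
        category=category,
        dna_site=dna_site,
        specific=specific,
    )


def enumerate_pairs(
    trajectory: Trajectory, config: HBondConfig = HBondConfig()
) -> list[HBondPair]:
    """All donor–H···acceptor candidates within the screening cutoff.

    A pair is emitted iff its H···acceptor distance drops below
    ``candidate_cutoff_A`` in at least one frame; donor and acceptor within
    the same residue are excluded; each (hydrogen, acceptor) combination
    appears once. Requires an explicitly protonated topology.
    """
    structure = trajectory.structure
    h_to_donor = assign_donor_hydrogens(structure)
    if not any(a.is_hydrogen for a in structure.atoms):
        raise ValueError(
            "structure contains no hydrogens; H-bond persistence needs a "
            "protonated model (use the synthetic generator or a pre-protonated "
            "topology)"
        )
    h_indices = sorted(h_to_donor)
    acceptor_indices = [
        i
        for i, a in enumerate(structure.atoms)
        if not a.is_hydrogen and a.element in ("N", "O")
    ]
    if not h_indices or not acceptor_indices:
        return []

    h_arr = np.asarray(h_indices)
    a_arr = np.asarray(acceptor_indices)
    found: set[tuple[int, int]] = set()
    for frame in trajectory.frames:
        tree = cKDTree(frame[a_arr])
        hits = tree.query_ball_point(frame[h_arr], r=config.candidate_cutoff_A)
        for hi, lst in zip(h_indices, hits):
            for k in lst:
                found.add((hi, int(a_arr[k])))

    pairs: list[HBondPair] = []
    for hi, ai in sorted(found):
        di = h_to_donor[hi]
        donor, hydrogen, acceptor = (
            structure.atoms[di],
            structure.atoms[hi],
            structure.atoms[ai],
        )
        if acceptor.residue_key == donor.residue_key:
            continue
        base = _classify(donor, hydrogen, acceptor)
        if base is None:
            continue
        pairs.append(
            replace(base, donor_index=di, hydrogen_index=hi, acceptor_index=ai)
        )
    return pairs


def score_occupancy(
    pair: HBondPair,
    trajectory: Trajectory,
    config: HBondConfig = HBondConfig(),
) -> OccupancyRecord:
    """Per-frame strict-< scoring of one pair against the threshold.

    A frame whose distance equals the threshold exactly scores 0 ("<2.10").
    """
    probe = pair.donor_index if config.heavy_atom_mode else pair.hydrogen_index
    delta = trajectory.frames[:, probe, :] - trajectory.frames[:, pair.acceptor_index, :]
    distances = np.linalg.norm(delta, axis=1)
    threshold = config.effective_threshold
    scores = (distances < threshold).astype(np.int8)
    return OccupancyRecord(
        pair=pair, distances=distances, scores=scores, threshold_A=threshold
    )


def score_all(
    trajectory: Trajectory, config: HBondConfig = HBondConfig()
) -> list[OccupancyRecord]:
    """Enumerate and score every candidate pair."""
    return [
        score_occupancy(p, trajectory, config)
        for p in enumerate_pairs(trajectory, config)
    ]


def _record_residues(rec: OccupancyRecord) -> list[tuple[str, int]]:
    """Residues a record is attributed to.

    R-R records are attributed to both participating residues (documented
    double-attribution); R-base records to the protein residue.
    """
    p = rec.pair
    if p.category == "R-R":
        keys = {p.donor.residue_key, p.acceptor.residue_key}
        return sorted(keys)
    protein = p.donor if p.donor.moiety == "protein" else p.acceptor
    return [protein.residue_key]


def aggregate_occupancy(
    records: Sequence[OccupancyRecord],
    group_by: str,
    boxes: Sequence["DomainBox"] | None = None,
    ebox_map: "EBoxMap | None" = None,
) -> pd.DataFrame:
    """Sum cumulated occupancies by a grouping key.

    group_by ∈ {"residue", "box", "category", "specificity", "dna_position"}.
    Box grouping needs ``boxes`` (a record counts toward every box holding at
    least one of its attributed residues, plus an ``(outside)`` remainder row);
    dna_position grouping needs ``ebox_map``.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows: list[tuple[str, int]] = []
    if group_by == "residue":
        acc: dict[tuple[str, int], int] = {}
        for rec in records:
            for key in _record_residues(rec):
                acc[key] = acc.get(key, 0) + rec.cumulated_occupancy
        rows = [(f"{c}:{r}", v) for (c, r), v in sorted(acc.items())]
    elif group_by == "box":
        if boxes is None:
            raise ValueError("box grouping requires boxes")
        accb: dict[str, int] = {b.name: 0 for b in boxes}
        accb["(outside)"] = 0
        for rec in records:
            residues = _record_residues(rec)
            hit = False
            for b in boxes:
                if any(b.contains(c, r) for c, r in residues):
                    accb[b.name] += rec.cumulated_occupancy
                    hit = True
            if not hit:
                accb["(outside)"] += rec.cumulated_occupancy
        rows = list(accb.items())
    elif group_by == "category":
        accc: dict[str, int] = {}
        for rec in records:
            accc[rec.pair.category] = (
                accc.get(rec.pair.category, 0) + rec.cumulated_occupancy
            )
        rows = sorted(accc.items())
    elif group_by == "specificity":
        accs = {"specific": 0, "non-specific": 0, "R-R": 0}
        for rec in records:
            if rec.pair.category == "R-R":
                accs["R-R"] += rec.cumulated_occupancy
            elif rec.pair.specific:
                accs["specific"] += rec.cumulated_occupancy
            else:
                accs["non-specific"] += rec.cumulated_occupancy
        rows = list(accs.items())
    elif group_by == "dna_position":
        if ebox_map is None:
            raise ValueError("dna_position grouping requires an ebox_map")
        accd: dict[str, int] = {}
        for rec in records:
            if rec.pair.category != "R-base":
                continue
            p = rec.pair
            dna = p.acceptor if p.acceptor.moiety == "nucleic" else p.donor
            label = ebox_map.label_of(dna.residue_key) or "(unlabeled)"
            accd[label] = accd.get(label, 0) + rec.cumulated_occupancy
        rows = sorted(accd.items())
    else:
        raise ValueError(f"unknown grouping key {group_by!r}")
    return pd.DataFrame(rows, columns=["group", "cumulated_occupancy"])


def percent_variation(mutant_total: float, wildtype_total: float) -> tuple[float, float]:
    """Signed percent change of mutant vs wild type, plus the normalized level.

    Returns ``(variation, normalized_level)`` where the wild type is anchored
    at 100%: a mutant at 59 against a wild type at 100 gives (−41.0, 59.0).
    """
    if wildtype_total <= 0:
        raise BaselineError(
            "wild-type total is zero: percent variation has no baseline"
        )
    variation = 100.0 * (mutant_total - wildtype_total) / wildtype_total
    return variation, 100.0 + variation


def records_table(records: Sequence[OccupancyRecord]) -> pd.DataFrame:
    """One row per scored pair (the occupancy TSV layout)."""
    rows = []
    for rec in records:
        p = rec.pair
        rows.append(
            {
                "donor_chain": p.donor.chain_id,
                "donor_residue": f"{p.donor.residue_name}{p.donor.residue_seq}",
                "donor_atom": p.donor.name,
                "hydrogen": p.hydrogen.name,
                "acceptor_chain": p.acceptor.chain_id,
                "acceptor_residue": f"{p.acceptor.residue_name}{p.acceptor.residue_seq}",
                "acceptor_atom": p.acceptor.name,
                "category": p.category,
                "dna_site": p.dna_site or "",
                "specific": "" if p.specific is None else str(bool(p.specific)),
                "cumulated_occupancy": rec.cumulated_occupancy,
                "rate": rec.rate,
                "n_frames": len(rec.scores),
            }
        )
    return pd.DataFrame(rows)
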