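"""Structure-specific interface analyses.

* basic-domain separation: mean CA–CA distance between index-paired residues
  of the two basic domains (the N-terminal arms that insert into the DNA
  major groove);
* named residue-pair distance series (bottom/middle/top of the dimer, the
  N125–K145 style loop contacts) with centered moving-average smoothing;
* domain boxes A–D (the dimerization sub-domains) for occupancy aggregation;
* the E-box per-position contact profile: how the cumulated hydrogen-bond
  occupancy against DNA distributes over the flanking (−1, −1*), consensus
  (+1, +2, +1*, +2*) and variable central (+3, +4, +3*, +4*) bases;
* the wild-type versus mutant comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hbond import (
    BaselineError,
    OccupancyRecord,
    aggregate_occupancy,
    percent_variation,
)
from .structure import Selection, Trajectory, resolve_selection

__all__ = [
    "DomainBox",
    "BasicDomainSpec",
    "NamedPair",
    "EBoxMap",
    "SpecError",
    "ComparabilityError",
    "BasicDomainResult",
    "PairDistanceResult",
    "EboxProfile",
    "ComparisonReport",
    "validate_boxes",
    "basic_domain_distance",
    "pair_distance_series",
    "smooth_series",
    "ebox_profile",
    "RunSummary",
    "summarize_records",
    "compare_reports",
]

FLANKING = {"-1", "-1*"}
CONSENSUS = {"+1", "+2", "+1*", "+2*"}
VARIABLE = {"+3", "+4", "+3*", "+4*"}


class SpecError(ValueError):
    pass


class ComparabilityError(ValueError):
    """Two runs analyzed under different configurations cannot be compared."""


@dataclass(frozen=True)
class DomainBox:
    """A named inclusive residue range on one chain (boxes A–D)."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise SpecError(f"box {self.name}: range wraps ({self.start}>{self.end})")

    def contains(self, chain_id: str, residue_seq: int) -> bool:
        return chain_id == self.chain_id and self.start <= residue_seq <= self.end


def validate_boxes(boxes: Sequence[DomainBox]) -> None:
    """Boxes on the same chain may not overlap."""
    for i, a in enumerate(boxes):
        for b in boxes[i + 1 :]:
            if a.chain_id == b.chain_id and not (
                a.end < b.start or b.end < a.start
            ):
                raise SpecError(f"boxes {a.name} and {b.name} overlap on chain {a.chain_id}")


@dataclass(frozen=True)
class BasicDomainSpec:
    """Two equal-length (chain, range) arms, paired in range order."""

    chain_a: str
    range_a: tuple[int, int]
    chain_b: str
    range_b: tuple[int, int]

    def __post_init__(self):
        na = self.range_a[1] - self.range_a[0] + 1
        nb = self.range_b[1] - self.range_b[0] + 1
        if na != nb:
            raise SpecError(
                f"basic-domain ranges have unequal lengths ({na} vs {nb})"
            )


@dataclass(frozen=True)
class BasicDomainResult:
    per_frame: np.ndarray  # mean paired CA–CA distance per frame (Å)
    mean: float
    n_pairs: int


def basic_domain_distance(
    trajectory: Trajectory,
    spec: BasicDomainSpec,
    cross_product: bool = False,
) -> BasicDomainResult:
    """Per-frame mean CA–CA distance between the two basic domains.

    Default pairing is index-paired in range order (first residue of arm A
    with first of arm B, and so on); ``cross_product=True`` averages over all
    residue combinations instead.
    """
    s = trajectory.structure

    def ca_indices(chain, rng):
        sel = Selection(chain_id=chain, residue_range=rng, atom_names=frozenset({"CA"}))
        return resolve_selection(sel, s)

    ia = ca_indices(spec.chain_a, spec.range_a)
    ib = ca_indices(spec.chain_b, spec.range_b)
    if len(ia) != len(ib):
        raise SpecError(
            f"CA lists have unequal lengths ({len(ia)} vs {len(ib)}); "
            "check chain ids and residue ranges"
        )
    if len(ia) == 0:
        raise SpecError("basic-domain ranges resolve to no CA atoms")
    fa = trajectory.frames[:, ia, :]
    fb = trajectory.frames[:, ib, :]
    if cross_product:
        diff = fa[:, :, None, :] - fb[:, None, :, :]
        per_frame = np.linalg.norm(diff, axis=3).mean(axis=(1, 2))
    else:
        per_frame = np.linalg.norm(fa - fb, axis=2).mean(axis=1)
    return BasicDomainResult(
        per_frame=per_frame, mean=float(per_frame.mean()), n_pairs=len(ia)
    )


@dataclass(frozen=True)
class NamedPair:
    """A labelled residue pair measured as the minimum over atom-name sets."""

    label: str
    chain_a: str
    residue_a: int
    names_a: frozenset[str]
    chain_b: str
    residue_b: int
    names_b: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "names_a", frozenset(self.names_a))
        object.__setattr__(self, "names_b", frozenset(self.names_b))


@dataclass(frozen=True)
class PairDistanceResult:
    pair: NamedPair
    raw: np.ndarray
    smoothed: np.ndarray
    times_ps: np.ndarray


def smooth_series(values: np.ndarray, neighbors: int = 8) -> np.ndarray:
    """Centered moving average over 2·neighbors+1 points.

    The window is truncated symmetrically at the edges so the smoothed series
    has the same length and no phase shift.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        half = min(neighbors, i, n - 1 - i)
        out[i] = values[i - half : i + half + 1].mean()
    return out


def _resolve_side(trajectory, chain, residue, names):
    s = trajectory.structure
    idx = [
        i
        for i, a in enumerate(s.atoms)
        if a.chain_id == chain and a.residue_seq == residue and a.name in names
    ]
    if not idx:
        candidates = sorted(
            a.name
            for a in s.atoms
            if a.chain_id == chain and a.residue_seq == residue
        )
        raise SpecError(
            f"no atom of {sorted(names)} in residue {chain}:{residue}; "
            f"available: {candidates}"
        )
    return np.asarray(idx)


def pair_distance_series(
    trajectory: Trajectory,
    pair: NamedPair,
    smoothing_neighbors: int = 8,
) -> PairDistanceResult:
    """Raw and smoothed per-frame minimum distance for a named residue pair."""
    ia = _resolve_side(trajectory, pair.chain_a, pair.residue_a, pair.names_a)
    ib = _resolve_side(trajectory, pair.chain_b, pair.residue_b, pair.names_b)
    fa = trajectory.frames[:, ia, :]
    fb = trajectory.frames[:, ib, :]
    diff = fa[:, :, None, :] - fb[:, None, :, :]
    raw = np.linalg.norm(diff, axis=3).min(axis=(1, 2))
    return PairDistanceResult(
        pair=pair,
        raw=raw,
        smoothed=smooth_series(raw, smoothing_neighbors),
        times_ps=trajectory.times_ps(),
    )


@dataclass(frozen=True)
class EBoxMap:
    """Position labels for the DNA duplex around the E-box.

    Maps (chain_id, residue_seq) of a nucleotide to one of the labels
    −1, +1…+4 and their starred complements. +k and +k* lie on opposite
    strands; −1/−1* sit immediately 5′ of +1/+1* on their own strand.
    """

    labels: Mapping[tuple[str, int], str]

    def __post_init__(self):
        used = list(self.labels.values())
        if len(used) != len(set(used)):
            raise SpecError("each E-box position label may be used at most once")

    def label_of(self, residue_key: tuple[str, int]) -> str | None:
        return self.labels.get(tuple(residue_key))

    @staticmethod
    def group_of(label: str | None) -> str:
        if label in FLANKING:
            return "flanking"
        if label in CONSENSUS:
            return "consensus"
        if label in VARIABLE:
            return "variable"
        return "unlabeled"


@dataclass(frozen=True)
class EboxProfile:
    """Per-position shares of cumulated R-base occupancy (percent of total)."""

    percentages: dict[str, float]
    group_shares: dict[str, float]
    residue_breakdown: pd.DataFrame
    total_occupancy: int
    specific_only: bool
    empty: bool = False


def ebox_profile(
    records: Sequence[OccupancyRecord],
    ebox_map: EBoxMap,
    specific_only: bool = False,
) -> EboxProfile:
    """Distribute cumulated R-base occupancy over E-box positions.

    Percentages are relative to the total R-base cumulated occupancy (after
    the optional specific-only filter) and sum to 100 whenever that total is
    positive. Zero total yields an ``empty`` profile, not a division error.
    """
    per_pos: dict[str, int] = {}
    rows = []
    total = 0
    for rec in records:
        p = rec.pair
        if p.category != "R-base":
            continue
        if specific_only and not p.specific:
            continue
        dna = p.acceptor if p.acceptor.moiety == "nucleic" else p.donor
        protein = p.donor if dna is p.acceptor else p.acceptor
        label = ebox_map.label_of(dna.residue_key) or "(unlabeled)"
        occ = rec.cumulated_occupancy
        per_pos[label] = per_pos.get(label, 0) + occ
        total += occ
        rows.append(
            {
                "position": label,
                "residue": f"{protein.residue_name}{protein.residue_seq}.{protein.chain_id}",
                "cumulated_occupancy": occ,
            }
        )
    breakdown = pd.DataFrame(rows, columns=["position", "residue", "cumulated_occupancy"])
    if total == 0:
        return EboxProfile(
            percentages={},
            group_shares={},
            residue_breakdown=breakdown,
            total_occupancy=0,
            specific_only=specific_only,
            empty=True,
        )
    percentages = {k: 100.0 * v / total for k, v in sorted(per_pos.items())}
    groups: dict[str, float] = {}
    for label, pct in percentages.items():
        g = EBoxMap.group_of(label if label != "(unlabeled)" else None)
        groups[g] = groups.get(g, 0.0) + pct
    return EboxProfile(
        percentages=percentages,
        group_shares=groups,
        residue_breakdown=breakdown,
        total_occupancy=total,
        specific_only=specific_only,
    )


@dataclass(frozen=True)
class RunSummary:
    """Everything one analyzed trajectory contributes to a comparison.

    A flat record table (one row per persisting H-bond pair) plus the boxes
    and the configuration fingerprint; fully serializable, so a comparison
    can be rebuilt from files alone.
    """

    table: pd.DataFrame  # residues, category, specific, dna_site, ebox_label, cumulated_occupancy
    boxes: tuple[DomainBox, ...]
    fingerprint: str

    def box_totals(self, rr_only: bool) -> dict[str, int]:
        df = self.table
        if rr_only:
            df = df[df["category"] == "R-R"]
        out = {b.name: 0 for b in self.boxes}
        for _, row in df.iterrows():
            hit_boxes = set()
            for res in row["residues"]:
                chain, seq = res.split(":")
                for b in self.boxes:
                    if b.contains(chain, int(seq)):
                        hit_boxes.add(b.name)
            for name in hit_boxes:  # once per box, even if both residues lie in it
                out[name] += int(row["cumulated_occupancy"])
        return out

    def residue_totals(self) -> dict[str, int]:
        acc: dict[str, int] = {}
        for _, row in self.table.iterrows():
            for res in row["residues"]:
                acc[res] = acc.get(res, 0) + int(row["cumulated_occupancy"])
        return dict(sorted(acc.items()))

    def ebox_shares(self, specific_only: bool) -> dict[str, float]:
        df = self.table[self.table["category"] == "R-base"]
        if specific_only:
            df = df[df["specific"].astype(bool)]
        total = int(df["cumulated_occupancy"].sum())
        if total == 0:
            return {}
        sums = df.groupby("ebox_label")["cumulated_occupancy"].sum()
        return {str(k): 100.0 * v / total for k, v in sums.sort_index().items()}

    def to_json_dict(self) -> dict:
        return {
            "fingerprint": self.fingerprint,
            "boxes": [
                {"name": b.name, "chain": b.chain_id, "start": b.start, "end": b.end}
                for b in self.boxes
            ],
            "records": [
                {
                    "residues": list(row["residues"]),
                    "category": row["category"],
                    "specific": bool(row["specific"]),
                    "dna_site": row["dna_site"],
                    "ebox_label": row["ebox_label"],
                    "cumulated_occupancy": int(row["cumulated_occupancy"]),
                }
                for _, row in self.table.iterrows()
            ],
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "RunSummary":
        boxes = tuple(
            DomainBox(b["name"], b["chain"], b["start"], b["end"])
            for b in data["boxes"]
        )
        table = pd.DataFrame(
            [
                {
                    "residues": tuple(r["residues"]),
                    "category": r["category"],
                    "specific": bool(r["specific"]),
                    "dna_site": r["dna_site"],
                    "ebox_label": r["ebox_label"],
                    "cumulated_occupancy": int(r["cumulated_occupancy"]),
                }
                for r in data["records"]
            ],
            columns=_SUMMARY_COLUMNS,
        )
        return cls(table=table, boxes=boxes, fingerprint=data["fingerprint"])


_SUMMARY_COLUMNS = [
    "residues",
    "category",
    "specific",
    "dna_site",
    "ebox_label",
    "cumulated_occupancy",
]


def summarize_records(
    records: Sequence[OccupancyRecord],
    boxes: Sequence[DomainBox],
    ebox_map: EBoxMap,
    fingerprint: str,
) -> RunSummary:
    """Flatten scored occupancy records into a comparable RunSummary."""
    validate_boxes(list(boxes))
    rows = []
    for rec in records:
        p = rec.pair
        if p.category == "R-R":
            residues = tuple(
                sorted(
                    {
                        f"{p.donor.chain_id}:{p.donor.residue_seq}",
                        f"{p.acceptor.chain_id}:{p.acceptor.residue_seq}",
                    }
                )
            )
            label = ""
        else:
            dna = p.acceptor if p.acceptor.moiety == "nucleic" else p.donor
            protein = p.donor if dna is p.acceptor else p.acceptor
            residues = (f"{protein.chain_id}:{protein.residue_seq}",)
            label = ebox_map.label_of(dna.residue_key) or "(unlabeled)"
        rows.append(
            {
                "residues": residues,
                "category": p.category,
                "specific": bool(p.specific) if p.specific is not None else False,
                "dna_site": p.dna_site or "",
                "ebox_label": label,
                "cumulated_occupancy": rec.cumulated_occupancy,
            }
        )
    table = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    return RunSummary(table=table, boxes=tuple(boxes), fingerprint=fingerprint)


@dataclass(frozen=True)
class ComparisonReport:
    """Wild-type versus mutant aggregates.

    Percent variation is baseline-anchored (wild type = 100%); the delta
    fields are antisymmetric under swapping the two runs, percent variation
    is not.
    """

    box_variation_rr: dict[str, float | None]
    box_variation_all: dict[str, float | None]
    residue_deltas: dict[str, int]
    ebox_share_deltas_pp: dict[str, float]
    ebox_share_deltas_specific_pp: dict[str, float]
    fingerprint: str


def _box_variation(
    wt: RunSummary, mut: RunSummary, rr_only: bool
) -> dict[str, float | None]:
    wt_tot = wt.box_totals(rr_only)
    mut_tot = mut.box_totals(rr_only)
    out: dict[str, float | None] = {}
    for name in wt_tot:
        if name == "(outside)":
            continue
        try:
            out[name] = percent_variation(mut_tot.get(name, 0), wt_tot[name])[0]
        except BaselineError:
            out[name] = None
    return out


def _share_deltas(
    wt: RunSummary, mut: RunSummary, specific_only: bool
) -> dict[str, float]:
    pw = wt.ebox_shares(specific_only)
    pm = mut.ebox_shares(specific_only)
    labels = set(pw) | set(pm)
    return {lab: pm.get(lab, 0.0) - pw.get(lab, 0.0) for lab in sorted(labels)}


def compare_reports(wildtype: RunSummary, mutant: RunSummary) -> ComparisonReport:
    """Compare two runs analyzed under the identical configuration.

    A configuration-fingerprint mismatch is an error, not a warning: percent
    variations are meaningless across different thresholds, boxes or maps.
    """
    if wildtype.fingerprint != mutant.fingerprint:
        raise ComparabilityError(
            "configuration fingerprints differ: "
            f"{wildtype.fingerprint[:12]} vs {mutant.fingerprint[:12]}"
        )
    wt_res = wildtype.residue_totals()
    mut_res = mutant.residue_totals()
    residue_deltas = {
        k: mut_res.get(k, 0) - wt_res.get(k, 0)
        for k in sorted(set(wt_res) | set(mut_res))
    }
    return ComparisonReport(
        box_variation_rr=_box_variation(wildtype, mutant, rr_only=True),
        box_variation_all=_box_variation(wildtype, mutant, rr_only=False),
        residue_deltas=residue_deltas,
        ebox_share_deltas_pp=_share_deltas(wildtype, mutant, specific_only=False),
        ebox_share_deltas_specific_pp=_share_deltas(wildtype, mutant, specific_only=True),
        fingerprint=wildtype.fingerprint,
    )
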