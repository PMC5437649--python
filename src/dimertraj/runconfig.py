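"""Run configuration: one YAML file drives every analysis stage.

The *fingerprint* is a SHA-256 over the canonical JSON of the semantic
analysis content (threshold, boxes, domain specs, named pairs, E-box map,
window sizes — not input/output paths and not the seed). Two runs are
comparable iff their fingerprints match; `compare` enforces this.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .hbond import HBondConfig
from .profiles import BasicDomainSpec, DomainBox, EBoxMap, NamedPair

__all__ = ["RunConfig", "ConfigError", "default_run_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    topology: str
    trajectory: str
    frame_interval_ps: float = 10.0
    hbond: HBondConfig = field(default_factory=HBondConfig)
    rmsf_window_frames: int = 5
    rmsf_step_frames: int = 1
    smoothing_neighbors: int = 8
    boxes: list[DomainBox] = field(default_factory=list)
    basic_domains: BasicDomainSpec | None = None
    named_pairs: list[NamedPair] = field(default_factory=list)
    ebox_map: EBoxMap = field(default_factory=lambda: EBoxMap(labels={}))
    seed: int = 0
    log_level: str = "INFO"

    # -- comparability ---------------------------------------------------
    def semantic_dict(self) -> dict:
        return {
            "frame_interval_ps": self.frame_interval_ps,
            "hbond": {
                "threshold_A": self.hbond.threshold_A,
                "candidate_cutoff_A": self.hbond.candidate_cutoff_A,
                "heavy_atom_mode": self.hbond.heavy_atom_mode,
                "heavy_threshold_A": self.hbond.heavy_threshold_A,
            },
            "rmsf_window_frames": self.rmsf_window_frames,
            "rmsf_step_frames": self.rmsf_step_frames,
            "smoothing_neighbors": self.smoothing_neighbors,
            "boxes": [
                {"name": b.name, "chain": b.chain_id, "start": b.start, "end": b.end}
                for b in self.boxes
            ],
            "basic_domains": (
                None
                if self.basic_domains is None
                else {
                    "chain_a": self.basic_domains.chain_a,
                    "range_a": list(self.basic_domains.range_a),
                    "chain_b": self.basic_domains.chain_b,
                    "range_b": list(self.basic_domains.range_b),
                }
            ),
            "named_pairs": [
                {
                    "label": p.label,
                    "a": {
                        "chain": p.chain_a,
                        "residue": p.residue_a,
                        "names": sorted(p.names_a),
                    },
                    "b": {
                        "chain": p.chain_b,
                        "residue": p.residue_b,
                        "names": sorted(p.names_b),
                    },
                }
                for p in self.named_pairs
            ],
            "ebox_map": {
                f"{c}:{s}": lab for (c, s), lab in sorted(self.ebox_map.labels.items())
            },
        }

    def fingerprint(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = self.semantic_dict()
        d.update(
            {
                "topology": self.topology,
                "trajectory": self.trajectory,
                "seed": self.seed,
                "log_level": self.log_level,
            }
        )
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            hb = d.get("hbond", {})
            boxes = [
                DomainBox(b["name"], b["chain"], int(b["start"]), int(b["end"]))
                for b in d.get("boxes", [])
            ]
            bd = d.get("basic_domains")
            basic = (
                None
                if bd is None
                else BasicDomainSpec(
                    bd["chain_a"],
                    tuple(bd["range_a"]),
                    bd["chain_b"],
                    tuple(bd["range_b"]),
                )
            )
            pairs = [
                NamedPair(
                    p["label"],
                    p["a"]["chain"],
                    int(p["a"]["residue"]),
                    frozenset(p["a"]["names"]),
                    p["b"]["chain"],
                    int(p["b"]["residue"]),
                    frozenset(p["b"]["names"]),
                )
                for p in d.get("named_pairs", [])
            ]
            labels = {}
            for key, lab in d.get("ebox_map", {}).items():
                chain, seq = key.split(":")
                labels[(chain, int(seq))] = lab
            return cls(
                topology=d["topology"],
                trajectory=d["trajectory"],
                frame_interval_ps=float(d.get("frame_interval_ps", 10.0)),
                hbond=HBondConfig(
                    threshold_A=float(hb.get("threshold_A", 2.1)),
                    candidate_cutoff_A=float(hb.get("candidate_cutoff_A", 4.0)),
                    heavy_atom_mode=bool(hb.get("heavy_atom_mode", False)),
                    heavy_threshold_A=float(hb.get("heavy_threshold_A", 3.0)),
                ),
                rmsf_window_frames=int(d.get("rmsf_window_frames", 5)),
                rmsf_step_frames=int(d.get("rmsf_step_frames", 1)),
                smoothing_neighbors=int(d.get("smoothing_neighbors", 8)),
                boxes=boxes,
                basic_domains=basic,
                named_pairs=pairs,
                ebox_map=EBoxMap(labels=labels),
                seed=int(d.get("seed", 0)),
                log_level=str(d.get("log_level", "INFO")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(data)


def default_run_config(
    topology: str,
    trajectory: str,
    seed: int = 0,
    frame_interval_ps: float = 10.0,
) -> RunConfig:
    """The canonical TWIST1/E12-on-E-box analysis configuration.

    Boxes A/B on the TWIST1-like chain T (120–127, 149–157) and C/D on the
    E12-like chain E (565–574, 588–594); basic domains R110–E126 / R550–N566
    (17 residues each); the bottom/middle/top CA pairs and the two
    loop-closing asparagine–lysine pairs; E-box position labels on DNA chains
    X (reference strand) and Y (complement), both numbered 1–16 from their own
    5' end.
    """
    from .synthetic import DnaSpec  # label layout lives with the duplex builder

    boxes = [
        DomainBox("A", "T", 120, 127),
        DomainBox("B", "T", 149, 157),
        DomainBox("C", "E", 565, 574),
        DomainBox("D", "E", 588, 594),
    ]
    basic = BasicDomainSpec("T", (110, 126), "E", (550, 566))
    ca = frozenset({"CA"})
    pairs = [
        NamedPair("bottom", "T", 112, ca, "E", 552, ca),
        NamedPair("middle", "T", 124, ca, "E", 564, ca),
        NamedPair("top", "T", 134, ca, "E", 578, ca),
        NamedPair("N125-K145", "T", 125, frozenset({"OD1"}), "T", 145, frozenset({"HZ1"})),
        NamedPair("N566-K588", "E", 566, frozenset({"OD1"}), "E", 588, frozenset({"HZ1"})),
    ]
    return RunConfig(
        topology=str(topology),
        trajectory=str(trajectory),
        frame_interval_ps=frame_interval_ps,
        boxes=boxes,
        basic_domains=basic,
        named_pairs=pairs,
        ebox_map=EBoxMap(labels=DnaSpec().position_labels()),
        seed=seed,
    )
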