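"""Synthetic dimer+DNA trajectories with planted ground truth.

Builds an idealized two-chain helical protein dimer flanking a B-form-like
16-bp DNA duplex carrying the E-box 5'-TAGGCCATCTGGTCCT-3', then synthesizes
trajectory frames as

    frame_t = mean structure + independent Gaussian displacement (σ per residue)

with designated donor–H···acceptor contacts overridden per frame: with the
planted Bernoulli probability the hydrogen is placed so its distance to the
acceptor draws from a *bound* sampler (uniform 1.7–2.05 Å, strictly below the
2.1 Å scoring threshold), otherwise from an *unbound* sampler (uniform
2.3–3.5 Å, strictly above it). The dead zone around the threshold makes
planted occupancy rates exactly recoverable up to Bernoulli sampling noise.

Geometry is idealized, not physical: rigid helical templates, no sterics, no
bonded dynamics — the analysis layer consumes coordinates only. Each protein
chain folds back on itself at a configurable residue (helix–loop–helix-like),
which brings the loop lysines near the helix asparagines the way the real
dimer's N125–K145 / N566–K588 contacts sit.

Everything is deterministic given the seed; identical configs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .structure import Atom, Structure, Trajectory
from .pdbio import write_pdb
from .dcdio import write_dcd

__all__ = [
    "PlantedContact",
    "ProtomerSpec",
    "DnaSpec",
    "GeneratorConfig",
    "default_config",
    "default_mutant_config",
    "generate_dimer_trajectory",
    "write_fixture_bundle",
    "EBOX_SEQUENCE",
]

EBOX_SEQUENCE = "TAGGCCATCTGGTCCT"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: one representative polar side-chain heavy atom per residue type
SIDECHAIN_HEAVY = {
    "SER": "OG",
    "THR": "OG1",
    "ASN": "OD1",
    "ASP": "OD1",
    "GLN": "OE1",
    "GLU": "OE1",
    "LYS": "NZ",
    "ARG": "NH1",
    "HIS": "ND1",
    "TYR": "OH",
    "TRP": "NE1",
    "CYS": "SG",
    "MET": "SD",
}

#: two nucleobase polar atoms per base type; the first is placed facing the
#: protein (groove side) and is the one planted contacts may target
BASE_POLAR = {
    "A": ("N1", "N3"),
    "T": ("O4", "O2"),
    "G": ("O6", "N7"),
    "C": ("O2", "N3"),
}


@dataclass(frozen=True)
class PlantedContact:
    """A donor–H···acceptor contact with a planted per-frame Bernoulli rate."""

    donor_chain: str
    donor_residue: int
    donor_heavy: str
    hydrogen: str
    acceptor_chain: str
    acceptor_residue: int
    acceptor_name: str
    rate: float
    bound_range: tuple[float, float] = (1.7, 2.05)
    unbound_range: tuple[float, float] = (2.3, 3.5)

    def __post_init__(self):
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"contact rate {self.rate} outside [0, 1]")
        if not (self.bound_range[1] < 2.1 and self.bound_range[0] > 0):
            raise ValueError("bound sampler support must lie strictly below 2.1 Å")
        if self.unbound_range[0] <= 2.1:
            raise ValueError("unbound sampler support must lie strictly above 2.1 Å")


@dataclass(frozen=True)
class ProtomerSpec:
    """One idealized protein chain: a helix that folds back at ``fold_at``."""

    chain_id: str
    start: int
    end: int
    axis_x: float
    fold_at: int | None = None
    fold_y_offset: float = 18.0
    residue_names: dict[int, str] = field(default_factory=dict)
    default_residue: str = "ALA"

    def name_of(self, seq: int) -> str:
        return self.residue_names.get(seq, self.default_residue)


@dataclass(frozen=True)
class DnaSpec:
    sequence: str = EBOX_SEQUENCE
    chain_fwd: str = "X"
    chain_rev: str = "Y"
    ebox_offset: int = 5  # 0-based index of the CANNTG core in `sequence`

    @property
    def complement(self) -> str:
        return "".join(_COMPLEMENT[b] for b in reversed(self.sequence))

    def position_labels(self) -> dict[tuple[str, int], str]:
        """E-box position labels keyed by (chain, residue_seq), 1-based.

        Consensus +1/+2, variable central +3/+4, starred complement labels
        mirror-numbered from the complement's own 5' end, −1/−1* immediately
        5' of +1/+1* on each strand.
        """
        o = self.ebox_offset  # core starts at residue o+1 (1-based)
        labels: dict[tuple[str, int], str] = {}
        for k, lab in enumerate(("+1", "+2", "+3", "+4")):
            labels[(self.chain_fwd, o + 1 + k)] = lab
            labels[(self.chain_rev, o + 1 + k)] = lab + "*"
        labels[(self.chain_fwd, o)] = "-1"
        labels[(self.chain_rev, o)] = "-1*"
        return labels


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_frames: int = 200
    frame_interval_ps: float = 10.0
    protomers: tuple[ProtomerSpec, ...] = ()
    dna: DnaSpec | None = None
    contacts: tuple[PlantedContact, ...] = ()
    sigma_protein: float = 0.30  # Å per coordinate, mean-structure Gaussian
    sigma_dna: float = 0.10
    sigma_overrides: dict[tuple[str, int], float] = field(default_factory=dict)
    helix_radius: float = 2.3
    helix_rise: float = 1.5
    helix_turn_deg: float = 100.0
    # distance between the donor-heavy and acceptor tips of a planted contact;
    # must exceed the unbound sampler maximum so the hydrogen always stays
    # between the two tips
    contact_gap: float = 5.2

    def sigma_of(self, chain: str, seq: int, moiety: str) -> float:
        if (chain, seq) in self.sigma_overrides:
            return self.sigma_overrides[(chain, seq)]
        return self.sigma_dna if moiety == "nucleic" else self.sigma_protein


_TWIST_NAMES = {
    108: "THR", 109: "GLN", 110: "ARG", 111: "VAL", 112: "MET", 113: "ALA",
    114: "ASN", 115: "VAL", 116: "ARG", 117: "GLU", 118: "ARG", 119: "GLN",
    120: "ARG", 121: "THR", 122: "GLN", 123: "SER", 124: "LEU", 125: "ASN",
    126: "GLU", 134: "ILE", 135: "ILE", 144: "SER", 145: "LYS", 149: "LEU",
    150: "LYS", 152: "ALA", 154: "ARG", 157: "ARG",
}

_E12_NAMES = {
    548: "GLU", 550: "ARG", 551: "ARG", 552: "VAL", 553: "ALA", 554: "ASN",
    555: "ASN", 556: "ALA", 557: "ARG", 558: "GLU", 559: "ARG", 560: "LEU",
    561: "ARG", 562: "VAL", 563: "ARG", 564: "ASP", 565: "ILE", 566: "ASN",
    569: "GLU", 570: "ASN", 574: "ASN", 578: "LEU", 588: "LYS",
}


def default_config(seed: int = 0, n_frames: int = 200) -> GeneratorConfig:
    """The default study conditions: a TWIST1/E12-like heterodimer on the E-box.

    Chain T emulates TWIST1 (residues 108–164, helix folding back at 135) and
    chain E emulates E12 (548–594, folding at 576); planted contacts mirror
    the interactions the analyses target: the loop-to-helix N125–K145 and
    N566–K588 couples, two inter-chain box-B/box-C bonds, and four
    protein–DNA contacts covering flanking (−1), consensus (+1/+1*) and
    phosphate-backbone sites.
    """
    protomers = (
        ProtomerSpec("T", 108, 164, axis_x=-10.0, fold_at=135,
                     residue_names=dict(_TWIST_NAMES)),
        ProtomerSpec("E", 548, 594, axis_x=+10.0, fold_at=576,
                     residue_names=dict(_E12_NAMES)),
    )
    contacts = (
        PlantedContact("T", 145, "NZ", "HZ1", "T", 125, "OD1", 0.85),
        PlantedContact("E", 588, "NZ", "HZ1", "E", 566, "OD1", 0.80),
        PlantedContact("T", 154, "NH1", "HH11", "E", 569, "OE1", 0.70),
        PlantedContact("T", 150, "NZ", "HZ1", "E", 574, "OD1", 0.60),
        PlantedContact("T", 144, "OG", "HG", "X", 6, "O2", 0.45),
        PlantedContact("T", 120, "NH1", "HH11", "X", 5, "O2", 0.50),
        PlantedContact("E", 561, "NH1", "HH11", "Y", 6, "O2", 0.45),
        PlantedContact("E", 557, "NH1", "HH11", "X", 7, "O1P", 0.50),
    )
    return GeneratorConfig(
        seed=seed,
        n_frames=n_frames,
        protomers=protomers,
        dna=DnaSpec(),
        contacts=contacts,
    )


def default_mutant_config(seed: int = 1, n_frames: int = 200) -> GeneratorConfig:
    """The destabilized variant: every contact touching box B (T149–157) halved."""
    cfg = default_config(seed=seed, n_frames=n_frames)
    mutated = []
    for c in cfg.contacts:
        in_box_b = (c.donor_chain == "T" and 149 <= c.donor_residue <= 157) or (
            c.acceptor_chain == "T" and 149 <= c.acceptor_residue <= 157
        )
        mutated.append(replace(c, rate=c.rate / 2) if in_box_b else c)
    return replace(cfg, contacts=tuple(mutated))


def _build_protomer(spec: ProtomerSpec, cfg: GeneratorConfig):
    """Idealized helix (N, CA, C, O + one side-chain heavy per residue)."""
    atoms: list[tuple] = []  # (name, resname, resseq, chain, xyz)
    r, rise, turn = cfg.helix_radius, cfg.helix_rise, np.deg2rad(cfg.helix_turn_deg)
    z0 = -4.0
    for i, seq in enumerate(range(spec.start, spec.end + 1)):
        theta = i * turn
        if spec.fold_at is None or seq <= spec.fold_at:
            axis = np.array([spec.axis_x, 0.0])
            z = z0 + i * rise
        else:
            axis = np.array([spec.axis_x, spec.fold_y_offset])
            i_fold = spec.fold_at - spec.start
            z = z0 + i_fold * rise - (i - i_fold) * rise
        radial = np.array([np.cos(theta), np.sin(theta)])
        tangent = np.array([-np.sin(theta), np.cos(theta)])
        ca_xy = axis + r * radial
        ca = np.array([ca_xy[0], ca_xy[1], z])
        t3 = np.array([tangent[0], tangent[1], 0.0])
        resname = spec.name_of(seq)
        atoms.append(("N", resname, seq, spec.chain_id, ca - 0.95 * t3 + [0, 0, -0.85]))
        atoms.append(("CA", resname, seq, spec.chain_id, ca))
        atoms.append(("C", resname, seq, spec.chain_id, ca + 0.95 * t3 + [0, 0, 0.85]))
        atoms.append(("O", resname, seq, spec.chain_id, ca + 0.95 * t3 + [0, 0, 2.08]))
        sc_name = SIDECHAIN_HEAVY.get(resname, "CB")
        sc_dir = np.array([radial[0], radial[1], 0.0])
        atoms.append((sc_name, resname, seq, spec.chain_id, ca + 1.6 * sc_dir))
    return atoms


def _build_dna(dna: DnaSpec):
    """B-form-like duplex skeleton: P, O1P, O2P, C1' + 2 base polar atoms."""
    atoms: list[tuple] = []
    seq_f = dna.sequence
    seq_r = dna.complement
    n = len(seq_f)
    rise = 3.4
    z_dna = -12.0
    for strand, (chain, seq) in enumerate(
        ((dna.chain_fwd, seq_f), (dna.chain_rev, seq_r))
    ):
        ysign = +1.0 if strand == 0 else -1.0
        for j, base in enumerate(seq, start=1):
            # pairing partner of reverse-strand residue j is forward n+1-j
            x = (j - (n + 1) / 2) * rise if strand == 0 else ((n + 1 - j) - (n + 1) / 2) * rise
            center = np.array([x, ysign * 1.8, z_dna])
            resname = "D" + base
            p = center + np.array([-0.8, ysign * 3.2, -1.6])
            atoms.append(("P", resname, j, chain, p))
            # phosphate oxygens spread vertically: O1P faces the protein side
            atoms.append(("O1P", resname, j, chain, p + [0.0, ysign * 0.6, 1.0]))
            atoms.append(("O2P", resname, j, chain, p + [0.0, ysign * 0.6, -1.5]))
            atoms.append(("C1'", resname, j, chain, center + [0.0, ysign * 1.9, 0.4]))
            upper, lower = BASE_POLAR[base]
            atoms.append((upper, resname, j, chain, center + [0.0, 0.0, +0.9]))
            atoms.append((lower, resname, j, chain, center + [0.0, 0.0, -0.9]))
    return atoms


def _mean_structure(cfg: GeneratorConfig) -> Structure:
    raw: list[tuple] = []
    for spec in cfg.protomers:
        raw.extend(_build_protomer(spec, cfg))
    if cfg.dna is not None:
        raw.extend(_build_dna(cfg.dna))

    # index for placement of contact atoms
    index: dict[tuple[str, int, str], int] = {
        (chain, seq, name): i for i, (name, _rn, seq, chain, _xyz) in enumerate(raw)
    }
    coords = np.array([xyz for (_n, _rn, _s, _c, xyz) in raw], dtype=float)

    def ca_of(chain, seq):
        key = (chain, seq, "CA")
        if key in index:
            return coords[index[key]]
        # DNA: use the midpoint of the two base atoms as the residue anchor
        picks = [i for (c, s, nm), i in index.items() if c == chain and s == seq]
        return coords[picks].mean(axis=0)

    hydrogens: list[tuple] = []
    seen_h: set[tuple[str, int, str]] = set()
    for c in cfg.contacts:
        hkey = (c.donor_chain, c.donor_residue, c.hydrogen)
        if hkey in seen_h:
            raise ValueError(
                f"hydrogen {hkey} planted twice in the contact list"
            )
        seen_h.add(hkey)
        dkey = (c.donor_chain, c.donor_residue, c.donor_heavy)
        akey = (c.acceptor_chain, c.acceptor_residue, c.acceptor_name)
        if dkey not in index:
            raise ValueError(f"contact donor atom {dkey} not in the structure")
        if akey not in index:
            raise ValueError(f"contact acceptor atom {akey} not in the structure")
        # stretch the contact side chains toward a mid-gap rendezvous point so
        # the hydrogen corridor stays clear of both chain bodies (idealized,
        # deliberately unphysical reach)
        ca_d = ca_of(c.donor_chain, c.donor_residue)
        ca_a = ca_of(c.acceptor_chain, c.acceptor_residue)
        half = cfg.contact_gap / 2.0
        if (c.acceptor_chain, c.acceptor_residue, "CA") in index:
            mid = (ca_d + ca_a) / 2.0
            v = ca_d - ca_a
            v = v / np.linalg.norm(v)
            coords[index[dkey]] = mid + half * v
            coords[index[akey]] = mid - half * v
        else:
            # DNA acceptor stays put; the donor tip hovers above it
            apos = coords[index[akey]]
            v = ca_d - apos
            v = v / np.linalg.norm(v)
            coords[index[dkey]] = apos + cfg.contact_gap * v
        # provisional hydrogen 1 Å off the donor heavy; overridden per frame
        hydrogens.append(
            (c.hydrogen, raw[index[dkey]][1], c.donor_residue, c.donor_chain,
             coords[index[dkey]] - 1.0 * v)
        )

    all_raw = raw + hydrogens
    all_coords = np.vstack([coords] + [h[4][None] for h in hydrogens]) if hydrogens else coords
    atoms = [
        Atom.make(i + 1, name, resname, seq, chain)
        for i, (name, resname, seq, chain, _xyz) in enumerate(all_raw)
    ]
    return Structure(atoms, all_coords)


def generate_dimer_trajectory(cfg: GeneratorConfig):
    """Build the mean structure and synthesize frames.

    Returns ``(structure, trajectory, manifest)`` where the manifest is a JSON-
    serializable dict recording every planted value (per-residue σ, contact
    rates and classifications, the E-box position map).
    """
    structure = _mean_structure(cfg)
    n = structure.n_atoms
    rng = np.random.default_rng(cfg.seed)

    sigma = np.array(
        [cfg.sigma_of(a.chain_id, a.residue_seq, a.moiety) for a in structure.atoms]
    )
    frames = (
        structure.coordinates[None, :, :]
        + rng.standard_normal((cfg.n_frames, n, 3)) * sigma[None, :, None]
    )

    contact_truth = []
    for c in cfg.contacts:
        di = structure.atom_index(c.donor_chain, c.donor_residue, c.donor_heavy)
        hi = structure.atom_index(c.donor_chain, c.donor_residue, c.hydrogen)
        ai = structure.atom_index(c.acceptor_chain, c.acceptor_residue, c.acceptor_name)
        bound = rng.random(cfg.n_frames) < c.rate
        d_bound = rng.uniform(*c.bound_range, cfg.n_frames)
        d_unbound = rng.uniform(*c.unbound_range, cfg.n_frames)
        dist = np.where(bound, d_bound, d_unbound)
        vec = frames[:, di, :] - frames[:, ai, :]
        unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
        frames[:, hi, :] = frames[:, ai, :] + dist[:, None] * unit

        donor_atom = structure.atoms[di]
        acceptor_atom = structure.atoms[ai]
        moieties = {donor_atom.moiety, acceptor_atom.moiety}
        category = "R-R" if moieties == {"protein"} else "R-base"
        contact_truth.append(
            {
                "donor": f"{c.donor_chain}:{c.donor_residue}:{c.donor_heavy}",
                "hydrogen": c.hydrogen,
                "acceptor": f"{c.acceptor_chain}:{c.acceptor_residue}:{c.acceptor_name}",
                "rate": c.rate,
                "empirical_rate": float(bound.mean()),
                "category": category,
            }
        )

    per_residue_sigma = {
        f"{chain}:{seq}": cfg.sigma_of(chain, seq, moiety_lookup)
        for chain, seq, moiety_lookup in {
            (a.chain_id, a.residue_seq, a.moiety) for a in structure.atoms
        }
    }
    manifest = {
        "seed": cfg.seed,
        "n_frames": cfg.n_frames,
        "frame_interval_ps": cfg.frame_interval_ps,
        "sigma_per_residue": dict(sorted(per_residue_sigma.items())),
        "contacts": contact_truth,
        "dna_sequence": cfg.dna.sequence if cfg.dna else None,
        "ebox_labels": (
            {f"{c}:{s}": lab for (c, s), lab in cfg.dna.position_labels().items()}
            if cfg.dna
            else {}
        ),
        "chains": [p.chain_id for p in cfg.protomers]
        + ([cfg.dna.chain_fwd, cfg.dna.chain_rev] if cfg.dna else []),
    }
    trajectory = Trajectory(structure, frames, frame_interval_ps=cfg.frame_interval_ps)
    return structure, trajectory, manifest


def write_fixture_bundle(cfg: GeneratorConfig, directory) -> dict[str, str]:
    """Emit topology.pdb, trajectory.dcd, config.yaml and manifest.json.

    The analysis config matches the planted chains and ranges (boxes A–D,
    basic domains, named pairs, the E-box map), so the bundle drives the whole
    pipeline end to end. Returns the path map.
    """
    from .runconfig import default_run_config  # deferred: avoids a cycle

    os.makedirs(directory, exist_ok=True)
    structure, trajectory, manifest = generate_dimer_trajectory(cfg)
    paths = {
        "topology": os.path.join(directory, "topology.pdb"),
        "trajectory": os.path.join(directory, "trajectory.dcd"),
        "config": os.path.join(directory, "config.yaml"),
        "manifest": os.path.join(directory, "manifest.json"),
    }
    write_pdb(structure, paths["topology"])
    write_dcd(trajectory, paths["trajectory"])
    run_cfg = default_run_config(
        topology=paths["topology"],
        trajectory=paths["trajectory"],
        seed=cfg.seed,
        frame_interval_ps=cfg.frame_interval_ps,
    )
    run_cfg.to_yaml(paths["config"])
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths
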