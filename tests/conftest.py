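from __future__ import annotations

import numpy as np
import pytest

from dimertraj import (
    Atom,
    HBondPair,
    OccupancyRecord,
    Structure,
    Trajectory,
    default_config,
    generate_dimer_trajectory,
    write_fixture_bundle,
)


def make_structure(spec, coords) -> Structure:
    """spec: list of (name, resname, resseq, chain) tuples."""
    atoms = [
        Atom.make(i + 1, name, resname, resseq, chain)
        for i, (name, resname, resseq, chain) in enumerate(spec)
    ]
    return Structure(atoms, np.asarray(coords, dtype=float))


def make_record(
    structure: Structure,
    donor: tuple[str, int, str],
    hydrogen_name: str,
    acceptor: tuple[str, int, str],
    scores,
) -> OccupancyRecord:
    """Hand-built occupancy record for aggregation tests."""
    di = structure.atom_index(*donor)
    hi = structure.atom_index(donor[0], donor[1], hydrogen_name)
    ai = structure.atom_index(*acceptor)
    d_atom, h_atom, a_atom = (
        structure.atoms[di],
        structure.atoms[hi],
        structure.atoms[ai],
    )
    moieties = {d_atom.moiety, a_atom.moiety}
    if moieties == {"protein"}:
        category, site, specific = "R-R", None, None
    else:
        from dimertraj.hbond import dna_site_of, PROTEIN_BACKBONE

        dna = a_atom if a_atom.moiety == "nucleic" else d_atom
        protein = d_atom if dna is a_atom else a_atom
        category = "R-base"
        site = dna_site_of(dna.name)
        specific = protein.name not in PROTEIN_BACKBONE and site == "nucleobase"
    pair = HBondPair(
        donor_index=di,
        hydrogen_index=hi,
        acceptor_index=ai,
        donor=d_atom,
        hydrogen=h_atom,
        acceptor=a_atom,
        category=category,
        dna_site=site,
        specific=specific,
    )
    scores = np.asarray(scores, dtype=np.int8)
    # distances consistent with the scores: 1.9 when bonded, 3.0 otherwise
    distances = np.where(scores == 1, 1.9, 3.0)
    return OccupancyRecord(pair=pair, distances=distances, scores=scores, threshold_A=2.1)


@pytest.fixture(scope="session")
def default_traj():
    """A medium default-condition trajectory shared across tests."""
    cfg = default_config(seed=11, n_frames=120)
    structure, traj, manifest = generate_dimer_trajectory(cfg)
    return structure, traj, manifest


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """An on-disk fixture bundle (topology, DCD, config, manifest)."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = default_config(seed=11, n_frames=120)
    paths = write_fixture_bundle(cfg, out)
    return paths
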