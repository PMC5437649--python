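import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dimertraj import (
    BaselineError,
    DomainBox,
    HBondConfig,
    Trajectory,
    aggregate_occupancy,
    default_config,
    enumerate_pairs,
    generate_dimer_trajectory,
    percent_variation,
    score_all,
    score_occupancy,
)
from dimertraj.synthetic import GeneratorConfig, PlantedContact, ProtomerSpec
from conftest import make_record, make_structure


def _pair_fixture(distances):
    """SER donor OG–HG against an acceptor O placed at controlled distances."""
    spec = [
        ("OG", "SER", 1, "A"),
        ("HG", "SER", 1, "A"),
        ("O", "ALA", 2, "A"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
    s = make_structure(spec, coords)
    frames = np.repeat(coords[None], len(distances), axis=0)
    for k, d in enumerate(distances):
        frames[k, 2] = [1.0 + d, 0.0, 0.0]  # H···acceptor distance d
    return s, Trajectory(s, frames)


def test_score_occupancy_forced_rule():
    s, traj = _pair_fixture([3.0, 3.0, 3.0])
    (pair,) = enumerate_pairs(traj)
    rec = score_occupancy(pair, traj)
    assert rec.scores.tolist() == [0, 0, 0]
    assert rec.cumulated_occupancy == 0 and rec.rate == 0.0

    s, traj = _pair_fixture([2.0, 2.2, 1.9])
    (pair,) = enumerate_pairs(traj)
    rec = score_occupancy(pair, traj)
    assert rec.scores.tolist() == [1, 0, 1]
    assert rec.cumulated_occupancy == 2
    assert rec.rate == pytest.approx(2 / 3)


def test_threshold_is_strictly_less_than():
    s, traj = _pair_fixture([2.1] * 5)
    (pair,) = enumerate_pairs(traj)
    rec = score_occupancy(pair, traj)
    assert np.allclose(rec.distances, 2.1)
    assert rec.cumulated_occupancy == 0


def test_enumerate_requires_hydrogens():
    spec = [("OG", "SER", 1, "A"), ("O", "ALA", 2, "A")]
    coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    s = make_structure(spec, coords)
    with pytest.raises(ValueError, match="hydrogen"):
        enumerate_pairs(Trajectory(s, coords[None]))


def test_enumerate_far_apart_is_empty():
    spec = [
        ("OG", "SER", 1, "A"),
        ("HG", "SER", 1, "A"),
        ("O", "ALA", 2, "A"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [20.0, 0, 0]])
    s = make_structure(spec, coords)
    assert enumerate_pairs(Trajectory(s, coords[None])) == []


def test_serine_to_thymine_is_specific_nucleobase():
    spec = [
        ("OG", "SER", 1, "A"),
        ("HG", "SER", 1, "A"),
        ("O4", "DT", 3, "X"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
    s = make_structure(spec, coords)
    (pair,) = enumerate_pairs(Trajectory(s, coords[None]))
    assert pair.category == "R-base"
    assert pair.dna_site == "nucleobase"
    assert pair.specific is True


def test_phosphate_and_sugar_sites_are_nonspecific():
    spec = [
        ("NZ", "LYS", 1, "A"),
        ("HZ1", "LYS", 1, "A"),
        ("O1P", "DA", 3, "X"),
        ("O4'", "DA", 4, "X"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0], [1.0, 3.0, 0]])
    s = make_structure(spec, coords)
    pairs = enumerate_pairs(Trajectory(s, coords[None]))
    sites = {p.acceptor.name: (p.dna_site, p.specific) for p in pairs}
    assert sites["O1P"] == ("phosphate", False)
    assert sites["O4'"] == ("sugar", False)


def test_enumerate_finds_exactly_planted_contacts(default_traj):
    _, traj, manifest = default_traj
    records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
    found = {
        (
            f"{r.pair.donor.chain_id}:{r.pair.donor.residue_seq}:{r.pair.donor.name}",
            f"{r.pair.acceptor.chain_id}:{r.pair.acceptor.residue_seq}:{r.pair.acceptor.name}",
        )
        for r in records
    }
    planted = {(c["donor"], c["acceptor"]) for c in manifest["contacts"]}
    assert found == planted
    by_key = {
        (c["donor"], c["acceptor"]): c["category"] for c in manifest["contacts"]
    }
    for r in records:
        key = (
            f"{r.pair.donor.chain_id}:{r.pair.donor.residue_seq}:{r.pair.donor.name}",
            f"{r.pair.acceptor.chain_id}:{r.pair.acceptor.residue_seq}:{r.pair.acceptor.name}",
        )
        assert r.pair.category == by_key[key]


def _isolated_contacts_config(rates, seed, n_frames):
    """Well-separated donor/acceptor columns: one planted contact per level."""
    n = len(rates)
    donors = {1 + 10 * k: "LYS" for k in range(n)}
    acceptors = {1 + 10 * k: "ASN" for k in range(n)}
    protomers = (
        ProtomerSpec("A", 1, 10 * n, axis_x=-10.0, residue_names=donors),
        ProtomerSpec("B", 1, 10 * n, axis_x=+10.0, residue_names=acceptors),
    )
    contacts = tuple(
        PlantedContact("A", 1 + 10 * k, "NZ", "HZ1", "B", 1 + 10 * k, "OD1", r)
        for k, r in enumerate(rates)
    )
    return GeneratorConfig(
        seed=seed, n_frames=n_frames, protomers=protomers, dna=None, contacts=contacts
    )


@pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
def test_planted_rate_recovery_within_binomial_bound(p):
    n = 1000
    tol = 3 * np.sqrt(p * (1 - p) / n)
    for seed in (1, 2, 3, 4, 5):
        cfg = _isolated_contacts_config([p], seed=seed, n_frames=n)
        _, traj, _ = generate_dimer_trajectory(cfg)
        records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
        assert len(records) == 1
        assert abs(records[0].rate - p) <= tol


def test_scoring_is_frame_local(default_traj):
    _, traj, _ = default_traj
    perm = np.random.default_rng(0).permutation(traj.n_frames)
    shuffled = Trajectory(traj.structure, traj.frames[perm])
    a = {r.pair.label: r.cumulated_occupancy for r in score_all(traj)}
    b = {r.pair.label: r.cumulated_occupancy for r in score_all(shuffled)}
    assert a == b


@given(st.lists(st.floats(min_value=0.5, max_value=6.0), min_size=3, max_size=40))
@settings(max_examples=50, deadline=None)
def test_threshold_monotonicity(distances):
    s, traj = _pair_fixture(distances)
    (pair,) = enumerate_pairs(traj, HBondConfig(candidate_cutoff_A=10.0))
    occ = [
        score_occupancy(pair, traj, HBondConfig(threshold_A=t, candidate_cutoff_A=10.0)).cumulated_occupancy
        for t in (1.5, 2.1, 2.8, 4.0)
    ]
    assert occ == sorted(occ)


def _toy_records():
    spec = [
        ("NZ", "LYS", 5, "A"),
        ("HZ1", "LYS", 5, "A"),
        ("OD1", "ASN", 9, "A"),
        ("OE1", "GLN", 21, "B"),
        ("OG", "SER", 30, "A"),
        ("HG", "SER", 30, "A"),
        ("O4", "DT", 3, "X"),
    ]
    s = make_structure(spec, np.zeros((len(spec), 3)))
    return s


def test_aggregate_by_residue_double_attribution():
    s = _toy_records()
    r1 = make_record(s, ("A", 5, "NZ"), "HZ1", ("A", 9, "OD1"), [1] * 5)
    r2 = make_record(s, ("A", 5, "NZ"), "HZ1", ("B", 21, "OE1"), [1] * 7)
    table = aggregate_occupancy([r1, r2], "residue")
    totals = dict(zip(table["group"], table["cumulated_occupancy"]))
    assert totals["A:5"] == 12  # attributed to both sides of each R-R pair
    assert totals["A:9"] == 5
    assert totals["B:21"] == 7


def test_aggregate_by_box_matches_brute_force(default_traj):
    _, traj, _ = default_traj
    records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
    boxes = [
        DomainBox("A", "T", 120, 127),
        DomainBox("B", "T", 149, 157),
        DomainBox("C", "E", 565, 574),
        DomainBox("D", "E", 588, 594),
    ]
    table = aggregate_occupancy(records, "box", boxes=boxes)
    totals = dict(zip(table["group"], table["cumulated_occupancy"]))

    def residues_of(rec):
        p = rec.pair
        if p.category == "R-R":
            return {p.donor.residue_key, p.acceptor.residue_key}
        prot = p.donor if p.donor.moiety == "protein" else p.acceptor
        return {prot.residue_key}

    for b in boxes:
        brute = sum(
            r.cumulated_occupancy
            for r in records
            if any(b.contains(c, q) for c, q in residues_of(r))
        )
        assert totals[b.name] == brute
    # conservation against the out-of-box remainder (single-box records only)
    single_box = [
        r
        for r in records
        if sum(any(b.contains(c, q) for c, q in residues_of(r)) for b in boxes) <= 1
    ]
    t2 = aggregate_occupancy(single_box, "box", boxes=boxes)
    assert (
        t2["cumulated_occupancy"].sum()
        == sum(r.cumulated_occupancy for r in single_box)
    )


def test_aggregate_specificity_on_rr_only_records():
    s = _toy_records()
    r1 = make_record(s, ("A", 5, "NZ"), "HZ1", ("A", 9, "OD1"), [1, 1, 0])
    table = aggregate_occupancy([r1], "specificity")
    totals = dict(zip(table["group"], table["cumulated_occupancy"]))
    assert totals == {"specific": 0, "non-specific": 0, "R-R": 2}


def test_aggregate_rejects_unknown_key():
    s = _toy_records()
    r1 = make_record(s, ("A", 5, "NZ"), "HZ1", ("A", 9, "OD1"), [1])
    with pytest.raises(ValueError, match="grouping"):
        aggregate_occupancy([r1], "flavor")
    with pytest.raises(ValueError):
        aggregate_occupancy([], "residue")


def test_percent_variation_arithmetic():
    assert percent_variation(100, 100) == (0.0, 100.0)
    var, level = percent_variation(59, 100)
    assert var == pytest.approx(-41.0)
    assert level == pytest.approx(59.0)
    with pytest.raises(BaselineError):
        percent_variation(5, 0)


@given(
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=1, max_value=10_000),
)
@settings(max_examples=100, deadline=None)
def test_percent_variation_matches_direct_formula(mut, wt):
    var, level = percent_variation(mut, wt)
    assert var == pytest.approx(100.0 * (mut - wt) / wt)
    assert level == pytest.approx(100.0 * mut / wt)
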