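import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dimertraj import (
    BasicDomainSpec,
    ComparabilityError,
    DomainBox,
    EBoxMap,
    NamedPair,
    SpecError,
    Trajectory,
    basic_domain_distance,
    compare_reports,
    ebox_profile,
    pair_distance_series,
    smooth_series,
    summarize_records,
    validate_boxes,
)
from dimertraj.synthetic import DnaSpec
from conftest import make_record, make_structure
from _oracles import brute_force_paired_mean


def _two_chain_ca(n=17, separation=8.0):
    spec = [("CA", "ALA", 100 + i, "A") for i in range(n)] + [
        ("CA", "ALA", 500 + i, "B") for i in range(n)
    ]
    ca_a = np.column_stack([np.zeros(n), np.zeros(n), 1.5 * np.arange(n)])
    ca_b = ca_a + np.array([separation, 0.0, 0.0])
    coords = np.vstack([ca_a, ca_b])
    s = make_structure(spec, coords)
    spec_bd = BasicDomainSpec("A", (100, 100 + n - 1), "B", (500, 500 + n - 1))
    return s, coords, spec_bd


def test_basic_domain_parallel_chains():
    s, coords, bd = _two_chain_ca(separation=8.0)
    traj = Trajectory(s, np.repeat(coords[None], 4, axis=0))
    res = basic_domain_distance(traj, bd)
    assert np.allclose(res.per_frame, 8.0)
    assert res.mean == pytest.approx(8.0)
    assert res.n_pairs == 17


def test_basic_domain_translation_shifts_mean_exactly():
    s, coords, bd = _two_chain_ca(separation=8.0)
    moved = coords.copy()
    moved[17:] += np.array([5.0, 0.0, 0.0])
    traj = Trajectory(s, np.stack([coords, moved]))
    res = basic_domain_distance(traj, bd)
    assert res.per_frame[1] - res.per_frame[0] == pytest.approx(5.0)


def test_basic_domain_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    s, coords, bd = _two_chain_ca()
    frames = coords[None] + rng.normal(scale=1.0, size=(6, len(coords), 3))
    traj = Trajectory(s, frames)
    res = basic_domain_distance(traj, bd)
    oracle = brute_force_paired_mean(frames[:, :17], frames[:, 17:])
    assert np.allclose(res.per_frame, oracle)


def test_basic_domain_rigid_invariance():
    rng = np.random.default_rng(6)
    s, coords, bd = _two_chain_ca()
    frames = coords[None] + rng.normal(scale=0.5, size=(4, len(coords), 3))
    rot = Rotation.random(random_state=rng).as_matrix()
    moved = frames @ rot.T + np.array([3.0, -2.0, 9.0])
    a = basic_domain_distance(Trajectory(s, frames), bd)
    b = basic_domain_distance(Trajectory(s, moved), bd)
    assert np.allclose(a.per_frame, b.per_frame, atol=1e-9)


def test_basic_domain_unequal_ranges_rejected():
    with pytest.raises(SpecError):
        BasicDomainSpec("A", (100, 116), "B", (500, 520))


def test_smoothing_constant_and_impulse():
    const = np.full(40, 4.2)
    assert np.allclose(smooth_series(const, 8), const)
    impulse = np.zeros(41)
    impulse[20] = 17.0
    sm = smooth_series(impulse, 8)
    assert sm[20] == pytest.approx(1.0)  # 17 averaged over 2·8+1 points
    assert sm[0] == 0.0


def test_pair_distance_hydrogen_min_dominates_heavy(default_traj):
    _, traj, _ = default_traj
    with_h = NamedPair(
        "N125-K145", "T", 125, frozenset({"OD1"}), "T", 145, frozenset({"HZ1"})
    )
    heavy = NamedPair(
        "N125-K145-NZ", "T", 125, frozenset({"OD1"}), "T", 145, frozenset({"NZ"})
    )
    both = NamedPair(
        "N125-K145-min", "T", 125, frozenset({"OD1"}), "T", 145,
        frozenset({"NZ", "HZ1"}),
    )
    d_h = pair_distance_series(traj, with_h).raw
    d_nz = pair_distance_series(traj, heavy).raw
    d_min = pair_distance_series(traj, both).raw
    assert np.all(d_min <= d_nz + 1e-12)
    assert np.allclose(d_min, np.minimum(d_h, d_nz))


def test_pair_distance_unknown_atom_lists_candidates(default_traj):
    _, traj, _ = default_traj
    bad = NamedPair("x", "T", 125, frozenset({"NZ9"}), "T", 145, frozenset({"NZ"}))
    with pytest.raises(SpecError, match="OD1"):
        pair_distance_series(traj, bad)


def _default_map():
    return EBoxMap(labels=DnaSpec().position_labels())


def _dna_record_structure():
    spec = [
        ("NH1", "ARG", 120, "T"),
        ("HH11", "ARG", 120, "T"),
        ("OG", "SER", 144, "T"),
        ("HG", "SER", 144, "T"),
        ("NH1", "ARG", 561, "E"),
        ("HH11", "ARG", 561, "E"),
        ("O2", "DC", 5, "X"),
        ("O2", "DC", 6, "X"),
        ("O2", "DC", 6, "Y"),
        ("O4", "DT", 8, "X"),
        ("O1P", "DA", 7, "X"),
    ]
    return make_structure(spec, np.zeros((len(spec), 3)))


def test_ebox_profile_single_position():
    s = _dna_record_structure()
    rec = make_record(s, ("T", 144, "OG"), "HG", ("X", 6, "O2"), [1] * 10)
    prof = ebox_profile([rec], _default_map())
    assert prof.percentages == {"+1": pytest.approx(100.0)}
    assert prof.group_shares["consensus"] == pytest.approx(100.0)


def test_ebox_profile_even_split_flanking_variable():
    s = _dna_record_structure()
    r1 = make_record(s, ("T", 120, "NH1"), "HH11", ("X", 5, "O2"), [1] * 6)
    r2 = make_record(s, ("T", 144, "OG"), "HG", ("X", 8, "O4"), [1] * 6)
    prof = ebox_profile([r1, r2], _default_map())
    assert prof.percentages["-1"] == pytest.approx(50.0)
    assert prof.percentages["+3"] == pytest.approx(50.0)
    assert prof.group_shares == {
        "flanking": pytest.approx(50.0),
        "variable": pytest.approx(50.0),
    }


def test_ebox_profile_percentages_sum_to_100(default_traj):
    _, traj, _ = default_traj
    from dimertraj import score_all

    records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
    prof = ebox_profile(records, _default_map())
    assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=1e-9)


def test_ebox_profile_specific_only_excludes_phosphate():
    s = _dna_record_structure()
    r_spec = make_record(s, ("T", 144, "OG"), "HG", ("X", 6, "O2"), [1] * 4)
    r_phos = make_record(s, ("E", 561, "NH1"), "HH11", ("X", 7, "O1P"), [1] * 4)
    prof_all = ebox_profile([r_spec, r_phos], _default_map())
    prof_spec = ebox_profile([r_spec, r_phos], _default_map(), specific_only=True)
    assert prof_all.percentages["+2"] == pytest.approx(50.0)
    assert prof_spec.percentages == {"+1": pytest.approx(100.0)}


def test_ebox_profile_zero_total_flags_empty():
    s = _dna_record_structure()
    rec = make_record(s, ("T", 144, "OG"), "HG", ("X", 6, "O2"), [0, 0])
    prof = ebox_profile([rec], _default_map())
    assert prof.empty and prof.percentages == {}


def test_ebox_map_rejects_duplicate_labels():
    with pytest.raises(SpecError):
        EBoxMap(labels={("X", 6): "+1", ("X", 7): "+1"})


def test_boxes_overlap_rejected():
    with pytest.raises(SpecError):
        validate_boxes([DomainBox("A", "T", 120, 130), DomainBox("B", "T", 125, 140)])
    with pytest.raises(SpecError):
        DomainBox("A", "T", 130, 120)


def _summary(record_specs, fingerprint="fp"):
    """record_specs: list of (donor, hname, acceptor, n_on) over the toy table."""
    s = _dna_record_structure()
    boxes = (
        DomainBox("A", "T", 120, 127),
        DomainBox("B", "T", 144, 157),
        DomainBox("C", "E", 561, 574),
    )
    records = [
        make_record(s, d, h, a, [1] * n + [0] * 2) for d, h, a, n in record_specs
    ]
    return summarize_records(records, boxes, _default_map(), fingerprint)


def test_compare_identical_runs_all_zero():
    specs = [
        (("T", 144, "OG"), "HG", ("X", 6, "O2"), 8),
        (("T", 120, "NH1"), "HH11", ("X", 5, "O2"), 4),
    ]
    report = compare_reports(_summary(specs), _summary(specs))
    assert all(v == 0 for v in report.box_variation_all.values() if v is not None)
    assert all(v == 0 for v in report.residue_deltas.values())
    assert all(v == 0 for v in report.ebox_share_deltas_pp.values())


def test_compare_halved_box_gives_minus_50():
    wt = [
        (("T", 144, "OG"), "HG", ("X", 6, "O2"), 8),  # box B residue
        (("T", 120, "NH1"), "HH11", ("X", 5, "O2"), 4),  # box A residue
    ]
    mut = [
        (("T", 144, "OG"), "HG", ("X", 6, "O2"), 4),
        (("T", 120, "NH1"), "HH11", ("X", 5, "O2"), 4),
    ]
    report = compare_reports(_summary(wt), _summary(mut))
    assert report.box_variation_all["B"] == pytest.approx(-50.0)
    assert report.box_variation_all["A"] == pytest.approx(0.0)


def test_compare_requires_matching_fingerprints():
    specs = [(("T", 144, "OG"), "HG", ("X", 6, "O2"), 8)]
    with pytest.raises(ComparabilityError):
        compare_reports(_summary(specs, "fp1"), _summary(specs, "fp2"))


def test_compare_deltas_antisymmetric_under_swap():
    a = [
        (("T", 144, "OG"), "HG", ("X", 6, "O2"), 8),
        (("T", 120, "NH1"), "HH11", ("X", 5, "O2"), 4),
    ]
    b = [
        (("T", 144, "OG"), "HG", ("X", 6, "O2"), 2),
        (("T", 120, "NH1"), "HH11", ("X", 5, "O2"), 6),
    ]
    fwd = compare_reports(_summary(a), _summary(b))
    rev = compare_reports(_summary(b), _summary(a))
    for k in fwd.residue_deltas:
        assert fwd.residue_deltas[k] == -rev.residue_deltas[k]
    for k in fwd.ebox_share_deltas_pp:
        assert fwd.ebox_share_deltas_pp[k] == pytest.approx(
            -rev.ebox_share_deltas_pp[k]
        )


def test_planted_share_recovery_2_1_1():
    from dataclasses import replace
    from dimertraj import PlantedContact, default_config, generate_dimer_trajectory, score_all

    cfg = default_config(seed=20, n_frames=1000)
    cfg = replace(
        cfg,
        contacts=(
            PlantedContact("T", 120, "NH1", "HH11", "X", 5, "O2", 0.8),
            PlantedContact("T", 144, "OG", "HG", "X", 6, "O2", 0.4),
            PlantedContact("E", 561, "NH1", "HH11", "Y", 6, "O2", 0.4),
        ),
    )
    _, traj, _ = generate_dimer_trajectory(cfg)
    records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
    prof = ebox_profile(records, _default_map())
    # binomial tolerance on the shares at n = 1000
    assert prof.percentages["-1"] == pytest.approx(50.0, abs=5.0)
    assert prof.percentages["+1"] == pytest.approx(25.0, abs=5.0)
    assert prof.percentages["+1*"] == pytest.approx(25.0, abs=5.0)
    assert sum(prof.percentages.values()) == pytest.approx(100.0, abs=1e-9)
    assert prof.group_shares["flanking"] == pytest.approx(50.0, abs=5.0)
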