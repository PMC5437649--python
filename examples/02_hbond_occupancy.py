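"""Hydrogen-bond persistence scoring against the 2.1 Å strict threshold.

Every candidate donor–H···acceptor pair is scored 1 per frame when the
H···acceptor distance is strictly below 2.1 Å; summed over the trajectory this
is the cumulated occupancy, and divided by the frame count the rate of
occupancy — the fraction of simulation time the bond persists.
"""

from dimertraj import default_config, generate_dimer_trajectory, records_table, score_all

cfg = default_config(seed=1, n_frames=200)
structure, traj, manifest = generate_dimer_trajectory(cfg)

records = [r for r in score_all(traj) if r.cumulated_occupancy > 0]
table = records_table(records)
print(table[["donor_residue", "hydrogen", "acceptor_residue", "acceptor_atom",
             "category", "specific", "cumulated_occupancy", "rate"]].to_string(index=False))

print("\nplanted versus recovered rates:")
for contact in manifest["contacts"]:
    rec = next(
        r for r in records
        if f"{r.pair.donor.chain_id}:{r.pair.donor.residue_seq}:{r.pair.donor.name}"
        == contact["donor"]
        and f"{r.pair.acceptor.chain_id}:{r.pair.acceptor.residue_seq}:{r.pair.acceptor.name}"
        == contact["acceptor"]
    )
    print(f"  {contact['donor']} -> {contact['acceptor']}: "
          f"planted {contact['rate']:.2f}, recovered {rec.rate:.3f}")
# A recovered rate near its planted value means the detection, scoring and
# classification chain is faithful end to end.
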