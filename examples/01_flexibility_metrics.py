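"""Per-residue RMSF and frame-aligned heavy-atom RMSD on a synthetic dimer.

Generates a 200-frame trajectory of the TWIST1/E12-like dimer bound to the
E-box duplex, then computes the two flexibility metrics: the windowed RMSF
profile (window 5 frames, step 1) and the per-frame 1D-RMSD against the first
frame over all non-hydrogen atoms (NoH), after optimal superposition.
"""

import numpy as np

from dimertraj import (
    default_config,
    generate_dimer_trajectory,
    rmsd_series,
    rmsf_profile,
)

cfg = default_config(seed=1, n_frames=200)
structure, traj, manifest = generate_dimer_trajectory(cfg)

series = rmsd_series(traj)  # NoH, aligned on frame 0
print(f"1D-RMSD (NoH): mean {series.values.mean():.3f} Å, "
      f"max {series.values.max():.3f} Å over {traj.n_frames} frames")

profile = rmsf_profile(traj, window_frames=5, step_frames=1)
twist = {k: v for k, v in profile.per_residue.items() if k[0] == "T"}
top = sorted(twist.items(), key=lambda kv: -kv[1])[:3]
print("most flexible TWIST1-like residues (RMSF, Å):")
for (chain, seq), v in top:
    print(f"  {profile.residue_names[(chain, seq)]}{seq}.{chain}  {v:.3f}")

# RMSF tracks the planted per-residue Gaussian amplitude: with the default
# uniform sigma the profile is flat, so the spread below should be small.
vals = np.array(list(twist.values()))
print(f"profile spread: std {vals.std():.3f} Å around mean {vals.mean():.3f} Å")
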