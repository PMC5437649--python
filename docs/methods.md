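# Methods

## What is being measured

The package analyses coordinate trajectories of a two-chain bHLH dimer bound
to a short DNA duplex. Three families of statistics are computed, all purely
geometric — no energies, no force field.

### Superposition, RMSD and RMSF

Optimal rigid-body superposition uses the Kabsch algorithm: SVD of the
cross-covariance of the centered point sets, with the sign of the smallest
singular vector flipped whenever the correlation matrix has negative
determinant, so the returned rotation is always proper (det = +1). Inputs with
fewer than three points or with collinear geometry are rejected. The
implementation is checked in the test suite against an independent numeric
rotation search (coarse Euler grid + Nelder-Mead refinement); agreement is at
machine precision on random 3–5-point instances.

The **1D-RMSD series** superposes every frame onto frame 0 over the analysis
selection (default: all non-hydrogen atoms, "NoH") and reports the
post-alignment RMSD over the same selection. Frame 0 therefore reads exactly 0.

The **RMSF profile** is windowed: after aligning all frames on frame 0, every
window of `window_frames` consecutive frames (default 5, advancing by
`step_frames` = 1) contributes a per-atom root-mean-square deviation from the
*window-mean* position; atoms are averaged into residues, and the profile is
the mean over windows. Two conventions were fixed deliberately:

* the window statistic is deviation from the window mean, not from a global
  mean — the sliding-window semantics of the timeline-style tools this
  mirrors; a static trajectory gives exactly zero everywhere;
* no mass weighting — all selected atoms count equally.

Windowing shrinks the absolute scale (a window of w frames recovers
√((w−1)/w)·√3·σ per coordinate σ in expectation, e.g. ≈ 0.98·√3·σ at w = 5),
which is why amplitude recovery is validated by correlation (Pearson r > 0.9
against the planted per-residue σ), not by absolute value.

### Hydrogen-bond persistence

A candidate pair is a donor hydrogen (hydrogen covalently associated with an
N or O of the same residue, matched by name with a geometric fallback) against
an N/O acceptor in a different residue. Scoring is distance-only and
frame-local:

    score_t = 1  if  d(H, acceptor)_t < 2.1 Å   (strict <),  else 0

The 2.1 Å threshold retains only the shortest, strongest hydrogen bonds; the
strict inequality means a distance of exactly 2.10 Å scores 0. *Cumulated
occupancy* is Σ score_t; *rate of occupancy* is the per-frame mean. Candidate
enumeration pre-screens at 4.0 Å (configurable); since any frame below the
threshold is also below the cutoff, screening never changes a result, only
cost. Design choices worth noting:

* the measured distance is hydrogen-to-acceptor, not heavy-to-heavy; a
  heavy-atom mode (default threshold 3.0 Å) exists for comparison but is never
  the default semantics;
* there is **no angular criterion** — a deliberate fidelity-over-orthodoxy
  choice, documented as a limitation;
* DNA–DNA pairs (base pairing) are excluded; categories are residue–residue
  (R-R) and residue–base (R-base) only;
* R-base contacts are subdivided by the DNA atom: phosphate
  {P, O1P/OP1, O2P/OP2, O5', O3'}, sugar (remaining primed names), nucleobase
  (unprimed). A contact is *specific* iff the protein atom is a side-chain
  atom **and** the DNA atom is a nucleobase atom; sugar contacts group with
  the non-specific backbone class.

Aggregation attributes an R-R record to *both* participating residues (a
declared double-attribution convention) and an R-base record to its protein
residue. Box totals count a record once per box containing at least one
attributed residue; consequently box totals plus the out-of-box remainder
equal the grand total only when no record spans two boxes (the synthetic
defaults are checked for the boxes they exercise). Percent variation is
baseline-anchored: 100·(mutant − wildtype)/wildtype, reported alongside the
normalized mutant level (100 + variation); a zero wild-type baseline raises an
error rather than yielding NaN.

### Interface profiles

Basic-domain separation pairs the two 17-residue arms index-by-index in range
order (first↔first … last↔last) and averages the CA–CA distances per frame; a
full cross-product mean is available as an option. Named residue pairs reduce
an atom-name cross product by minimum distance per frame; when a protonated
lysine is involved the hydrogen set {HZ1…} is preferred over {NZ}, since the
nitrogen's single proton-bearing tip is what actually approaches the acceptor.
Smoothing is a centered moving average over 2·k+1 points (default k = 8
neighbors), truncated symmetrically at the series edges — a transparent stand-in
for the proprietary "smooth with 8 neighbors" of common plotting software,
and configurable.

The E-box map labels duplex positions around the CANNTG core of
5'-TAGGC**CATCTG**GTCCT-3': on the reference strand C(+1) A(+2) T(+3) C(+4);
the complementary strand carries the starred labels mirror-numbered from its
own 5' end (its CAGATG core gives C(+1*) A(+2*) G(+3*) A(+4*)); −1/−1* are
the nucleotides immediately 5' of +1/+1* on each strand. Per-position
percentages are shares of the total R-base cumulated occupancy and sum to 100
whenever that total is positive; a zero total yields an explicitly flagged
empty profile. A parallel profile restricted to specific bonds separates
sequence read-out from backbone anchoring.

Comparisons require byte-identical analysis semantics: every run records a
SHA-256 fingerprint of its configuration content (threshold, boxes, domain
specs, named pairs, E-box map, window sizes — not file paths, not the seed),
and `compare` refuses mismatched fingerprints. Delta fields (residue, E-box
shares) are antisymmetric under swapping the runs; percent variation is not,
and is documented as baseline-anchored.

## The synthetic generator

The generator emulates the study conditions — a TWIST1/E12-like heterodimer
(chains T 108–164 and E 548–594, each an idealized α-helix of rise 1.5 Å,
100°/residue, radius 2.3 Å that folds back on itself at the loop, axes 20 Å
apart) above a B-form-like 16-bp duplex (rise 3.4 Å) carrying the E-box, with
10 ps between frames. Residues named in the analyses (the basic domains,
N125/K145, R154, S144, N566/K588, …) carry their real identities; unspecified
positions are alanine. Each residue contributes backbone N, CA, C, O plus one
representative side-chain heavy atom; polar hydrogens exist only on designated
donors. Each nucleotide contributes P, O1P, O2P, C1' and two nucleobase polar
atoms, the groove-facing one being the contactable site.

Frames are `mean structure + independent Gaussian displacement` with
per-residue amplitude σ (defaults: 0.30 Å per coordinate for protein, 0.10 Å
for DNA, overridable per residue). Planted contacts override the hydrogen
position per frame: with probability p the H···acceptor distance is drawn
uniformly from 1.70–2.05 Å, otherwise from 2.30–3.50 Å. The dead zone around
the 2.1 Å threshold makes planted rates exactly recoverable up to Bernoulli
noise. Everything is deterministic given the seed; identical configurations
produce byte-identical files.

Two deliberate departures from physical realism:

* geometry is idealized — rigid templates, no sterics, no bonded dynamics.
  Contact side chains are stretched to a mid-gap rendezvous point (tips 5.2 Å
  apart, exceeding the 3.5 Å unbound maximum) so the hydrogen corridor stays
  clear of both chain bodies; the planted-contact geometry is therefore
  unphysically long-armed but guarantees that the only persisting hydrogen
  bonds are the planted ones (verified across seeds in the tests);
* the default contact set (two loop-closing N–K bonds, two inter-chain
  box-B/box-C bonds, three specific DNA contacts on −1/+1/+1* and one
  phosphate contact) mirrors the interaction classes the analyses target, with
  rates 0.45–0.85 chosen as plausible persistence levels for stable contacts
  over a 10 ns window. The *mutant* variant halves the rate of every contact
  touching box B (T149–157), emulating a helix-destabilizing substitution at
  position 154.

Passing the recovery tests therefore shows the analysis chain is faithful to
planted geometry and statistics; it does **not** validate behaviour on real MD
output with correlated motions, solvent, or imperfect protonation — those
differ from the Gaussian, frame-independent synthetic dynamics in essentially
every physical respect.

## Numerical and validation choices

* Problem sizes: validation runs use 1000 frames (rate, RMSF and share
  recovery; 3·√(p(1−p)/n) binomial bounds), 30 residues for amplitude
  recovery, 100 random instances for the superposition cross-check, and
  120–400-frame bundles for end-to-end pipeline tests — sizes at which every
  recovery is statistically sharp.
* Collinearity is detected via the second singular value (relative 1e-10);
  degenerate selections (< 3 atoms) are geometry errors, empty selections are
  legal results but rejected by metric operations.
* PDB I/O keeps blank/'A' alternate locations, drops others, and rejects
  insertion codes outright — model-built structures have neither, and silent
  handling would corrupt residue keys. Coordinates must fit the fixed 8.3
  columns. Hydrogen identification uses the element column when present, else
  a leading-character heuristic handling the `1HZ`/`HZ1` convention.
* DCD I/O accepts CHARMM and X-PLOR header variants with endianness
  auto-detected from the leading record marker; fixed-atom compression and 4-D
  extensions are rejected explicitly. The writer emits little-endian
  CHARMM-style (version 24) files; readback is exact to float32.
* The CLI persists a `summary.json` with every `hbonds` run so `compare` is a
  pure function of files on disk; exit codes are 0 (success), 2 (config),
  3 (input), 4 (comparability).
* The `hbonds` occupancy table lists persisting pairs (cumulated occupancy ≥ 1)
  by default; `--include-transient` adds screened candidates that never score.

## Known limitations

* Distance-only H-bond criterion (no donor angle) — faithful to the scoring
  rule it reproduces, chemically permissive.
* Box attribution by "any member residue in the box" can double-count a record
  whose two residues lie in *different* boxes (it is counted once per box);
  this is a declared convention, as is the residue-level double attribution.
* The author-numbering/human-numbering split is handled entirely by
  configuration; reproductions on renumbered structures must adjust the config,
  not the code.
* Whisker conventions for box-plot style summaries of RMSD series are left to
  downstream plotting; the library returns full series only.
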