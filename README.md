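# dimertraj

Trajectory analysis for basic helix-loop-helix (bHLH) dimer/DNA complexes —
the kind of question posed by craniosynostosis-linked TWIST1 mutations such as
R154P, which destabilize the TWIST1/E12 heterodimer and its binding to E-box
DNA. Given a topology (PDB) and a coordinate trajectory (DCD or multi-model
PDB), the package computes:

* **Flexibility** — per-frame 1D-RMSD against the first frame over all
  non-hydrogen atoms ("NoH"), after optimal (Kabsch) superposition, and a
  sliding-window per-residue RMSF profile (window 5 frames, step 1);
* **Interface geometry** — mean CA–CA separation of the two basic domains
  (index-paired, TWIST1 R110–E126 ↔ E12 R550–N566), and named residue-pair
  distance series (bottom/middle/top of the dimer, the N125–K145 and
  N566–K588 loop contacts) with centered moving-average smoothing;
* **Hydrogen-bond persistence** — the core statistic. Every candidate
  donor–H···acceptor pair (O−H···N, O−H···O, N−H···N, N−H···O) is scored per
  frame: 1 if the H···acceptor distance is **strictly below 2.1 Å**, else 0.
  The sum over frames is the *cumulated occupancy* and the per-frame mean the
  *rate of occupancy* — the fraction of simulation time the bond persists;
* **Aggregation and comparison** — occupancy totals per residue, per
  dimerization box (A: TWIST1 120–127, B: 149–157, C: E12 565–574,
  D: 588–594), per category (residue–residue vs residue–base) and by
  specificity (side-chain-to-nucleobase contacts are *specific*; phosphate and
  sugar contacts are not); per-base E-box contact profiles over the flanking
  (−1, −1*), consensus (+1, +2, +1*, +2*) and variable central (+3, +4, +3*,
  +4*) positions of 5'-TAGGC**CATCTG**GTCCT-3'; and wild-type-versus-mutant
  reports with percent variation anchored at the wild type (100%);
* **Synthetic ground truth** — a generator that builds an idealized helical
  dimer flanking a B-form-like E-box duplex and synthesizes frames as mean
  structure + per-residue Gaussian displacement, with designated contacts
  whose H···acceptor distance falls below threshold with a planted Bernoulli
  rate per frame. Every analysis stage is validated by recovering what was
  planted.

## Worked example

```bash
dimertraj simulate --out wt  --seed 1 --frames 200
dimertraj simulate --out mut --seed 2 --frames 200 --mutant   # box-B rates halved
dimertraj hbonds --config wt/config.yaml  --out wt_hb
dimertraj hbonds --config mut/config.yaml --out mut_hb
dimertraj compare wt_hb mut_hb --out cmp
```

`wt_hb/occupancy.tsv` lists one persisting hydrogen bond per row, e.g.

```
donor_residue  donor_atom  hydrogen  acceptor_residue  acceptor_atom  category  specific  cumulated_occupancy  rate
LYS145         NZ          HZ1       ASN125            OD1            R-R                 169                  0.845
SER144         OG          HG        DC6               O2             R-base    True      108                  0.540
```

— the K145→N125 loop bond persisted in 169 of 200 frames (rate 0.845, planted
0.85), and serine 144 reads the +1 cytosine of the E-box specifically.
`cmp/box_variation.tsv` then shows the planted destabilization
(R-R-only column):

```
box  variation_rr_percent
A      3.6
B    -51.7
C    -30.3
D     10.6
```

Box B (the helix carrying residue 154) lost half its hydrogen-bond occupancy —
the mutant runs at 48% of the wild-type level, recovering the planted −50%
within sampling noise; boxes A and D, whose contacts were not perturbed,
fluctuate around zero. The scripts in `examples/` walk through each capability
(flexibility metrics, occupancy scoring, interface distances, E-box profiles,
comparison) with printed output and one-line interpretations.

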