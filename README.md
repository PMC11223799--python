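# cgfold

Coarse-grained RNA 3D folding by restrained Monte Carlo, with
replica exchange, chemical-probing restraints, and trajectory clustering.

`cgfold` is a desk-scale folding simulator and analysis toolkit for people
who want to steer RNA 3D models with the kinds of evidence experiments
actually produce: a secondary structure (possibly ambiguous, possibly
pseudoknotted), known noncanonical pairs in Leontis–Westhof notation,
per-nucleotide SHAPE/DMS reactivities, pairwise distance bounds, or a
partial 3D structure whose core should stay frozen.  It represents each
nucleotide as five beads (P, C4', glycosidic N, C2, C4|C6), samples with
Metropolis Monte Carlo (fixed temperature, simulated annealing, or replica
exchange), and analyzes the resulting trajectories — best-fraction
selection, all-against-all RMSD with or without superposition, three
clustering schemes, representative extraction — without re-simulating.

## The model in brief

A base-pair restraint of any Leontis–Westhof family (edges W/H/S,
orientation cis/trans) compiles to three atom–atom distance restraints
between the base beads of the two residues, with targets taken from
idealized pair geometry.  Two modes exist:

* **hard** (slope): a penalty `w·Δd` grows linearly outside the target
  window — use when a single pairing pattern is certain;
* **soft** (well): a bonus `−w` inside the window, no penalty outside —
  use for alternative, mutually incompatible structures (riboswitch-style),
  which hard restraints would smash together into a misfolded compromise.

Residues marked `x` in the dot-bracket input are discouraged from canonical
pairing by an energy penalty.  Chemical-probing restraints add
`w·Σᵢ (fᵢ − rᵢ)²`, where `fᵢ` is 0/1 for geometrically detected
paired/unpaired residues and `rᵢ` the user's reactivity in [0, 1]
(values clamp to [0, 1]; `NA` residues are skipped).

The surrounding potential is a documented surrogate (chain connectivity,
excluded volume, funneled canonical-pair attraction, helix cooperativity,
stacking) — see `docs/methods.md` for every term and constant.

## Worked example

Anneal a 14-mer hairpin from an extended coil under hard
secondary-structure restraints, then cluster the trajectory and evaluate
the best model:

```
$ echo "(((((....)))))" > ss.txt
$ cgfold anneal --seq GGGGGAAAACCCCC --ss-file ss.txt --hard \
        --steps 40000 --frame-every 1000 --seed 1 --out-dir run2
1 trajectories written to run2

$ cgfold analyze --traj run2/trajectory_run00.txt --percent 20 \
        --cluster-method D --threshold 5 --out-dir an2
cluster	size	representative	mean_intra_rmsd
1	9	run0:rep0:step38000	3.303
models: best_model.pdb, cluster_01_model.pdb

$ cgfold eval --model an2/best_model.pdb --ref-ss ss.txt
MCC (base pairs): 1.000
```

Reading the output: `analyze` kept the best-scored 20% of frames, built
their pairwise-superposition RMSD matrix, and ran clustering option D
(max-neighborhood, 5 Å threshold); the largest cluster holds 9 frames and
its representative is the frame at step 38000.  `eval` detects canonical
pairs geometrically in the written model and compares them with the
reference secondary structure as a Matthews correlation coefficient over
all residue pairs — 1.0 means the five restrained stem pairs, and nothing
else, formed.  The harder demonstrations (alternative registers under soft
restraints, probing-guided register selection) use the longer protocols in
`tests/test_acceptance.py`.

Re-running `analyze` with a different `--threshold` or `--cluster-method`
reuses the stored trajectory unchanged.  `gen-fixture` writes synthetic
sequences, structures, coordinates and reactivities so every example runs
without downloads.

## Layout

```
src/cgfold/
  cg_model_io.py         five-bead model; PDB/PDBx-mmCIF; trajectory format
  restraints.py          dot-bracket, Leontis-Westhof records, reactivities,
                         slope/well compilation and scoring
  energy.py              surrogate potential + geometric pair detection
  sampler.py             Metropolis MC, annealing, REMC, frozen residues
  trajectory_analysis.py selection, RMSD, clustering C/D/E, MCC, extraction
  fixtures.py            idealized geometry and synthetic-input generators
  cli.py                 the `cgfold` command
```
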