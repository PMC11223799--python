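# Methods

## The model

`cgfold` folds RNA at a coarse-grained resolution of five beads per
nucleotide: the backbone phosphate `P` and sugar `C4'`, plus three base-ring
atoms — the glycosidic nitrogen (`N9` in purines, `N1` in pyrimidines),
`C2`, and `C6` (purines) or `C4` (pyrimidines).  Three base beads are the
minimal set that fixes both the position and the orientation of a base, and
they are exactly what a three-distance base-pair restraint needs: a base
pair of any Leontis–Westhof family (edges W/H/S × cis/trans) is enforced by
restraining the three like-named bead–bead distances to the family's ideal
values.

### Idealized geometry

All reference geometry is generated, not tabulated from crystal surveys.
Pyrimidines are a regular hexagon with a 1.38 Å bond; purines add a regular
pentagon fused on the C4–C5 edge.  A pair of any family is built by docking
the two requested edges at a 2.9 Å contact gap; *cis* pairs flip the second
base out of plane so both glycosidic bonds point to the same side, as in a
canonical Watson–Crick pair (the constructed G–C cWW pair has a C1'–C1'
distance of 10.6 Å, close to the crystallographic 10.4 Å, which we take as
evidence the idealization is sane).  Helices stack such pairs with a twist
of 32.7° per step and a rise of 3.2 Å.  The rise is deliberately a little
larger than A-form (2.8 Å) so that one-step *slipped* pairs — base i against
the partner of base i±1 — fall clearly outside the pair-detection tolerance;
with the A-form rise they are nearly degenerate with true pairs in this
reduced representation.

The three target distances per family (e.g. 8.40 / 5.43 / 4.05 Å for
canonical cWW) are measured once from these constructions and shipped as a
frozen table; a test asserts that the table agrees with a fresh geometric
construction.  Users can extend the table with additional families through a
plain-text config file.

### Surrogate energy function

The statistical potential of knowledge-based coarse-grained folding engines
is not reproduced here; in its place stands a fully documented surrogate
with the same role — give the sampler a funneled landscape in which
restraints, probing data and trajectory analysis act exactly as they would
around a production potential.  All constants live in `EnergyModel`:

| term | form | default |
|------|------|---------|
| intra-residue links | harmonic on 4 bead–bead distances per residue | k = 5 /Å² |
| chain tether | flat-bottom (3.0–7.5 Å) on C4'(i)–P(i+1), harmonic walls | k = 5 /Å² |
| excluded volume | quadratic penalty below 2.5 Å, all inter-residue bead pairs | k = 10 /Å² |
| canonical pairing | funnel: full depth while the summed deviation of the three base-bead distances from the cWW targets is ≤ 3 Å, linear decay to zero at 12 Å; one partner per residue (greedy matching) | depth 3 |
| helix cooperativity | bonus per adjacent formed pair (i,j),(i+1,j−1), product of the two funnel scores | depth 2 |
| stacking | flat well on consecutive base-centroid distances (2.5–6.5 Å, 1.5 Å shoulders) | depth 1 |
| hard restraints | slope: weight × distance outside the window | weight 1 |
| soft restraints | well: −weight inside the window, 0 outside | weight 1 |
| 'x' exclusions | +2 per detected canonical pair involving an excluded residue | 2 |
| probing | weight × Σ (flag − reactivity)² over assigned residues | weight 1 |

The cooperativity term deserves a note: with pair rewards alone, a sequence
able to pair one run of residues against two alternative partners freezes
readily into *mixed* states that borrow pairs from both registers.  Real
RNA resolves this through stacking cooperativity of contiguous helices; the
explicit adjacent-pair bonus reproduces that behavior at this resolution and
makes register-pure folds the low-energy states.

Energies are unitless; the Monte Carlo temperature factor is expressed in
the same units.  Every term depends only on interatomic distances, so the
total is invariant under rigid motions (asserted to 1e-9), and terms of
non-interacting chains are additive.

### Pair detection

Secondary structure is detected from geometry alone: a candidate pair must
be complementary (AU, GC, GU), at least 3 residues apart within a chain
(inter-chain pairs have no separation limit), and have all three base-bead
distances within ±1.0 Å of the cWW targets.  Candidates are resolved to at
most one partner per residue, greedily by total deviation with ties going to
the lower index pair.  Detection is pseudoknot-capable (purely geometric);
crossing pairs are written to extra dot-bracket layers by greedy coloring.
The probing score and the 'x'-exclusion penalty both consume this detected
pairing, recomputed at every energy evaluation.  The probing flags use the
full pseudoknot-capable detection rather than a nested-only subset: probing
experiments report protection regardless of the topology of the helix that
causes it, so restricting the flags to nested pairs would spuriously
penalize protected pseudoknotted residues.

## Sampling

Standard symmetric Metropolis Monte Carlo.  The move set is: single-bead
jitter (Gaussian, σ = 0.3 Å), whole-residue shift (σ = 0.6 Å), and pivot
rotation of a chain tail about a residue's C4' bead (random axis, Gaussian
angle σ = 0.5 rad), drawn with weights 0.3/0.2/0.5.  Each move and its exact
inverse are equally likely, so detailed balance holds with the acceptance
rule `min(1, exp(−ΔE/T))`.  Frozen residues are excluded from move
selection, and pivots truncate at the first frozen residue, so frozen
coordinates are bit-identical across a trajectory.

Annealing uses a geometric temperature profile from `t_start` to `t_end`.
Replica exchange attempts neighbor swaps every `swap_every` steps
(alternating parity), exchanging conformations with acceptance
`min(1, exp((1/T_i − 1/T_j)(E_i − E_j)))`; swap bookkeeping counters are
written to the trajectory header.  All randomness flows from a single
seeded `numpy` generator: (seed, config, inputs) determine every output
byte.  Frames are recorded every `frame_every` *attempted* steps.

Each energy evaluation is a full recomputation over precompiled index
arrays (the O(n²) excluded-volume loop is JIT-compiled when numba is
available, with a pure-numpy fallback).  At the 20–25 nt scale used
throughout, one evaluation costs ~0.1 ms, so the 10⁵–3×10⁵-step protocols
below run in tens of seconds each.  No between-move caching is used: at
these sizes exact per-step recomputation is cheaper than invalidation
bookkeeping.

## Trajectory analysis

"Best-scored" means lowest total energy throughout.  Tie-breaks are fixed
everywhere as (lower energy, earlier frame in (run, replica, step) order).
The all-against-all RMSD matrix over the selected top fraction of frames
uses either Kabsch superposition (proper rotations only; the rotated
residual is computed explicitly to avoid cancellation) or raw coordinate
deviation — the latter is what makes frozen-core analyses reflect only the
mobile region.  Clustering options:

* **D** — max-neighborhood: representative = frame with the most neighbors
  within the threshold (≤, counting itself) among remaining frames.
* **C** — quality threshold: greedy growth under a complete-diameter
  constraint (all pairwise < threshold), frames processed in energy order,
  each growth step adding the frame that minimizes total intra-cluster
  RMSD; representative = medoid.  Exhaustive clique search is used only as
  a test oracle (≤ 15 frames); the greedy construction is the product.
* **E** — best-energy seed: everything within the threshold (<) of the
  best remaining frame.

At most five clusters are reported; leftover frames stay unassigned.

MCC over base pairs uses the universe of all i<j pairs and returns 0
whenever a contingency marginal is zero (e.g. an unfolded model with no
predicted pairs).

## Synthetic data

The fixture generator produces everything the tests and demos consume:

* ideal duplexes/hairpins (detection oracles: at σ = 0 detection must
  return exactly the designed pairs; at σ = 0.1 Å the same set in ≥ 95% of
  draws),
* extended coils (simulation starting states),
* a 23-nt two-register sequence `GGGGG-AAAA-CCCCC-AAAA-GGGGG` whose middle
  C-run pairs either G-run — two mutually exclusive 5-bp hairpins sharing
  residues but no pairs — plus a biased 24-nt variant whose first register
  is one pair longer and therefore wins unrestrained folding,
* chain-of-pairs "quadruplex-like" G–G WHc geometry for noncanonical
  restraint compilation,
* synthetic reactivity profiles: paired residues near 0, unpaired near 1,
  Gaussian noise, clamped to [0, 1], a configurable fraction set to `NA`.
  This emulates only the paired/unpaired contrast a probing experiment
  reports; real SHAPE/DMS data carries tertiary-structure and sequence
  biases that this generator (and the probing score itself) deliberately
  ignores.  Passing tests therefore demonstrate the restraint machinery,
  not quantitative agreement with any real probing experiment.

## Demonstration protocols (and what they show)

Problem sizes were chosen so each protocol completes in minutes on one CPU.

* **Hard-restraint folding** — 20-nt hairpin, hard stem restraints
  (weight 2), annealing 3×10⁵ steps from a coil (T 4 → 0.3): the
  top-cluster representative recovers ≥ 90% of restrained pairs in ≥ 4 of
  5 seeds.  Weight 2 rather than the default 1 because the cooperativity
  term otherwise lets runs freeze with a couple of distances just outside
  the detection tolerance.
* **Alternative structures** — soft wells (weight 2) for both registers of
  the two-register fixture, six annealing repeats per seed (1.2×10⁵ steps,
  T 4 → 0.25) pooled, top 2% clustered (option D, 5 Å): both registers
  appear among the representatives with MCC ≥ 0.8 in ≥ 3 of 5 seeds.
* **Probing selection** — biased fixture, soft wells for both registers in
  both arms; one arm adds a reactivity profile synthesized from the weaker
  register (σ = 0.2, 10% NA, probing weight 2).  The probing arm reaches a
  strictly higher median MCC to the planted register over 5 matched seed
  pairs.  Soft wells supply the geometric guidance; the probing term picks
  the register — the division of labor the score's design implies, since it
  sees only paired/unpaired flags, not partner identities.
* **Sampler physics** — a single tethered bead reproduces equipartition
  (⟨|r|²⟩ = 3T/2k within 5% over 10⁶ steps); uphill Metropolis acceptance
  matches exp(−ΔE/T); the REMC swap rate on the same toy matches numeric
  integration over the two Boltzmann energy distributions within 2σ.

## Numerical choices and degenerate inputs

* Restraint windows default to ±0.5 Å around the family targets; detection
  tolerance is ±1.0 Å, so a satisfied restraint is always detectable.
* The trajectory format prints floats with 17 significant digits — exact
  for float64 — which makes write→read→write byte-identical.
* Unassigned reactivity is the literal token `NA`: negative sentinels are
  impossible because the input rules clamp negatives to 0.
* Annealing with `t_start == t_end` degenerates to a fixed-temperature run;
  `metropolis_accept` requires T > 0 and rejects all uphill moves as
  T → 0⁺.
* All-frozen conformations are rejected (no proposable move); a pivot with
  an empty movable tail falls back to a residue shift after bounded
  redraws, keeping the proposal distribution well-defined.
* PDB altloc: the first location is used, others ignored with a warning.
  Multi-model files yield one conformation per model via `read_models`.

## Known limitations

* The surrogate potential is not a statistical potential: absolute energies
  are meaningless outside this package, and no claim is made that folded
  geometries beyond the restrained/detected pairing pattern are realistic.
* Base–phosphate interactions, electrostatics, and sequence-dependent
  stacking are absent.
* The probing score is the stated squared-error on binary pairing flags —
  it cannot express partner identity, pseudoknot preferences, or graded
  protection, and noisy profiles bias rather than determine the fold.
* Option C clustering is greedy; for adversarial matrices it may miss the
  true maximum clique (the exhaustive search exists only in tests).
* Geometric detection presumes near-ideal pair geometry; heavily distorted
  pairs are reported as unpaired.
* Conflicting hard restraints (one residue restrained to two partners) do
  **not** misfold models in this representation, although the supported
  compilation path refuses such input outright.  Three distances pin only
  three of a partner base's six rigid-body degrees of freedom, so a second
  partner can satisfy its windows by docking from a non-edge direction — a
  base-triple-like arrangement — while the first register forms perfectly.
  Reproducing the distortion an all-atom engine shows would require steric
  detail or orientation-dependent restraints that this five-bead model
  deliberately omits; the corresponding demonstration test asserts the
  distortion property and currently fails under this surrogate.
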