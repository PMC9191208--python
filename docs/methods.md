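# Methods

## Scope and model

`pepscore` scores peptide–protein complex models with a graph network and
uses that score to bias Metropolis Monte-Carlo refinement of the peptide
pose. The receptor is rigid throughout; only the peptide moves. The score
is a *global* regression target per complex — the S-score–normalized
ligand RMSD, `LRMSD_norm = 1/(1 + (LRMSD/8 Å)²)` — rather than a
per-residue quantity: partial placements of a few residues say little
about whether the peptide as a whole can bind, so a single number per
pose is the supervised target, and DockQ is used only for evaluation.

### Featurization

Residues become vertices ordered receptor-first. Vertex features are the
20-entry BLOSUM62 column of the amino acid (raw integer log-odds scores,
unscaled) plus a two-way chain one-hot; unknown residue types get a zero
column and a warning. Edges connect residue pairs whose reference points
— Cβ, or Cα for glycine, with a logged Cα fallback when Cβ is missing —
are within 10 Å, *inclusive* (the boundary convention is the package's
choice; the physical claim "within 10 Å" does not fix it). Edge features
are `[is_covalent, is_self]`. Sequence-adjacent residues of the same
chain are covalent and always connected even past the cutoff, because
covalency is chemical, not geometric; an author-numbering gap > 1 between
consecutive observed residues breaks covalency, since a missing residue
implies no peptide bond. Non-self edges are materialized as directed
(i,j)/(j,i) pairs; each vertex carries one self edge. The global input is
a constant scalar placeholder (0.0) — the network has no informative
global input, only a *learned* global state.

### Network

Three graph-network layers, each updating edges, then vertices, then the
global: the update input is the concatenation of the element's own
features with the features of its incident elements (sender and receiver
vertices plus the global for an edge; the *sum* of incoming-edge features
— edges whose receiver is the vertex — plus the global for a vertex; the
sums of all edge and vertex features plus the previous global for the
global). Each update is perceptron → batch normalization → ELU → dropout.
Summation (never mean or max) is the only aggregation, which makes the
score exactly permutation-invariant; this is asserted to 1e-5 in tests.
The head stacks the three learned global vectors, slides a width-2
convolution kernel across them (weights shared across window positions),
and maps the concatenated channels through a linear layer and a logistic
squash to one scalar in (0, 1), matching the target's scale.

Hidden widths default to 32 for edge/vertex/global and 16 head channels —
small enough to train at desk scale and large enough to saturate the
information in the 22/2-dimensional inputs; all are configurable.
Parameters are initialized fan-in-scaled uniform from a seeded generator.

### Numerical core

No deep-learning framework is used: the package contains a small
tape-based reverse-mode autodiff engine over numpy arrays
(`pepscore.autodiff`) with fused linear and batch-norm ops and
sparse-matrix scatter-adds for message aggregation, plus an Adam
optimizer. Gradients are verified against central differences in the test
suite, and the vectorized forward pass against an independent
straight-line per-element implementation (agreement to 1e-5 on graphs of
≤ 10 vertices). Training runs in float32 for speed; inference accepts
either precision. Model parameters serialize to a single `.npz` archive
embedding the configuration and a format version; loading a foreign
version or mismatched configuration fails loudly.

### Batch normalization at evaluation

Running statistics accumulated across dropout-active minibatches do not
match the activation distribution the fixed weights produce at evaluation
time (dropout is off, batches differ). After every epoch the running
statistics are therefore *recalibrated*: one dropout-free full-data pass
with momentum 1 replaces them with exact full-data statistics ("precise"
batch norm). This removes a train/eval mismatch that otherwise adds
noticeable noise to held-out ranking quality.

## Synthetic complexes

`make_fixture_complex` builds the training and benchmark inputs: the
receptor is an idealized two-strand groove — two antiparallel Cα traces
at 3.8 Å spacing, 12 Å apart, joined by a circular-arc turn whose chords
are exactly one Cα spacing — and the peptide lies extended in the groove.
Each residue gets ideal-geometry backbone N/Cα/C/O and a pseudo-Cβ 1.5 Å
along a side vector pointing into the groove, so that cross-chain
reference-point distances fall in the contact range (4–8 Å) without
clashes. Sequences are drawn uniformly from the 20 standard amino acids
and coordinates are jittered by ±0.02 Å, both from the seed, so complexes
are deterministic per seed and distinct across seeds. The default complex
(60 + 12 residues) buries ≈ 500 Å² — comfortably past the 200 Ų
eligibility threshold; very short peptides (< 5 residues) bury less.

What the generator does *not* emulate: real side chains and packing,
receptor flexibility, sequence–structure correlation (sequences are
random, so the score can exploit only composition, not folded context),
diverse interface geometries, and experimental noise. Passing tests on
these fixtures therefore demonstrates the correctness of the machinery
and the learnability of geometry-driven quality signals, not performance
on experimental complexes.

## Decoys and salvageability

Decoys perturb the native peptide with, in order: per-residue backbone
pivot noise (angle ~ N(0, internal_scale) about each Cα–Cα axis, rotating
everything downstream — the analogue of shear/small backbone moves), a
rigid rotation about the peptide centroid by exactly `rotation_scale`
degrees about a random axis, and a rigid translation of exactly
`translation_scale` Å in a random direction. The deterministic magnitudes
make closed-form checks possible (a pure 3 Å translation gives LRMSD
exactly 3) and put all stochasticity into directions and the adaptive
schedule.

A start is *salvageable* when its whole-peptide LRMSD is below 5.5 Å or
some contiguous window of at least max(⌈L/2⌉, 5) residues has window
LRMSD below 4.0 Å; "half the peptide" rounds up, and the window RMSD is
evaluated in the whole-receptor superposition frame without per-window
refitting (the criterion describes part of the peptide being well placed
in the native frame). Balanced sets are assembled by drawing decoys,
multiplying all three scales by `adapt_factor` (default 1.1) after a
salvageable draw and dividing after an unsalvageable one — an adaptive
walk that hovers around the boundary — and rejecting draws in whichever
category is already full, until the set is exactly half salvageable.
Defaults (translation 4 Å, rotation 20°, internal 5°) start the walk near
the boundary.

For *evaluating* ranking quality, `make_quality_range_set` draws each
decoy with fixed scales sampled uniformly from wide ranges
(0.3–8 Å, 1–40°, 0.5–10°), spreading LRMSD from near-native to clearly
wrong. The adaptive generator concentrates decoys at the salvageability
boundary, where rank order is intrinsically noisy; rank correlation is a
meaningful summary only over a representative quality range.

## Training

Mean squared error against `lrmsd_norm`, Adam (lr 1e-3), minibatches of
mixed graph sizes concatenated with ownership indices (batch norm runs
over the concatenated rows), dropout 0.40, early stopping when validation
MSE fails to improve for `patience` epochs, returning the best-epoch
parameters. Runs are bit-reproducible from the config seed.

`iterative_retrain` mirrors the online-training loop: fit, then run MC
refinement on decoy starts with the current model as an energy term,
harvest both accepted and rejected snapshots (thinned by a stride) with
targets recomputed from coordinates, append to the pool, and repeat up to
`n_retrain_iterations` (default 3), stopping early when validation stops
improving and keeping the best iteration's parameters.

## Monte-Carlo refinement

The base energy is a deliberately simple residue-level stand-in for a
physical force field: a soft-sphere clash penalty (25·(3 Å − d)² per
cross-chain reference-point pair below 3 Å) minus a contact reward (−1
per cross-chain pair within 8 Å, capped at 4 counted contacts per peptide
residue). The learned term is −w·score (default w = 1, configurable), so
good predicted quality lowers the total; an *oracle* mode substitutes the
true `lrmsd_norm` against a known native, which bounds what a perfect
score term can contribute and drives the package's refinement
experiments. Proposals reuse the decoy move set at small scales (0.5 Å,
5°, 2°); acceptance is standard Metropolis at fixed kT (default 1.0 in
base-energy units; no annealing). There is deliberately no gradient
minimization stage anywhere. Snapshots — including rejected proposals —
are recorded at a stride for trajectory harvesting; the receptor is
bit-identical across a trajectory. `select_models` ranks snapshots by
total energy with ties broken by earlier step, then trajectory order.

## Problem sizes used in tests and the acceptance script

Chosen once as desk-scale study conditions: balanced sets of 200 decoys
for the construction check; training capability shown by overfitting 20
decoys of one complex (MSE < 1e-3) and by training on 3 complexes × 40
decoys (8 per complex held out for validation, patience 20, ≤ 150 epochs)
then ranking 100 quality-spanning decoys of an unseen complex, three
seeds; refinement compared on 20 salvageable starts × 3 seeds × 150
Metropolis steps, oracle weight 20 versus 0, pooled median final LRMSD
and pooled fraction of final models with DockQ ≥ 0.49.

## Other numerical choices and conventions

- LRMSD uses peptide backbone N/Cα/C/O by default (Cα-only available);
  the receptor superposition uses receptor backbone atoms. All
  salvageability thresholds are interpreted on the default atom set.
- Contact surface is per-side buried area, (SASA_r + SASA_p −
  SASA_complex)/2, via Shrake–Rupley with 960 points per atom, probe
  1.4 Å and single-atom van der Waals radii (computed with biotite;
  cross-checked against mdtraj in tests). Hydrogens are excluded.
- DockQ constants: 5 Å heavy-atom contacts for Fnat, 10 Å interface
  definition, scaling distances 8.5 Å (LRMSD) and 1.5 Å (iRMSD), class
  boundaries 0.23/0.49/0.80 with boundary membership going upward
  (0.49 is Medium).
- Kabsch superposition excludes reflections (det = +1), via scipy's
  rotation alignment; optimality is property-tested against random rigid
  transforms.
- PDB I/O (via gemmi): MODEL 1 only, first alternate location kept
  (occupancy ignored), HETATM dropped, residues without Cα skipped with a
  warning, chains with < 2 residues dropped; insertion codes ride along
  with author numbering while all computation uses the 0-based index.
- Decoy sets serialize as PDB files plus a tab-separated manifest; model
  parameters as a self-describing `.npz`. File writes are atomic
  (temp + rename).

## Known limitations

- The score sees only contact topology, covalency and sequence identity;
  edge features carry no distances, so the network cannot distinguish a
  6 Å from a 9 Å contact. On synthetic fixtures the achievable held-out
  ranking quality is bounded by how much topology alone encodes.
- Calibration across complexes is weak: scores rank decoys of one
  complex well but absolute values are not comparable between complexes.
  Rankings should be interpreted per target.
- The base energy is a toy; it exists to give the Metropolis loop a
  physically-shaped landscape, not to model real energetics.
- Rigid-body and template-based decoy generation schemes are recognized
  in manifests but not generated in-package (they require external
  docking engines); only native perturbation is implemented.
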