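# Methods

This note documents the models and procedures implemented in `kinodock`,
the defaults and why they were chosen, and what the synthetic study
conditions do and do not establish about real data.

## Data curation

Bioactivity records carry a pChEMBL value, the −log₁₀ of a molar IC50, Ki
or Kd. The three activity types are pooled deliberately: mixing them adds
heterogeneity (IC50 depends on assay setup in ways Ki does not) but
multiplies the usable training data, and the scoring function is meant as
a ranking tool rather than a thermodynamic predictor. Replicate
measurements for a compound–kinase pair are combined by plain arithmetic
mean after discarding records on mutant proteins; no weighting by activity
type is applied because there is no principled basis for one.

Compound filters are inclusive bounds on RDKit descriptors: molecular
weight 250–750 Da, H-bond donors ≤ 10, acceptors ≤ 15, rotatable bonds
≤ 15 — a deliberately lax drug-likeness window that keeps molecules likely
to dock sensibly. Missing descriptors produce a distinct "undetermined"
status rather than a silent rejection, so curation reports can separate
"filtered out" from "could not be evaluated".

Structure curation keeps X-ray structures with resolution ≤ 2.5 Å, a
binding-site quality score ≥ 8, and ≤ 5 missing residues (the three
filters are applied jointly). Kinase binding sites adopt four canonical
geometries from the DFG motif (in/out) and the αC helix (in/out); per
kinase and per geometry the highest-quality structure is retained, so
every kinase contributes at most four complementary pockets.
"DFG-out-like" annotations are folded into "out" to preserve the
four-cell grid. Quality ties break by lower resolution, then structure id,
making selection deterministic.

## Clash score

Docked poses — especially from generative docking methods — can interpenetrate
the protein. The clash score of a pose is

    clash = Σ_pairs max(0, r₁ + r₂ − d)

over all (ligand atom, protein atom) pairs in which the protein atom lies
within 4 Å of any ligand atom (closed boundary), with d the Euclidean
distance and r₁, r₂ Bondi van der Waals radii (H 1.20, C 1.70, N 1.55,
O 1.52, S 1.80, F 1.47, Cl 1.75, Br 1.85, I 1.98, P 1.80 Å; unknown
elements fall back to 1.50 Å with a logged warning). The linear overlap
form was chosen as the simplest functional consistent with the roles of d,
r₁ and r₂; because the operating threshold is calibrated on the score
distribution itself, downstream behaviour is robust to the exact form.
The 4 Å pre-selection is an exact optimization, not an approximation:
contributions vanish once d exceeds the radius sum, which is below 4 Å for
all supported element pairs — a property the test suite verifies against
an unrestricted all-pairs oracle.

Poses with clash < 10 (strict) are retained — the operating criterion.
`fit_clash_threshold` recomputes μ + 3σ (sample mean, sample SD with
ddof = 1) of a score population so the criterion can be recalibrated for a
new engine; under a single normal population the 3σ rule retains ≳ 99.7%
of genuine poses.

All atoms present in the input files participate; no implicit-hydrogen
reconstruction is attempted, since docked outputs vary in protonation and
guessing would silently change scores.

## Ligand preparation and RMSD

Unassigned stereocenters and double-bond geometries are enumerated
(RDKit), preserving any stereochemistry already specified, deduplicated by
canonical SMILES, and capped at 32 isomers per compound as a combinatorial
guard; truncation warns. Docking boxes are the axis-aligned bounding box
of the pocket point cloud padded by 5 Å on every face.

Benchmark RMSD between poses of the same molecule is the minimum over
graph automorphisms of the heavy-atom RMSD *without* re-superposition:
docking accuracy is judged in the fixed receptor frame, and automorphism
minimization prevents symmetric groups (e.g. a flipped phenyl ring) from
inflating the deviation.

## Fingerprints

Both fingerprints build on iteratively hashed circular atom environments.
The atom invariant tuple is the ECFP-standard set: (element, formal
charge, aromatic flag, heavy-atom degree, attached-H count, ring flag).
The depth-0 identifier hashes this tuple; depth-k hashes the depth-(k−1)
identifier together with the sorted (bond order, neighbor identifier)
list, making identifiers invariant under atom relabeling.

- **ECFP**: every environment of depth 0..2 sets bit (id mod 2048).
- **PLEC**: heavy-atom ligand–protein contacts within 4.5 Å (closed
  boundary) are found; for each contact, every pair of (ligand environment
  at depth i ≤ 2, protein environment at depth j ≤ 4) — the full Cartesian
  product of depths — is hashed into 65536 bits. Depths and cutoff follow
  the original PLEC publication's defaults and are exposed as parameters.

Hashing is 32-bit FNV-1a over a canonical serialization, reduced modulo
the width; `nbits` must be a power of two so the modular reduction uses
well-mixed low bits. This makes fingerprints bit-identical across runs and
platforms without external dependencies. Protein-side environments use the
residue-local graph actually provided; for PDB inputs (which carry no bond
table) covalent bonds are inferred by a 1.9 Å heavy-atom distance
criterion, charges set to 0 and aromaticity to false — the protein side
encodes local topology, not chemistry annotations.

## Scoring network and training

The scoring function is a 3-layer fully connected regressor:
input (2048 ECFP or 65536 PLEC) → 4000 → 1000 → 1, ReLU activations, and
inverted dropout of 0.25 on the input and both hidden activations during
training only. Training minimizes MSE with Adam at a fixed 1e-5 learning
rate, batch size 128, 100 epochs; after each epoch the held-out R² is
recorded and the best checkpoint is returned, not the final epoch. The
optimizer, loss and R²-based checkpoint metric are package choices where
the procedure was otherwise underdetermined; R² here is the squared
Pearson correlation (the scoring-function convention — affine
miscalibration is not penalized), with the coefficient-of-determination
variant available behind a flag. Weights initialize with a uniform fan-in
scheme from the config seed; the implementation is a self-contained dense
network on NumPy arrays (forward, backprop, Adam), which at fingerprint
widths used here trains in seconds on one CPU. Non-finite losses abort
with a diagnostic rather than silently continuing.

Two modelling modes exist: one pooled network over all kinases (the
default for PLEC, where the protein side of the fingerprint carries target
information) and per-kinase ECFP models restricted to kinases with at
least 100 unique inhibitors (ligand-only fingerprints cannot distinguish
targets, so each kinase needs its own model and enough data to fit one).

## Splits

Random, compound and kinase strategies partition activity records 80:20;
entity strategies hold out whole compounds or kinases, measuring
generalization to unseen molecules or targets. Candidate partitions are
resampled 25 times and the one minimizing the Kolmogorov–Smirnov statistic
between train and test pChEMBL distributions is kept — a deterministic
implementation of distribution-matched split curation. Entity packing is
greedy-closest toward the 20% record target, so with equal-sized entities
the split is exact; with very unequal entities the achievable deviation is
bounded by the largest entity, which is a property of the data, not the
splitter.

## Aggregation

A compound–kinase prediction aggregates many pose scores: per
(structure, isomer) group the top-3 poses by engine rank are kept, and the
final avg_score is the flat arithmetic mean over all retained scores
across groups — not a mean of group means, so structures contributing more
surviving poses weigh proportionally. Rank-based (not model-score-based)
top-k selection trusts the engine's own pose prioritization.
`evaluate_aggregation_strategies` compares top-1/top-2/top-3/all-mean R²
on the same prediction set; under independent per-pose noise, averaging
provably reduces variance, which the simulation check reproduces.

## Pose database

One SQLite file holds six tables — proteins, structures, compounds,
isomers, activities, poses — with enforced foreign keys and a uniqueness
constraint on (isomer, structure, engine, rank). Pose MOL blocks are
zlib-compressed blobs with the uncompressed size stored alongside;
round-trips are bit-exact. `PRAGMA foreign_key_check` backs the
`db-audit` command.

## Synthetic study conditions

The generators define the conditions every test and the acceptance script
run under:

- **Toy complexes**: ~40 protein atoms on a jittered 8 Å shell and a
  compact bonded ligand blob; ligand displacement is scan-bracketed and
  bisected until the clash score is within ±10% of the requested target.
  This exercises geometry, selection and scoring — not real pocket shapes.
- **Planted SAR**: X ~ Bernoulli(0.1) over 256 bits, w ~ N(0, 0.25²),
  y = Xw + ε with ε ~ N(0, 0.3²) and n = 5,000. The analytic noise ceiling
  is R²_max = v/(v + σ²) with v = p(1−p)·Σw²; under the default spec this
  is ≈ 0.94, and both ridge regression and the network reach it within
  0.05. Training at this toy width uses hidden layers 256/64 and learning
  rate 1e-3 — the full-width schedule (4000/1000, 1e-5) scaled so the same
  100-epoch budget converges; full-width defaults remain unchanged.
- **Toy benchmark tables**: curation inputs with a planted fraction of MW
  violations, mutant records and low-resolution structures, plus exact
  expected surviving counts computed alongside.

What passing these conditions shows: the filters, scores, fingerprints,
splits, trainer and persistence are each correct against independent
oracles and analytic ground truth, and the pipeline is deterministic end
to end. What they do not show: predictive performance on real kinase data,
which depends on real docking engines, real pocket geometry, and
literature-scale training sets outside the scope of these fixtures.

## Numerical and degenerate-input conventions

Boundary conventions are closed everywhere (drug-likeness bounds, the 4 Å
clash selection, the 4.5 Å contact cutoff); the clash filter itself is
strict (< threshold). Empty point lists, empty graphs, single-score
threshold fits, one-entity splits, and constant observations raise
errors; kinases with one test point are flagged and excluded from group
means rather than contributing a meaningless R². All randomness flows
through explicitly seeded counter-based (Philox) generators, so every
fixture and every pipeline run is reproducible cross-platform.

## Known limitations

- The mock engine places rigid conformers; it preserves every contract of
  the engine interface but produces no chemically meaningful poses.
  Adapters for external Vina/DiffDock-compatible executables raise a clear
  "engine unavailable" error when unconfigured.
- The clash functional is linear in overlap; a normalized form would
  rescale the threshold (recalibrate with `fit_clash_threshold` if
  changed).
- PLEC protein environments inherit whatever atoms the structure file
  provides; truncated binding-site files yield truncated environments.
- No covalent-inhibitor handling, no homology models, no cavity detection:
  pocket points are supplied by the caller or the fixtures.
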