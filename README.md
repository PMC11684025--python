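# kinodock

Docking-informed prediction of kinase inhibitor affinity.

Protein kinases are the largest drug-target family in oncology, and most
inhibitors bind many kinases at once, so estimating a compound's affinity
across the kinome — not just against one target — is central to selectivity
profiling. `kinodock` implements a structure-based pipeline for this task:
curated kinase binding-site structures and literature bioactivities are
combined with docked ligand poses, each pose is encoded as a
protein–ligand extended connectivity (PLEC) fingerprint, and a neural
scoring function maps the fingerprint to a predicted pChEMBL value
(the unified −log₁₀ molar activity, pooling pIC50/pKi/pKd).

## What the package does

- **Curation** (`kinodock.curation`) — drug-likeness filters on compounds
  (MW 250–750 Da, HBD ≤ 10, HBA ≤ 15, rotatable bonds ≤ 15, inclusive
  bounds), arithmetic averaging of replicate pChEMBL values per
  compound–kinase pair with mutant records discarded, and structure
  selection: resolution ≤ 2.5 Å, quality score ≥ 8, ≤ 5 missing residues,
  then the highest-quality structure per DFG-in/out × αC-helix-in/out
  conformation (≤ 4 structures per kinase).
- **Complexes** (`kinodock.complexes`) — PDB/MOL I/O, stereoisomer
  enumeration, docking boxes (pocket bounding box + 5 Å padding), and a
  steric clash score: the sum over ligand–protein atom pairs within 4 Å of
  the linear van der Waals overlap max(0, r₁ + r₂ − d). Poses with clash
  score < 10 are retained; the threshold can be recalibrated as μ + 3σ of a
  fitted normal on any engine's score population. Symmetry-aware ligand
  RMSD (minimum over graph automorphisms, fixed receptor frame) supports
  docking benchmarks.
- **Fingerprints** (`kinodock.fingerprints`) — deterministic ECFP (2048
  bits) and PLEC (65536 bits; ligand depth 2, protein depth 4, 4.5 Å
  contacts) built on 32-bit FNV-1a hashing of iterated atom environments.
- **Model** (`kinodock.model`) — the 3-layer scoring network
  (input → 4000 → 1000 → 1, ReLU, dropout 0.25, Adam at 1e-5, batch 128,
  100 epochs, best test-epoch checkpoint), leakage-aware random /
  compound / kinase 80:20 splits curated by Kolmogorov–Smirnov distance,
  squared-Pearson R² metrics with per-kinase and per-group roll-ups.
- **Pipeline** (`kinodock.pipeline`) — a pluggable docking-engine contract
  (with a deterministic mock engine), flat-mean aggregation over the top-3
  ranked poses of every structure × isomer, and an SQLite pose database
  (proteins, structures, compounds, isomers, activities, zlib-compressed
  poses) with enforced foreign keys.
- **Synthetic** (`kinodock.synthetic`) — deterministic toy generators:
  complexes with controlled clash, fingerprint data with a planted linear
  structure–activity relationship and a known noise ceiling, and raw
  curation tables with planted filter violations.

## Worked example

```python
import numpy as np
from kinodock import curation, model, pipeline, synthetic

# toy raw tables with planted curation defects
tb = synthetic.make_toy_benchmark(seed=5, n_kinases=3, n_compounds=10,
                                  n_structures_per_kinase=1,
                                  frac_bad_resolution=0.0)
structs = [curation.KinaseStructure(r.structure_id, r.accession, r.pdb_code,
                                    r.resolution, r.quality_score,
                                    r.missing_residues, r.dfg_state,
                                    r.ac_helix_state, r.kinase_group,
                                    tb["pdb_texts"][r.structure_id])
           for r in tb["structures"].itertuples()]

db = pipeline.PoseDatabase("poses.sqlite")
for s in structs:
    db.store_protein(s.accession, kinase_group=s.kinase_group)
for s in curation.select_structures(structs):
    db.store_structure(s)

net = model.ScoringNetwork(
    model.ScoringNetworkSpec(input_bits=2048, hidden1=32, hidden2=16), seed=0)
records = pipeline.run_pipeline(["CC(=O)Nc1ccc(O)cc1"], ["K000"],
                                pipeline.MockEngine(), db, net, seed=1)
r = records[0]
print(r.accession, r.n_poses_used, round(r.avg_score, 3))
```

This prints `K000 9 0.077`: the compound's two–three surviving poses per
isomer in the kinase's structure were PLEC-encoded and scored, and the flat
mean of the 9 retained pose scores is the predicted pChEMBL. (The network
here is untrained, so the value reflects random initial weights; after
`model.train` on curated data the same call yields calibrated affinities.)

The same flow is available from the shell:

```bash
kinodock curate  --db poses.sqlite --activities acts.csv \
                 --compounds cmpds.csv --structures structs.csv --pdb-dir pdbs/
kinodock predict --db poses.sqlite --model net.kdm \
                 --smiles-file query.smi --kinases K000,K001 --out pred.csv
kinodock db-audit --db poses.sqlite
```

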