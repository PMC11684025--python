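"""Shared fixtures: toy complexes, oracle helpers, and a curated toy DB."""

from __future__ import annotations

import numpy as np
import pytest

from kinodock import complexes, curation, pipeline, synthetic
from kinodock.complexes import AtomSite, LigandPose, ProteinStructure


def random_complex(rng, n_lig: int = 3, n_prot: int = 5, spread: float = 4.0):
    """Random toy complex with atoms close enough to overlap."""
    elements = ["C", "N", "O", "S", "H"]
    lig = LigandPose(
        pose_id="rnd",
        isomer_id="rnd",
        structure_id="rnd",
        engine="mock",
        rank=1,
        engine_score=0.0,
        atoms=[
            AtomSite(element=str(rng.choice(elements)),
                     coords=tuple(rng.uniform(-spread, spread, 3)))
            for _ in range(n_lig)
        ],
        bonds=[(i, i + 1, 1.0) for i in range(n_lig - 1)],
    )
    prot = ProteinStructure(
        structure_id="rnd",
        atoms=[
            AtomSite(element=str(rng.choice(elements)),
                     coords=tuple(rng.uniform(-spread, spread, 3)))
            for _ in range(n_prot)
        ],
    )
    return lig, prot


def brute_force_clash(pose: LigandPose, protein: ProteinStructure) -> float:
    """All-pairs clash oracle: no 4 A pre-selection shortcut."""
    total = 0.0
    for la in pose.atoms:
        for pa in protein.atoms:
            d = float(np.linalg.norm(np.array(la.coords) - np.array(pa.coords)))
            total += max(0.0, la.vdw_radius + pa.vdw_radius - d)
    return total


@pytest.fixture(scope="session")
def toy_db_factory(tmp_path_factory):
    """Factory building a curated pose database from toy benchmark tables."""

    def build(name: str, seed: int = 5, n_kinases: int = 3, n_compounds: int = 10,
              n_structures_per_kinase: int = 1):
        tb = synthetic.make_toy_benchmark(
            seed=seed,
            n_kinases=n_kinases,
            n_compounds=n_compounds,
            n_structures_per_kinase=n_structures_per_kinase,
            frac_bad_resolution=0.0,
        )
        structs = [
            curation.KinaseStructure(
                r.structure_id, r.accession, r.pdb_code, r.resolution,
                r.quality_score, r.missing_residues, r.dfg_state,
                r.ac_helix_state, r.kinase_group, tb["pdb_texts"][r.structure_id],
            )
            for r in tb["structures"].itertuples()
        ]
        path = tmp_path_factory.mktemp("dbs") / f"{name}.sqlite"
        db = pipeline.PoseDatabase(str(path))
        for s in structs:
            db.store_protein(s.accession, kinase_group=s.kinase_group)
        for s in curation.select_structures(structs):
            db.store_structure(s)
        db.commit()
        return db, tb

    return build
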