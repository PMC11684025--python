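"""End-to-end orchestration: docking-engine contract, pose database, score
aggregation, and the SMILES-to-prediction pipeline.

A run takes a list of compound SMILES and kinase accessions, enumerates
stereoisomers, docks every isomer into every curated structure of each
kinase through a pluggable engine (a deterministic mock engine is provided;
adapters for real Vina/DiffDock-compatible executables shell out when
configured), discards clashing poses (clash score < 10 retained), encodes
the top-3 surviving poses per (structure, isomer) as PLEC fingerprints,
scores them with the neural network, and reports the flat arithmetic mean
over all retained pose scores as the predicted pChEMBL.  Everything —
proteins, structures, compounds, isomers, activities, poses — is persisted
in a single SQLite file with enforced foreign keys; pose MOL blocks are
zlib-compressed.
"""

from __future__ import annotations

import shutil
import sqlite3
import subprocess
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from . import complexes, fingerprints, model as model_mod
from .complexes import DockingBox, LigandPose, ProteinStructure
from .curation import CompoundRecord, KinaseStructure

__all__ = [
    "DockingEngine",
    "MockEngine",
    "ExternalEngine",
    "PredictionRecord",
    "PoseDatabase",
    "mock_dock",
    "aggregate_prediction",
    "evaluate_aggregation_strategies",
    "run_pipeline",
]


class DockingEngine(Protocol):
    """Contract every docking engine adapter satisfies."""

    name: str
    needs_box: bool

    def dock(
        self,
        isomer_smiles: str,
        structure: ProteinStructure,
        box: DockingBox | None,
        n_poses: int,
        seed: int,
    ) -> list[LigandPose]: ...


@dataclass
class PredictionRecord:
    """Aggregated affinity prediction for one compound-kinase pair."""

    smiles: str
    accession: str
    engine: str
    n_poses_used: int
    per_pose: list[tuple[str, str, int, float]]  # (structure, isomer, rank, score)
    avg_score: float | None
    error: str | None = None


def _pose_from_mol(mol, conf_id: int, **meta) -> LigandPose:
    order_map = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}
    conf = mol.GetConformer(conf_id)
    atoms = [
        complexes.AtomSite(
            element=mol.GetAtomWithIdx(i).GetSymbol(),
            coords=(
                float(conf.GetAtomPosition(i).x),
                float(conf.GetAtomPosition(i).y),
                float(conf.GetAtomPosition(i).z),
            ),
        )
        for i in range(mol.GetNumAtoms())
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map.get(str(b.GetBondType()), 1.0))
        for b in mol.GetBonds()
    ]
    return LigandPose(atoms=atoms, bonds=bonds, **meta)


class MockEngine:
    """Deterministic stand-in engine for tests and toy pipelines.

    Embeds one rigid 3D conformer of the isomer and places seeded random
    rigid-body copies (rotation + translation) with their centroids inside
    the box; engine scores are a seeded strictly decreasing sequence.
    """

    name = "mock"
    needs_box = True

    def dock(
        self,
        isomer_smiles: str,
        structure: ProteinStructure,
        box: DockingBox | None,
        n_poses: int = 5,
        seed: int = 0,
    ) -> list[LigandPose]:
        if box is None:
            raise ValueError("mock engine requires a docking box")
        if n_poses <= 0:
            return []
        rng = np.random.Generator(np.random.Philox([seed, fingerprints.fnv1a32(
            f"{isomer_smiles}|{structure.structure_id}".encode())]))
        mol = complexes.embed_3d(isomer_smiles, seed=seed)
        conf = mol.GetConformer()
        xyz = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        xyz -= xyz.mean(axis=0)
        span = 2.0 * np.abs(xyz).max()
        half = np.asarray(box.extents) / 2.0
        if span > 2.0 * float(half.max()):
            raise ValueError("docking box smaller than the ligand extent")
        center = np.asarray(box.center)
        poses = []
        base_score = -float(rng.uniform(7.0, 12.0))
        for k in range(n_poses):
            # Haar-ish random rotation via QR of a Gaussian matrix
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            margin = np.minimum(half * 0.5, half)
            offset = rng.uniform(-margin, margin)
            placed = xyz @ q.T + center + offset
            atoms = [
                complexes.AtomSite(
                    element=mol.GetAtomWithIdx(i).GetSymbol(),
                    coords=tuple(np.round(placed[i], 4)),
                )
                for i in range(mol.GetNumAtoms())
            ]
            order_map = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}
            bonds = [
                (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                 order_map.get(str(b.GetBondType()), 1.0))
                for b in mol.GetBonds()
            ]
            poses.append(
                LigandPose(
                    pose_id=f"{structure.structure_id}:{k + 1}",
                    isomer_id=isomer_smiles,
                    structure_id=structure.structure_id,
                    engine=self.name,
                    rank=k + 1,
                    engine_score=round(base_score + 0.3 * k, 4),
                    atoms=atoms,
                    bonds=bonds,
                )
            )
        return poses


def mock_dock(isomer_smiles, structure, box, n_poses: int = 5, seed: int = 0):
    """Functional wrapper around :class:`MockEngine`."""
    return MockEngine().dock(isomer_smiles, structure, box, n_poses, seed)


class ExternalEngine:
    """Adapter that shells out to a user-installed docking executable.

    Absent executables raise a clear "engine unavailable" error rather than
    silently degrading to the mock engine.
    """

    def __init__(self, name: str, executable: str, needs_box: bool = True):
        self.name = name
        self.executable = executable
        self.needs_box = needs_box

    def dock(self, isomer_smiles, structure, box, n_poses=5, seed=0):
        if shutil.which(self.executable) is None:
            raise RuntimeError(
                f"engine {self.name!r} unavailable: executable "
                f"{self.executable!r} not found on PATH"
            )
        raise NotImplementedError(
            f"adapter for {self.name!r} requires a configured invocation template"
        )


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_prediction(
    per_pose: Iterable[tuple[str, str, int, float]], top_k: int = 3
) -> float:
    """Flat mean over the top-``top_k`` ranked poses of every
    (structure, isomer) group.

    ``per_pose`` yields (structure_id, isomer_id, rank, score).  Within each
    group poses are ordered by engine rank (1 = best) and the first
    ``top_k`` retained; the result is the plain arithmetic mean over ALL
    retained scores across groups (not a mean of group means).
    """
    groups: dict[tuple[str, str], list[tuple[int, float]]] = {}
    n = 0
    for structure_id, isomer_id, rank, score in per_pose:
        groups.setdefault((structure_id, isomer_id), []).append((int(rank), float(score)))
        n += 1
    if n == 0:
        raise ValueError("cannot aggregate an empty score list")
    retained = [
        s for members in groups.values() for _, s in sorted(members)[:top_k]
    ]
    return float(np.mean(retained))


def evaluate_aggregation_strategies(
    predictions: Iterable[tuple[object, list[tuple[str, str, int, float]], float]],
) -> dict[str, float]:
    """R-squared of four aggregation strategies on the same prediction set.

    ``predictions`` yields (pair_key, per_pose list, observed value).
    Strategies: ``top1`` (best-ranked pose per group), ``top2``/``top3``
    (flat mean of top-k per group), ``all`` (flat mean of every pose).
    """
    items = list(predictions)
    if len(items) < 2:
        raise ValueError("need at least 2 compound-kinase pairs")
    strategies = {"top1": 1, "top2": 2, "top3": 3, "all": None}
    obs = [float(o) for _, _, o in items]
    out: dict[str, float] = {}
    for name, k in strategies.items():
        preds = [
            aggregate_prediction(pp, top_k=(k if k is not None else len(pp) or 1))
            for _, pp, _ in items
        ]
        out[name] = model_mod.r_squared(preds, obs)
    return out


# ---------------------------------------------------------------------------
# Pose database

_SCHEMA = """
PRAGMA foreign_keys = ON;
CREATE TABLE IF NOT EXISTS proteins (
    accession TEXT PRIMARY KEY,
    gene TEXT,
    kinase_group TEXT
);
CREATE TABLE IF NOT EXISTS structures (
    structure_id TEXT PRIMARY KEY,
    accession TEXT NOT NULL REFERENCES proteins(accession),
    pdb_code TEXT,
    resolution REAL,
    quality_score REAL,
    missing_residues INTEGER,
    dfg_state TEXT,
    ac_helix_state TEXT,
    pdb_text TEXT
);
CREATE TABLE IF NOT EXISTS compounds (
    compound_id TEXT PRIMARY KEY,
    smiles TEXT NOT NULL,
    mw REAL, hbd INTEGER, hba INTEGER, rotb INTEGER
);
CREATE TABLE IF NOT EXISTS isomers (
    isomer_id TEXT PRIMARY KEY,
    compound_id TEXT NOT NULL REFERENCES compounds(compound_id),
    isomeric_smiles TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS activities (
    activity_id INTEGER PRIMARY KEY,
    compound_id TEXT NOT NULL REFERENCES compounds(compound_id),
    accession TEXT NOT NULL REFERENCES proteins(accession),
    pchembl REAL NOT NULL,
    activity_type TEXT
);
CREATE TABLE IF NOT EXISTS poses (
    pose_id TEXT PRIMARY KEY,
    isomer_id TEXT NOT NULL REFERENCES isomers(isomer_id),
    structure_id TEXT NOT NULL REFERENCES structures(structure_id),
    engine TEXT NOT NULL,
    rank INTEGER NOT NULL,
    engine_score REAL,
    clash_score REAL,
    molblock_z BLOB,
    molblock_size INTEGER,
    UNIQUE (isomer_id, structure_id, engine, rank)
);
"""

_TABLES = ["proteins", "structures", "compounds", "isomers", "activities", "poses"]


class PoseDatabase:
    """SQLite persistence for the whole pipeline (foreign keys enforced)."""

    def __init__(self, path: str):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- stores ------------------------------------------------------------
    def _execute(self, sql: str, params: tuple):
        try:
            self.conn.execute(sql, params)
        except sqlite3.IntegrityError as e:
            raise ValueError(f"database integrity violation: {e}") from e

    def store_protein(self, accession: str, gene: str = "", kinase_group: str = ""):
        self._execute(
            "INSERT OR REPLACE INTO proteins VALUES (?,?,?)",
            (accession, gene, kinase_group),
        )

    def store_structure(self, s: KinaseStructure):
        self._execute(
            "INSERT OR REPLACE INTO structures VALUES (?,?,?,?,?,?,?,?,?)",
            (
                s.structure_id, s.accession, s.pdb_code, s.resolution,
                s.quality_score, s.missing_residues, s.dfg_state,
                s.ac_helix_state, s.pdb_text,
            ),
        )

    def store_compound(self, c: CompoundRecord):
        self._execute(
            "INSERT OR REPLACE INTO compounds VALUES (?,?,?,?,?,?)",
            (c.compound_id, c.smiles, c.mw, c.hbd, c.hba, c.rotb),
        )

    def store_isomer(self, isomer_id: str, compound_id: str, isomeric_smiles: str):
        self._execute(
            "INSERT OR REPLACE INTO isomers VALUES (?,?,?)",
            (isomer_id, compound_id, isomeric_smiles),
        )

    def store_activity(self, compound_id: str, accession: str, pchembl: float,
                       activity_type: str = "pchembl_mean"):
        self._execute(
            "INSERT INTO activities (compound_id, accession, pchembl, activity_type)"
            " VALUES (?,?,?,?)",
            (compound_id, accession, pchembl, activity_type),
        )

    def store_pose(self, pose: LigandPose, clash_score: float | None = None,
                   replace: bool = False):
        molblock = complexes.write_pose_mol(pose)
        raw = molblock.encode("utf-8")
        verb = "INSERT OR REPLACE" if replace else "INSERT"
        self._execute(
            f"{verb} INTO poses (pose_id, isomer_id, structure_id, engine, rank,"
            " engine_score, clash_score, molblock_z, molblock_size)"
            " VALUES (?,?,?,?,?,?,?,?,?)",
            (
                pose.pose_id, pose.isomer_id, pose.structure_id, pose.engine,
                pose.rank, pose.engine_score, clash_score,
                zlib.compress(raw), len(raw),
            ),
        )

    def commit(self):
        self.conn.commit()

    # -- loads -------------------------------------------------------------
    def load_pose_molblock(self, pose_id: str) -> str:
        row = self.conn.execute(
            "SELECT molblock_z, molblock_size FROM poses WHERE pose_id = ?",
            (pose_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown pose {pose_id!r}")
        raw = zlib.decompress(row[0])
        assert len(raw) == row[1]
        return raw.decode("utf-8")

    def load_structures(self, accession: str) -> list[KinaseStructure]:
        rows = self.conn.execute(
            "SELECT structure_id, accession, pdb_code, resolution, quality_score,"
            " missing_residues, dfg_state, ac_helix_state, pdb_text"
            " FROM structures WHERE accession = ? ORDER BY structure_id",
            (accession,),
        ).fetchall()
        return [KinaseStructure(*row[:8], pdb_text=row[8], kinase_group="") for row in rows]

    def known_accessions(self) -> list[str]:
        return [r[0] for r in self.conn.execute(
            "SELECT accession FROM proteins ORDER BY accession")]

    def table_counts(self) -> dict[str, int]:
        return {
            t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in _TABLES
        }

    def audit_foreign_keys(self) -> list[tuple]:
        """Run SQLite's referential-integrity audit; empty list = clean."""
        return self.conn.execute("PRAGMA foreign_key_check").fetchall()


# ---------------------------------------------------------------------------
# End-to-end run


def run_pipeline(
    smiles_list: Sequence[str],
    accessions: Sequence[str],
    engine: DockingEngine,
    db: PoseDatabase,
    model: model_mod.ScoringNetwork,
    seed: int = 0,
    n_poses: int = 5,
    clash_threshold: float = 10.0,
    top_k: int = 3,
    max_isomers: int = 32,
    plec_params: dict | None = None,
) -> list[PredictionRecord]:
    """SMILES-to-prediction run against curated structures in ``db``.

    For every compound: enumerate isomers, dock each isomer into every
    structure of each requested kinase, clash-filter the poses, PLEC-encode
    the top-``top_k`` surviving poses per (structure, isomer), score them
    with ``model``, and aggregate to one predicted pChEMBL per
    (compound, kinase).  Poses are persisted in ``db``.  Invalid SMILES
    yield an error record (the run continues); unknown accessions raise
    immediately, listing the known ones.
    """
    from rdkit import Chem

    known = set(db.known_accessions())
    unknown = [a for a in accessions if a not in known]
    if unknown:
        raise ValueError(
            f"unknown accession(s) {unknown}; database knows {sorted(known)}"
        )
    plec_params = plec_params or {}
    nbits = plec_params.get("nbits", model.spec.input_bits)
    records: list[PredictionRecord] = []
    for smiles in smiles_list:
        if Chem.MolFromSmiles(smiles) is None:
            for acc in accessions:
                records.append(PredictionRecord(
                    smiles=smiles, accession=acc, engine=engine.name,
                    n_poses_used=0, per_pose=[], avg_score=None,
                    error="invalid SMILES",
                ))
            continue
        compound_id = f"cmpd-{fingerprints.fnv1a32(smiles.encode()):08x}"
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        db.store_compound(CompoundRecord(compound_id=compound_id, smiles=canon))
        isomers = complexes.enumerate_isomers(smiles, max_isomers=max_isomers)
        for acc in accessions:
            per_pose: list[tuple[str, str, int, float]] = []
            n_used = 0
            for structure in db.load_structures(acc):
                protein = complexes.read_protein_pdb(
                    structure.pdb_text, structure_id=structure.structure_id
                )
                box = complexes.make_box(protein.coords(), padding=5.0)
                prot_graph, prot_xyz = fingerprints.graph_from_protein(protein)
                for iso_idx, iso_smiles in enumerate(isomers):
                    isomer_id = f"{compound_id}-i{iso_idx}"
                    db.store_isomer(isomer_id, compound_id, iso_smiles)
                    pose_seed = np.random.SeedSequence(
                        [seed, fingerprints.fnv1a32(
                            f"{isomer_id}|{structure.structure_id}".encode())]
                    ).generate_state(1)[0] % (2**31)
                    try:
                        poses = engine.dock(
                            iso_smiles, structure, box, n_poses, int(pose_seed)
                        )
                    except ValueError:
                        continue  # this isomer failed embedding/docking only
                    scored = []
                    for pose in poses:
                        pose.pose_id = f"{isomer_id}:{structure.structure_id}:{pose.rank}"
                        pose.isomer_id = isomer_id
                        report = complexes.pose_clash_score(pose, protein)
                        db.store_pose(pose, clash_score=report.total, replace=True)
                        scored.append((pose, report.total))
                    surviving = complexes.filter_poses(scored, clash_threshold)
                    surviving = sorted(surviving, key=lambda pc: pc[0].rank)[:top_k]
                    for pose, _clash in surviving:
                        lig_graph, lig_xyz = fingerprints.graph_from_pose(pose)
                        fp = fingerprints.plec(
                            lig_graph, lig_xyz, prot_graph, prot_xyz,
                            nbits=nbits,
                            **{k: v for k, v in plec_params.items() if k != "nbits"},
                        )
                        score = float(model_mod.predict(model, fp.to_dense())[0])
                        per_pose.append(
                            (structure.structure_id, isomer_id, pose.rank, score)
                        )
                        n_used += 1
            if per_pose:
                records.append(PredictionRecord(
                    smiles=smiles, accession=acc, engine=engine.name,
                    n_poses_used=n_used, per_pose=per_pose,
                    avg_score=aggregate_prediction(per_pose, top_k=top_k),
                ))
            else:
                records.append(PredictionRecord(
                    smiles=smiles, accession=acc, engine=engine.name,
                    n_poses_used=0, per_pose=[], avg_score=None,
                    error="no valid pose",
                ))
    db.commit()
    return records


def predictions_to_csv(records: Sequence[PredictionRecord]) -> str:
    """Render prediction records as the CSV the `predict` command writes."""
    lines = ["smiles,accession,engine,n_poses,avg_score,error"]
    for r in records:
        score = "" if r.avg_score is None else f"{r.avg_score:.6f}"
        lines.append(
            f"{r.smiles},{r.accession},{r.engine},{r.n_poses_used},{score},{r.error or ''}"
        )
    return "\n".join(lines) + "\n"
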