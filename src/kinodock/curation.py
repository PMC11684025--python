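"""Curation of kinase bioactivity and structure records.

Raw inputs are literature affinity measurements (pChEMBL values: pooled
pIC50/pKi/pKd on the -log10 molar scale), the compounds they refer to, and
candidate binding-site structures with quality metadata.  Curation applies
drug-likeness filters to compounds, averages replicate measurements per
compound-kinase pair (discarding mutant-protein records), and keeps at most
one structure per kinase per binding-site conformation (DFG-in/out x
alphaC-helix in/out), preferring the highest quality score.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CompoundRecord",
    "ActivityRecord",
    "KinaseStructure",
    "DruglikenessRules",
    "CuratedDataset",
    "FilterStatus",
    "compute_descriptors",
    "filter_compound",
    "aggregate_activities",
    "select_structures",
    "build_dataset",
    "read_activities_csv",
    "read_compounds_csv",
    "read_structures_csv",
]


class FilterStatus(enum.Enum):
    """Outcome of a compound drug-likeness check."""

    PASS = "pass"
    FAIL = "fail"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CompoundRecord:
    """A small molecule with precomputed drug-likeness descriptors.

    ``mw`` is the molecular weight in Da; ``hbd``/``hba`` are hydrogen-bond
    donor/acceptor counts and ``rotb`` the rotatable-bond count, all under the
    chemistry toolkit's default definitions (see :func:`compute_descriptors`).
    Descriptors may be ``None`` when they could not be computed; such
    compounds are rejected with :attr:`FilterStatus.UNDETERMINED`.
    """

    compound_id: str
    smiles: str
    mw: float | None = None
    hbd: int | None = None
    hba: int | None = None
    rotb: int | None = None


@dataclass(frozen=True)
class ActivityRecord:
    """One literature affinity measurement for a compound-kinase pair."""

    compound_id: str
    accession: str
    pchembl: float
    activity_type: str = "pIC50"  # one of pIC50 / pKi / pKd, pooled downstream
    is_mutant: bool = False


@dataclass(frozen=True)
class KinaseStructure:
    """One curated kinase binding-site structure with quality metadata."""

    structure_id: str
    accession: str
    pdb_code: str
    resolution: float
    quality_score: float
    missing_residues: int
    dfg_state: str  # "in", "out" or "out-like"
    ac_helix_state: str  # "in" or "out"
    kinase_group: str = ""
    pdb_text: str = ""


@dataclass(frozen=True)
class DruglikenessRules:
    """Inclusive drug-likeness bounds; defaults are the curation operating
    point: MW 250-750 Da, HBD <= 10, HBA <= 15, rotatable bonds <= 15."""

    mw_min: float = 250.0
    mw_max: float = 750.0
    hbd_max: int = 10
    hba_max: int = 15
    rotb_max: int = 15

    def __post_init__(self) -> None:
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if min(self.hbd_max, self.hba_max, self.rotb_max) < 0:
            raise ValueError("descriptor maxima must be >= 0")


@dataclass
class CuratedDataset:
    """Model-ready dataset: filtered compounds, averaged activities (one row
    per compound-kinase pair), and selected structures."""

    compounds: list[CompoundRecord] = field(default_factory=list)
    activities: list[tuple[str, str, float]] = field(default_factory=list)
    structures: list[KinaseStructure] = field(default_factory=list)

    def validate(self) -> None:
        compound_ids = {c.compound_id for c in self.compounds}
        accessions = {s.accession for s in self.structures}
        seen: set[tuple[str, str]] = set()
        for cid, acc, _ in self.activities:
            if cid not in compound_ids:
                raise ValueError(f"activity references unknown compound {cid!r}")
            if acc not in accessions:
                raise ValueError(f"activity references structureless kinase {acc!r}")
            key = (cid, acc)
            if key in seen:
                raise ValueError(f"duplicate activity for pair {key!r}")
            seen.add(key)


def compute_descriptors(smiles: str) -> tuple[float, int, int, int]:
    """Compute (mw, hbd, hba, rotb) from a SMILES string with RDKit defaults.

    Raises ``ValueError`` naming the string when it does not parse.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, Lipinski

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return (
        float(Descriptors.MolWt(mol)),
        int(Lipinski.NumHDonors(mol)),
        int(Lipinski.NumHAcceptors(mol)),
        int(Lipinski.NumRotatableBonds(mol)),
    )


def filter_compound(
    compound: CompoundRecord, rules: DruglikenessRules | None = None
) -> FilterStatus:
    """Check a compound against inclusive drug-likeness bounds.

    Missing or non-finite descriptors yield ``UNDETERMINED`` rather than a
    silent fail, so callers can distinguish "outside bounds" from "unknown".
    """
    rules = rules or DruglikenessRules()
    values = (compound.mw, compound.hbd, compound.hba, compound.rotb)
    if any(v is None for v in values) or not math.isfinite(float(compound.mw)):
        return FilterStatus.UNDETERMINED
    ok = (
        rules.mw_min <= compound.mw <= rules.mw_max
        and compound.hbd <= rules.hbd_max
        and compound.hba <= rules.hba_max
        and compound.rotb <= rules.rotb_max
    )
    return FilterStatus.PASS if ok else FilterStatus.FAIL


def aggregate_activities(
    records: Iterable[ActivityRecord],
) -> list[tuple[str, str, float]]:
    """Average replicate measurements per (compound, kinase) pair.

    Mutant-protein records are discarded; pIC50/pKi/pKd are pooled
    indiscriminately and the plain arithmetic mean is taken.  Output is
    sorted by (compound_id, accession) for determinism.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.is_mutant:
            continue
        groups.setdefault((rec.compound_id, rec.accession), []).append(rec.pchembl)
    return [
        (cid, acc, sum(vals) / len(vals))
        for (cid, acc), vals in sorted(groups.items())
    ]


def select_structures(
    structures: Iterable[KinaseStructure],
    res_max: float = 2.5,
    quality_min: float = 8.0,
    missing_max: int = 5,
) -> list[KinaseStructure]:
    """Quality-filter structures, then keep the best per conformation.

    Structures failing resolution <= ``res_max``, quality >= ``quality_min``
    or missing residues <= ``missing_max`` are removed (joint application).
    Per kinase and per (DFG, alphaC) state combination the highest-quality
    structure is retained — DFG "out-like" is folded into "out" so the grid
    has at most four cells — so each kinase keeps at most 4 structures.
    Ties on quality break by lower resolution, then structure_id.
    """
    surviving = [
        s
        for s in structures
        if s.resolution <= res_max
        and s.quality_score >= quality_min
        and s.missing_residues <= missing_max
    ]
    best: dict[tuple[str, str, str], KinaseStructure] = {}
    for s in surviving:
        dfg = "out" if s.dfg_state == "out-like" else s.dfg_state
        key = (s.accession, dfg, s.ac_helix_state)
        cur = best.get(key)
        if cur is None or _rank(s) < _rank(cur):
            best[key] = s
    return sorted(best.values(), key=lambda s: s.structure_id)


def _rank(s: KinaseStructure) -> tuple[float, float, str]:
    # Higher quality first, then lower resolution, then lexicographic id.
    return (-s.quality_score, s.resolution, s.structure_id)


def build_dataset(
    activities: Iterable[ActivityRecord],
    compounds: Iterable[CompoundRecord],
    structures: Iterable[KinaseStructure],
    rules: DruglikenessRules | None = None,
    *,
    res_max: float = 2.5,
    quality_min: float = 8.0,
    missing_max: int = 5,
) -> CuratedDataset:
    """Compose the three curation filters into a model-ready dataset.

    Compounds must pass :func:`filter_compound`; activities are averaged with
    :func:`aggregate_activities` and kept only when both their compound
    survived and their kinase retains at least one selected structure.
    Duplicate compound ids with conflicting SMILES raise ``ValueError``.
    """
    by_id: dict[str, CompoundRecord] = {}
    for c in compounds:
        prev = by_id.get(c.compound_id)
        if prev is not None and prev.smiles != c.smiles:
            raise ValueError(
                f"conflicting SMILES for compound id {c.compound_id!r}: "
                f"{prev.smiles!r} vs {c.smiles!r}"
            )
        by_id.setdefault(c.compound_id, c)

    rules = rules or DruglikenessRules()
    kept_compounds = {
        cid: c
        for cid, c in by_id.items()
        if filter_compound(c, rules) is FilterStatus.PASS
    }
    kept_structures = select_structures(
        structures, res_max=res_max, quality_min=quality_min, missing_max=missing_max
    )
    kept_accessions = {s.accession for s in kept_structures}
    kept_activities = [
        (cid, acc, val)
        for cid, acc, val in aggregate_activities(activities)
        if cid in kept_compounds and acc in kept_accessions
    ]
    # Compounds without surviving activities are retained as curated
    # chemistry; the dataset invariant only requires activities to resolve.
    ds = CuratedDataset(
        compounds=sorted(kept_compounds.values(), key=lambda c: c.compound_id),
        activities=kept_activities,
        structures=kept_structures,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Tabular I/O

_ACTIVITY_COLS = ["compound_id", "accession", "pchembl", "activity_type", "is_mutant"]
_COMPOUND_COLS = ["compound_id", "smiles", "mw", "hbd", "hba", "rotb"]
_STRUCTURE_COLS = [
    "structure_id",
    "accession",
    "pdb_code",
    "resolution",
    "quality_score",
    "missing_residues",
    "dfg_state",
    "ac_helix_state",
    "kinase_group",
]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_activities_csv(path) -> list[ActivityRecord]:
    df = _read_table(path, _ACTIVITY_COLS)
    return [
        ActivityRecord(
            compound_id=str(r.compound_id),
            accession=str(r.accession),
            pchembl=float(r.pchembl),
            activity_type=str(r.activity_type),
            is_mutant=bool(r.is_mutant),
        )
        for r in df.itertuples()
    ]


def read_compounds_csv(path) -> list[CompoundRecord]:
    df = _read_table(path, _COMPOUND_COLS)

    def _opt(v, cast):
        return None if pd.isna(v) else cast(v)

    return [
        CompoundRecord(
            compound_id=str(r.compound_id),
            smiles=str(r.smiles),
            mw=_opt(r.mw, float),
            hbd=_opt(r.hbd, int),
            hba=_opt(r.hba, int),
            rotb=_opt(r.rotb, int),
        )
        for r in df.itertuples()
    ]


def read_structures_csv(path, pdb_texts: dict[str, str] | None = None) -> list[KinaseStructure]:
    """Read a structure metadata table; ``pdb_texts`` maps structure_id to
    PDB file content (optional — metadata-only curation works without it)."""
    df = _read_table(path, _STRUCTURE_COLS)
    pdb_texts = pdb_texts or {}
    return [
        KinaseStructure(
            structure_id=str(r.structure_id),
            accession=str(r.accession),
            pdb_code=str(r.pdb_code),
            resolution=float(r.resolution),
            quality_score=float(r.quality_score),
            missing_residues=int(r.missing_residues),
            dfg_state=str(r.dfg_state),
            ac_helix_state=str(r.ac_helix_state),
            kinase_group=str(r.kinase_group),
            pdb_text=pdb_texts.get(str(r.structure_id), ""),
        )
        for r in df.itertuples()
    ]
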