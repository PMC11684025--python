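"""Protein-ligand complexes: structure/pose I/O, docking boxes, isomer
enumeration, steric clash scoring, and symmetry-aware ligand RMSD.

The clash score quantifies unphysical atomic overlap of a docked pose: for
every (ligand atom, nearby protein atom) pair the linear van der Waals
overlap max(0, r1 + r2 - d) is accumulated, where d is the Euclidean
distance and r1, r2 the Bondi vdW radii of the two atoms.  Protein atoms are
pre-selected within 4 A of the ligand (closed boundary); since contributions
vanish once d exceeds the radius sum (< 4 A for common elements), the
pre-selection is an exact shortcut, not an approximation.  A data-driven
retention threshold mu + 3*sigma can be fitted on a population of scores;
the operating default is 10.0 (poses with clash < 10 are kept).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "VDW_RADII",
    "AtomSite",
    "ProteinStructure",
    "LigandPose",
    "DockingBox",
    "ClashReport",
    "vdw_radius",
    "enumerate_isomers",
    "make_box",
    "clash_contribution",
    "pose_clash_score",
    "fit_clash_threshold",
    "filter_poses",
    "ligand_rmsd",
    "read_protein_pdb",
    "read_pose_mol",
    "write_pose_mol",
    "embed_3d",
]

# Bondi van der Waals radii (A) for the elements common in kinase pockets
# and drug-like ligands; anything else falls back to 1.50 A with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "P": 1.80,
}
_DEFAULT_VDW = 1.50


def vdw_radius(element: str) -> float:
    el = element.capitalize()
    r = VDW_RADII.get(el)
    if r is None:
        logger.warning("unknown element %r: using default vdW radius %.2f A", element, _DEFAULT_VDW)
        return _DEFAULT_VDW
    return r


@dataclass(frozen=True)
class AtomSite:
    """One atom: element symbol, Cartesian coordinates (A), vdW radius (A)."""

    element: str
    coords: tuple[float, float, float]
    vdw_radius: float = 0.0

    def __post_init__(self):
        if self.vdw_radius <= 0.0:
            object.__setattr__(self, "vdw_radius", vdw_radius(self.element))
        if not all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")


@dataclass
class ProteinStructure:
    structure_id: str
    atoms: list[AtomSite]
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("protein structure has no atoms")
        if not self.residue_labels:
            self.residue_labels = ["UNK"] * len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass
class LigandPose:
    """Ranked 3D coordinates of one docked isomer in one structure."""

    pose_id: str
    isomer_id: str
    structure_id: str
    engine: str
    rank: int
    engine_score: float
    atoms: list[AtomSite]
    bonds: list[tuple[int, int, float]]  # (i, j, order); aromatic = 1.5

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("pose rank must be >= 1")
        if not self.atoms:
            raise ValueError("ligand pose has no atoms")
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) index out of range for {n} atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class DockingBox:
    """Axis-aligned search box: center and full edge lengths, both in A."""

    center: tuple[float, float, float]
    extents: tuple[float, float, float]

    def __post_init__(self):
        if min(self.extents) <= 0:
            raise ValueError("box extents must be positive")


@dataclass
class ClashReport:
    pose_id: str
    per_pair: list[tuple[int, int, float]]  # (ligand atom, protein atom, A)
    total: float


def enumerate_isomers(smiles: str, max_isomers: int = 32) -> list[str]:
    """Enumerate unassigned stereocenters and double-bond geometries.

    Already-specified stereochemistry is preserved; output is deduplicated
    canonical isomeric SMILES, capped at ``max_isomers`` (warns on
    truncation).
    """
    from rdkit import Chem
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers,
        StereoEnumerationOptions,
    )

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    opts = StereoEnumerationOptions(
        onlyUnassigned=True, unique=True, maxIsomers=max_isomers + 1
    )
    out: list[str] = []
    seen: set[str] = set()
    for iso in EnumerateStereoisomers(mol, options=opts):
        canon = Chem.MolToSmiles(iso)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
        if len(out) > max_isomers:
            break
    if len(out) > max_isomers:
        warnings.warn(
            f"isomer enumeration for {smiles!r} truncated at {max_isomers}",
            stacklevel=2,
        )
        out = out[:max_isomers]
    return out


def make_box(points, padding: float = 5.0) -> DockingBox:
    """Axis-aligned bounding box of ``points`` padded on every face."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("cannot build a box from an empty point list")
    if padding < 0:
        raise ValueError("padding must be >= 0")
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    center = (lo + hi) / 2.0
    return DockingBox(center=tuple(center), extents=tuple(hi - lo))


def clash_contribution(d: float, r1: float, r2: float) -> float:
    """Linear vdW overlap of two atoms: max(0, r1 + r2 - d), in A."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("vdW radii must be positive")
    return max(0.0, (r1 + r2) - d)


def pose_clash_score(
    pose: LigandPose,
    protein: ProteinStructure,
    selection_cutoff: float = 4.0,
) -> ClashReport:
    """Sum pairwise vdW overlaps between the pose and nearby protein atoms.

    Protein atoms within ``selection_cutoff`` (closed boundary) of any ligand
    atom are selected; all (ligand, selected protein) pairs contribute
    ``clash_contribution``.
    """
    lig_xyz = pose.coords()
    prot_xyz = protein.coords()
    dists = cdist(lig_xyz, prot_xyz)
    selected = np.where((dists <= selection_cutoff).any(axis=0))[0]
    per_pair: list[tuple[int, int, float]] = []
    total = 0.0
    lig_r = pose.radii()
    prot_r = protein.radii()
    for pj in selected:
        overlaps = lig_r + prot_r[pj] - dists[:, pj]
        for li in np.where(overlaps > 0)[0]:
            c = float(overlaps[li])
            per_pair.append((int(li), int(pj), c))
            total += c
    return ClashReport(pose_id=pose.pose_id, per_pair=per_pair, total=total)


def fit_clash_threshold(scores) -> float:
    """Fit a normal distribution to clash scores and return the mu + 3*sigma
    upper limit (sample mean and sample standard deviation, ddof=1)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 scores to fit a threshold")
    return float(arr.mean() + 3.0 * arr.std(ddof=1))


def filter_poses(poses_with_scores, threshold: float = 10.0):
    """Retain (pose, clash_total) entries with total strictly below
    ``threshold``, preserving order.  Accepts (pose, float) pairs or
    bare scores, or ClashReport-bearing poses via a ``clash`` attribute."""
    kept = []
    for item in poses_with_scores:
        if isinstance(item, tuple):
            total = float(item[1])
        elif isinstance(item, (int, float, np.floating)):
            total = float(item)
        else:
            total = float(getattr(item, "clash"))
        if total < threshold:
            kept.append(item)
    return kept


# ---------------------------------------------------------------------------
# Symmetry-aware RMSD


def _pose_to_rdkit(pose: LigandPose):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    em = Chem.RWMol()
    for a in pose.atoms:
        em.AddAtom(Chem.Atom(a.element))
    bt = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, order in pose.bonds:
        em.AddBond(int(i), int(j), bt.get(float(order), Chem.BondType.SINGLE))
    conf = Chem.Conformer(len(pose.atoms))
    for idx, a in enumerate(pose.atoms):
        conf.SetAtomPosition(idx, Point3D(*a.coords))
    mol = em.GetMol()
    mol.AddConformer(conf)
    # docked poses may carry nonstandard valences: no strict sanitization
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def ligand_rmsd(pose_a: LigandPose, pose_b: LigandPose, max_matches: int = 10000) -> float:
    """Minimum heavy-atom RMSD over graph automorphisms, without re-fitting.

    Poses are compared in the shared receptor frame (no Kabsch
    superposition), so equivalent atoms related by molecular symmetry (e.g.
    a flipped para-substituted ring) do not inflate the deviation.  Raises
    ``ValueError`` if the molecular graphs differ.
    """
    from rdkit import Chem

    mol_a = _pose_to_rdkit(pose_a)
    mol_b = _pose_to_rdkit(pose_b)
    heavy_a = [i for i, a in enumerate(pose_a.atoms) if a.element != "H"]
    heavy_b = [i for i, a in enumerate(pose_b.atoms) if a.element != "H"]
    if len(heavy_a) != len(heavy_b):
        raise ValueError("poses have different heavy-atom counts")
    matches = mol_b.GetSubstructMatches(
        mol_a, uniquify=False, useChirality=False, maxMatches=max_matches
    )
    if not matches:
        raise ValueError("molecular graphs do not match (no automorphism found)")
    xyz_a = pose_a.coords()
    xyz_b = pose_b.coords()
    heavy_mask = np.array([pose_a.atoms[i].element != "H" for i in range(len(pose_a.atoms))])
    best = np.inf
    for match in matches:
        mapped = xyz_b[list(match)]
        diff = xyz_a[heavy_mask] - mapped[heavy_mask]
        rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
        best = min(best, rmsd)
    return best


# ---------------------------------------------------------------------------
# File I/O


def read_protein_pdb(
    text: str, structure_id: str = "", include_hetatm: bool = False
) -> ProteinStructure:
    """Parse PDB text into a ProteinStructure (ATOM records; HETATM only when
    ``include_hetatm``).  Malformed coordinate records raise ``ValueError``
    with the offending line number."""
    import biotite.structure.io.pdb as pdb

    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                [float(line[s:e]) for s, e in ((30, 38), (38, 46), (46, 54))]
            except (ValueError, IndexError):
                raise ValueError(f"malformed PDB coordinate record at line {lineno}")
    pdb_file = pdb.PDBFile.read(io.StringIO(text))
    arr = pdb_file.get_structure(model=1)
    if not include_hetatm:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise ValueError("no protein atoms in PDB text")
    atoms = [
        AtomSite(element=str(el).capitalize(), coords=tuple(map(float, xyz)))
        for el, xyz in zip(arr.element, arr.coord)
    ]
    labels = [f"{rn}{ri}" for rn, ri in zip(arr.res_name, arr.res_id)]
    return ProteinStructure(structure_id=structure_id, atoms=atoms, residue_labels=labels)


_BOND_ORDER_FROM_RDKIT = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}


def read_pose_mol(
    text: str,
    pose_id: str = "",
    isomer_id: str = "",
    structure_id: str = "",
    engine: str = "mock",
    rank: int = 1,
    engine_score: float = 0.0,
) -> LigandPose:
    """Parse an MDL MOL (V2000) block into a LigandPose."""
    from rdkit import Chem

    mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        raise ValueError("malformed MOL block")
    conf = mol.GetConformer()
    atoms = [
        AtomSite(
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
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _BOND_ORDER_FROM_RDKIT.get(str(b.GetBondType()), 1.0),
        )
        for b in mol.GetBonds()
    ]
    return LigandPose(
        pose_id=pose_id,
        isomer_id=isomer_id,
        structure_id=structure_id,
        engine=engine,
        rank=rank,
        engine_score=engine_score,
        atoms=atoms,
        bonds=bonds,
    )


def write_pose_mol(pose: LigandPose) -> str:
    """Serialize a LigandPose as an MDL MOL (V2000) block; coordinates keep
    4 decimal places, so read(write(p)) preserves them to < 1e-3 A."""
    from rdkit import Chem

    mol = _pose_to_rdkit(pose)
    return Chem.MolToMolBlock(mol, kekulize=False)


def embed_3d(smiles: str, seed: int = 0):
    """Generate one 3D conformer for a SMILES (RDKit ETKDG, deterministic
    given seed); returns an RDKit Mol with hydrogens added, or raises
    ``ValueError`` when embedding fails."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"3D embedding failed for {smiles!r}")
    return mol
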