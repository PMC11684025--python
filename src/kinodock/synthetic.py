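"""Deterministic toy-data generators.

Everything downstream — curation, clash scoring, fingerprints, the scoring
network, the full pipeline — is testable offline on fixtures produced here.
Generators are pure functions of their specs (Philox counter-based RNG, so
fixtures are identical across platforms):

* :func:`make_toy_complex` — a jittered-shell "pocket" plus a ligand placed
  to hit a requested clash score (binary search on displacement).
* :func:`plant_sar` — binary fingerprints with a planted linear
  structure-activity relationship and Gaussian noise, with a known analytic
  noise ceiling for held-out R-squared.
* :func:`make_toy_benchmark` — raw activity/compound/structure tables with
  a planted fraction of records that must fail each curation filter, plus
  the expected surviving counts.

Toy ligands come from a small fixed library of valid molecules (5-15 heavy
atoms), so isomer enumeration and fingerprint code paths always see
chemically sensible graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import AtomSite, LigandPose, ProteinStructure, pose_clash_score

__all__ = [
    "TOY_LIGANDS",
    "ToyComplexSpec",
    "PlantedSARSpec",
    "make_toy_complex",
    "plant_sar",
    "sar_noise_ceiling",
    "make_toy_benchmark",
    "toy_pdb_text",
]

# Valid drug-fragment-like molecules, 5-15 heavy atoms.
TOY_LIGANDS: tuple[str, ...] = (
    "CC(=O)Nc1ccc(O)cc1",        # paracetamol
    "c1ccc2[nH]ccc2c1",          # indole
    "CC(C)Cc1ccccc1",            # isobutylbenzene
    "O=C(O)c1ccccc1O",           # salicylic acid
    "c1ccc(-c2ccccn2)cc1",       # 2-phenylpyridine
    "CC(N)Cc1ccccc1",            # amphetamine (unassigned stereocenter)
    "CN1CCN(C)CC1",              # dimethylpiperazine
    "Clc1ccc(F)cc1CO",           # halogenated benzyl alcohol
    "CC=CC(=O)Nc1ccccc1",        # crotonanilide (unassigned alkene)
    "O=S(=O)(N)c1ccccc1",        # benzenesulfonamide
)


@dataclass(frozen=True)
class ToyComplexSpec:
    seed: int = 0
    n_protein_atoms: int = 40
    n_ligand_atoms: int = 8
    target_clash: float = 0.0  # Angstrom; 0 = clash-free

    def __post_init__(self):
        if min(self.n_protein_atoms, self.n_ligand_atoms) < 1:
            raise ValueError("atom counts must be >= 1")
        if self.target_clash < 0:
            raise ValueError("target_clash must be >= 0")


@dataclass(frozen=True)
class PlantedSARSpec:
    seed: int = 0
    n_samples: int = 5000
    nbits: int = 256
    bit_density: float = 0.1
    weight_scale: float = 0.25
    noise_sd: float = 0.3

    def __post_init__(self):
        if not 0.0 < self.bit_density < 1.0:
            raise ValueError("bit_density must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_ELEMENTS = ("C", "N", "O", "S")


def _ligand_cluster(rng, n_atoms: int) -> tuple[list[str], np.ndarray]:
    elements = [str(rng.choice(_ELEMENTS)) for _ in range(n_atoms)]
    # compact blob: chain with 1.5 A steps plus jitter
    coords = np.cumsum(rng.normal(scale=0.9, size=(n_atoms, 3)), axis=0)
    coords -= coords.mean(axis=0)
    return elements, coords


def make_toy_complex(spec: ToyComplexSpec) -> tuple[ProteinStructure, LigandPose]:
    """Protein shell + ligand blob at a controlled clash score.

    Protein atoms sit on a jittered sphere of radius ~8 A.  The ligand is
    slid along +x from far outside toward the shell; displacement is binary-
    searched until the clash score lands within +-10% of ``target_clash``
    (0 requests a strictly clash-free placement).  Deterministic given seed.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    shell_r = 8.0
    dirs = rng.normal(size=(spec.n_protein_atoms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = shell_r + rng.normal(scale=0.4, size=spec.n_protein_atoms)
    prot_xyz = dirs * radii[:, None]
    prot_elements = [str(rng.choice(_ELEMENTS)) for _ in range(spec.n_protein_atoms)]
    protein = ProteinStructure(
        structure_id=f"toy-{spec.seed}",
        atoms=[AtomSite(element=el, coords=tuple(xyz))
               for el, xyz in zip(prot_elements, prot_xyz)],
    )
    lig_elements, lig_xyz = _ligand_cluster(rng, spec.n_ligand_atoms)

    def pose_at(x_offset: float) -> LigandPose:
        placed = lig_xyz + np.array([x_offset, 0.0, 0.0])
        return LigandPose(
            pose_id=f"toy-pose-{spec.seed}",
            isomer_id="toy",
            structure_id=protein.structure_id,
            engine="mock",
            rank=1,
            engine_score=0.0,
            atoms=[AtomSite(element=el, coords=tuple(xyz))
                   for el, xyz in zip(lig_elements, placed)],
            bonds=[(i, i + 1, 1.0) for i in range(spec.n_ligand_atoms - 1)],
        )

    far = shell_r + 30.0
    if spec.target_clash == 0.0:
        pose = pose_at(far)
        assert pose_clash_score(pose, protein).total == 0.0
        return protein, pose

    # Clash is zero far away, grows as the ligand approaches the shell, and
    # peaks when it overlaps it.  Scan inward for a bracket, then bisect.
    offsets = np.linspace(far, 0.0, 400)
    prev_off, prev_score = far, 0.0
    bracket = None
    for off in offsets:
        score = pose_clash_score(pose_at(float(off)), protein).total
        if score >= spec.target_clash:
            bracket = (float(off), prev_off)  # increasing toward smaller off
            break
        prev_off, prev_score = float(off), score
    if bracket is None:
        raise ValueError(
            f"target clash {spec.target_clash} unreachable with "
            f"{spec.n_ligand_atoms} ligand atoms"
        )
    lo, hi = bracket  # score(lo) >= target >= score(hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        score = pose_clash_score(pose_at(mid), protein).total
        if abs(score - spec.target_clash) <= 0.1 * spec.target_clash:
            return protein, pose_at(mid)
        if score > spec.target_clash:
            lo = mid
        else:
            hi = mid
    raise ValueError("bisection failed to reach target clash")  # pragma: no cover


def plant_sar(spec: PlantedSARSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary fingerprints with a planted linear SAR: y = X.w + eps.

    X ~ Bernoulli(bit_density) i.i.d.; w ~ Normal(0, weight_scale^2) drawn
    once; eps ~ Normal(0, noise_sd^2).  Returns (X, y, w), all deterministic
    given the seed.
    """
    rng = np.random.Generator(np.random.Philox(spec.seed))
    w = rng.normal(scale=spec.weight_scale, size=spec.nbits)
    X = (rng.random((spec.n_samples, spec.nbits)) < spec.bit_density).astype(np.float64)
    eps = rng.normal(scale=spec.noise_sd, size=spec.n_samples) if spec.noise_sd else 0.0
    y = X @ w + eps
    return X, y, w


def sar_noise_ceiling(spec: PlantedSARSpec) -> float:
    """Analytic best achievable R-squared: Var(signal)/(Var(signal)+sd^2),
    with Var(signal) = p(1-p) * sum(w_j^2) under independent Bernoulli bits."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    w = rng.normal(scale=spec.weight_scale, size=spec.nbits)
    p = spec.bit_density
    v = p * (1.0 - p) * float((w**2).sum())
    return v / (v + spec.noise_sd**2)


# ---------------------------------------------------------------------------
# Curation benchmark tables


def toy_pdb_text(seed: int = 0, n_atoms: int = 40) -> str:
    """Tiny synthetic PDB text (shell pocket) the real parser can read."""
    protein, _ = make_toy_complex(ToyComplexSpec(seed=seed, n_protein_atoms=n_atoms,
                                                 n_ligand_atoms=1))
    lines = []
    for i, atom in enumerate(protein.atoms, start=1):
        x, y, z = atom.coords
        el = atom.element
        name = (el + "A")[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} ALA A{(i - 1) // 5 + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


_GROUPS = ("TK", "CMGC", "STE", "AGC", "CAMK")


def make_toy_benchmark(
    seed: int = 0,
    n_kinases: int = 5,
    n_structures_per_kinase: int = 3,
    n_compounds: int = 50,
    activities_per_compound: int = 2,
    frac_mw_violations: float = 0.1,
    frac_mutant: float = 0.1,
    frac_bad_resolution: float = 0.2,
) -> dict:
    """Raw curation tables with planted filter violations.

    Returns a dict with pandas DataFrames ``activities``, ``compounds``,
    ``structures`` (spec'd column names), per-structure ``pdb_texts``, and
    an ``expected`` bookkeeping dict with the planted surviving counts.
    Descriptor values are synthetic draws in plausible ranges; SMILES come
    from the fixed toy-ligand library so they always parse.
    """
    import pandas as pd

    rng = np.random.Generator(np.random.Philox(seed))
    accs = [f"K{k:03d}" for k in range(n_kinases)]
    groups = {acc: _GROUPS[k % len(_GROUPS)] for k, acc in enumerate(accs)}

    n_bad_mw = int(round(frac_mw_violations * n_compounds))
    bad_mw_ids = set(range(n_bad_mw))  # first n_bad_mw compounds violate MW
    compounds = []
    for c in range(n_compounds):
        mw = float(rng.uniform(900, 1200) if c in bad_mw_ids else rng.uniform(300, 700))
        compounds.append({
            "compound_id": f"C{c:04d}",
            "smiles": TOY_LIGANDS[c % len(TOY_LIGANDS)],
            "mw": round(mw, 2),
            "hbd": int(rng.integers(0, 6)),
            "hba": int(rng.integers(0, 10)),
            "rotb": int(rng.integers(0, 12)),
        })

    activities = []
    n_mutant = 0
    pair_seen: set[tuple[str, str]] = set()
    for c in range(n_compounds):
        targets = rng.choice(n_kinases, size=min(activities_per_compound, n_kinases),
                             replace=False)
        for t in targets:
            is_mut = bool(rng.random() < frac_mutant)
            n_mutant += is_mut
            pair = (f"C{c:04d}", accs[t])
            if not is_mut:
                pair_seen.add(pair)
            activities.append({
                "compound_id": pair[0],
                "accession": pair[1],
                "pchembl": round(float(rng.uniform(4.0, 10.0)), 3),
                "activity_type": str(rng.choice(["pIC50", "pKi", "pKd"])),
                "is_mutant": is_mut,
            })

    structures = []
    pdb_texts: dict[str, str] = {}
    states = [("in", "in"), ("in", "out"), ("out", "in"), ("out", "out")]
    n_bad_res = 0
    surviving_structures = 0
    for k, acc in enumerate(accs):
        for s in range(n_structures_per_kinase):
            sid = f"S{k:03d}_{s}"
            bad = rng.random() < frac_bad_resolution
            n_bad_res += bad
            dfg, ac = states[s % 4]
            structures.append({
                "structure_id": sid,
                "accession": acc,
                "pdb_code": f"{1000 + k * 10 + s}",
                "resolution": round(float(rng.uniform(2.6, 3.5) if bad
                                          else rng.uniform(1.2, 2.5)), 2),
                "quality_score": round(float(rng.uniform(8.0, 10.0)), 2),
                "missing_residues": int(rng.integers(0, 6)),
                "dfg_state": dfg,
                "ac_helix_state": ac,
                "kinase_group": groups[acc],
            })
            pdb_texts[sid] = toy_pdb_text(seed=seed * 1000 + k * 10 + s, n_atoms=30)

    # planted survival bookkeeping (structure selection collapses duplicates
    # of the same state combination; compute it exactly)
    per_cell: dict[tuple[str, str, str], int] = {}
    for row in structures:
        if row["resolution"] <= 2.5:
            key = (row["accession"], row["dfg_state"], row["ac_helix_state"])
            per_cell[key] = per_cell.get(key, 0) + 1
    surviving_structures = len(per_cell)
    surviving_kinases = {k for k, _, _ in per_cell}
    surviving_compounds = n_compounds - n_bad_mw
    surviving_pairs = {
        (cid, acc) for cid, acc in pair_seen
        if int(cid[1:]) not in bad_mw_ids and acc in surviving_kinases
    }

    expected = {
        "n_compounds_failing_mw": n_bad_mw,
        "n_surviving_compounds": surviving_compounds,
        "n_mutant_records": n_mutant,
        "n_surviving_structures": surviving_structures,
        "n_surviving_activity_pairs": len(surviving_pairs),
        "groups": groups,
    }
    return {
        "activities": pd.DataFrame(activities),
        "compounds": pd.DataFrame(compounds),
        "structures": pd.DataFrame(structures),
        "pdb_texts": pdb_texts,
        "expected": expected,
    }
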