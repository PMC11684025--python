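"""ECFP-style ligand fingerprints and PLEC protein-ligand interaction
fingerprints.

Both fingerprints hash iteratively grown circular atom neighborhoods.  The
depth-0 identifier of an atom hashes its invariant tuple (element, formal
charge, aromatic flag, heavy-atom degree, attached-H count, ring flag); the
depth-k identifier hashes the atom's depth-(k-1) identifier together with
the sorted (bond order, neighbor depth-(k-1) identifier) list.  ECFP folds
every environment of depth 0..radius into an ``nbits``-wide bit vector.
PLEC pairs ligand and protein environments across all heavy-atom contacts
within a distance cutoff and hashes every (ligand depth i, protein depth j)
identifier pair — the full Cartesian product of depths — into the vector.

Hashing uses 32-bit FNV-1a over a canonical byte serialization, so bit
assignments are deterministic across runs and platforms.  ``nbits`` must be
a power of two (the modular reduction assumes well-mixed low bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomInvariant",
    "MolecularGraph",
    "ContactPair",
    "Fingerprint",
    "fnv1a32",
    "atom_environments",
    "ecfp",
    "find_contacts",
    "plec",
    "graph_from_rdkit",
    "graph_from_pose",
    "graph_from_protein",
]

# (element, formal charge, aromatic, heavy-atom degree, attached H, in ring)
AtomInvariant = tuple[str, int, bool, int, int, bool]


@dataclass(frozen=True)
class MolecularGraph:
    """A simple molecular graph: per-atom invariant tuples and typed bonds."""

    atoms: tuple[AtomInvariant, ...]
    bonds: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i},{j}) in graph of {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    def neighbors(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


@dataclass(frozen=True)
class ContactPair:
    ligand_atom: int
    protein_atom: int
    distance: float


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width binary fingerprint: set-bit indices in [0, nbits)."""

    nbits: int
    set_bits: tuple[int, ...]

    def __post_init__(self):
        bits = tuple(sorted(set(int(b) for b in self.set_bits)))
        object.__setattr__(self, "set_bits", bits)
        if bits and not (0 <= bits[0] and bits[-1] < self.nbits):
            raise ValueError("bit index out of range")

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.nbits, dtype=np.float32)
        if self.set_bits:
            v[list(self.set_bits)] = 1.0
        return v

    def popcount(self) -> int:
        return len(self.set_bits)

    def __or__(self, other: "Fingerprint") -> "Fingerprint":
        if self.nbits != other.nbits:
            raise ValueError("fingerprint widths differ")
        return Fingerprint(self.nbits, tuple(set(self.set_bits) | set(other.set_bits)))


_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def fnv1a32(data: bytes) -> int:
    """32-bit FNV-1a hash; fixed and platform-independent."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


def _hash_tuple(*parts) -> int:
    # Canonical serialization: repr of the flattened parts, UTF-8 encoded.
    return fnv1a32(repr(parts).encode("utf-8"))


def _check_nbits(nbits: int) -> None:
    if nbits < 1 or (nbits & (nbits - 1)) != 0:
        raise ValueError(f"nbits must be a power of two, got {nbits}")


def atom_environments(
    graph: MolecularGraph, atom: int, max_depth: int
) -> list[tuple[int, int]]:
    """Iteratively hashed circular environments of one atom.

    Returns [(depth, identifier)] for depths 0..max_depth.  Identifiers are
    invariant under atom relabeling because neighbor contributions are
    sorted before hashing.
    """
    if not (0 <= atom < len(graph.atoms)):
        raise ValueError(f"atom index {atom} out of range")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    ids = _all_environments(graph, max_depth)
    return [(d, ids[d][atom]) for d in range(max_depth + 1)]


def _all_environments(graph: MolecularGraph, max_depth: int) -> list[list[int]]:
    """Per-depth identifier lists for every atom (shared iteration)."""
    adj = graph.neighbors()
    current = [_hash_tuple("atom", inv) for inv in graph.atoms]
    layers = [current]
    for _ in range(max_depth):
        nxt = [
            _hash_tuple(
                "env",
                current[i],
                tuple(sorted((order, current[j]) for j, order in adj[i])),
            )
            for i in range(len(graph.atoms))
        ]
        layers.append(nxt)
        current = nxt
    return layers


def ecfp(graph: MolecularGraph, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Extended-connectivity fingerprint: one bit per atom environment of
    depth 0..radius, folded modulo ``nbits``."""
    _check_nbits(nbits)
    if not graph.atoms:
        raise ValueError("empty molecular graph")
    layers = _all_environments(graph, radius)
    bits = {ident % nbits for layer in layers for ident in layer}
    return Fingerprint(nbits=nbits, set_bits=tuple(bits))


def find_contacts(
    ligand_elements: Sequence[str],
    ligand_coords,
    protein_elements: Sequence[str],
    protein_coords,
    cutoff: float = 4.5,
) -> list[ContactPair]:
    """All (ligand heavy atom, protein heavy atom) pairs within ``cutoff``
    (closed boundary), with their Euclidean distances."""
    lig_xyz = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    prot_xyz = np.atleast_2d(np.asarray(protein_coords, dtype=float))
    lig_heavy = [i for i, el in enumerate(ligand_elements) if el != "H"]
    prot_heavy = [j for j, el in enumerate(protein_elements) if el != "H"]
    if not lig_heavy or not prot_heavy:
        return []
    d = cdist(lig_xyz[lig_heavy], prot_xyz[prot_heavy])
    pairs = []
    for a, b in zip(*np.where(d <= cutoff)):
        pairs.append(
            ContactPair(
                ligand_atom=lig_heavy[a],
                protein_atom=prot_heavy[b],
                distance=float(d[a, b]),
            )
        )
    return pairs


def plec(
    ligand_graph: MolecularGraph,
    ligand_coords,
    protein_graph: MolecularGraph,
    protein_coords,
    depth_ligand: int = 2,
    depth_protein: int = 4,
    cutoff: float = 4.5,
    nbits: int = 65536,
) -> Fingerprint:
    """Protein-ligand extended-connectivity fingerprint.

    For every heavy-atom contact within ``cutoff`` and every depth pair
    (i <= depth_ligand, j <= depth_protein), the (ligand environment i,
    protein environment j) identifier pair is hashed into [0, nbits).
    Invariant under rigid motion of the whole complex (depends only on
    pairwise distances and the two graphs).
    """
    _check_nbits(nbits)
    if not ligand_graph.atoms or not protein_graph.atoms:
        raise ValueError("empty molecular graph")
    lig_el = [inv[0] for inv in ligand_graph.atoms]
    prot_el = [inv[0] for inv in protein_graph.atoms]
    contacts = find_contacts(lig_el, ligand_coords, prot_el, protein_coords, cutoff)
    if not contacts:
        return Fingerprint(nbits=nbits, set_bits=())
    lig_layers = _all_environments(ligand_graph, depth_ligand)
    prot_layers = _all_environments(protein_graph, depth_protein)
    bits = set()
    for c in contacts:
        for i in range(depth_ligand + 1):
            lid = lig_layers[i][c.ligand_atom]
            for j in range(depth_protein + 1):
                pid = prot_layers[j][c.protein_atom]
                bits.add(_hash_tuple("plec", i, j, lid, pid) % nbits)
    return Fingerprint(nbits=nbits, set_bits=tuple(bits))


# ---------------------------------------------------------------------------
# Graph construction adapters


def graph_from_rdkit(mol) -> MolecularGraph:
    """Build a MolecularGraph from an RDKit Mol (heavy atoms only; attached
    hydrogens enter the atom invariants)."""
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    remap = {idx: k for k, idx in enumerate(heavy)}
    atoms = []
    for idx in heavy:
        a = mol.GetAtomWithIdx(idx)
        n_h = a.GetTotalNumHs(includeNeighbors=True)
        heavy_deg = sum(1 for nb in a.GetNeighbors() if nb.GetSymbol() != "H")
        atoms.append(
            (
                a.GetSymbol(),
                a.GetFormalCharge(),
                bool(a.GetIsAromatic()),
                heavy_deg,
                int(n_h),
                bool(a.IsInRing()),
            )
        )
    order_map = {"SINGLE": 1.0, "DOUBLE": 2.0, "TRIPLE": 3.0, "AROMATIC": 1.5}
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            bonds.append((remap[i], remap[j], order_map.get(str(b.GetBondType()), 1.0)))
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(bonds))


def graph_from_pose(pose) -> tuple[MolecularGraph, np.ndarray]:
    """MolecularGraph + heavy-atom coordinates from a docked LigandPose.
    Explicit hydrogens in the pose are folded into attached-H counts."""
    import networkx as nx

    elements = [a.element for a in pose.atoms]
    heavy = [i for i, el in enumerate(elements) if el != "H"]
    remap = {i: k for k, i in enumerate(heavy)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(elements))}
    for i, j, order in pose.bonds:
        adj[i].append((j, order))
        adj[j].append((i, order))
    g = nx.Graph()
    g.add_nodes_from(range(len(heavy)))
    bonds = []
    for i, j, order in pose.bonds:
        if i in remap and j in remap:
            bonds.append((remap[i], remap[j], order))
            g.add_edge(remap[i], remap[j])
    ring_atoms = set().union(*nx.cycle_basis(g)) if g.number_of_edges() else set()
    atoms = []
    for i in heavy:
        n_h = sum(1 for j, _ in adj[i] if elements[j] == "H")
        heavy_deg = sum(1 for j, _ in adj[i] if elements[j] != "H")
        aromatic = any(order == 1.5 for _, order in adj[i])
        atoms.append((elements[i], 0, aromatic, heavy_deg, n_h, remap[i] in ring_atoms))
    coords = pose.coords()[heavy]
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(bonds)), coords


def graph_from_protein(protein, bond_cutoff: float = 1.9) -> tuple[MolecularGraph, np.ndarray]:
    """Residue-local MolecularGraph + coordinates for a ProteinStructure.

    PDB files carry no bond table, so covalent bonds between heavy atoms are
    inferred by distance (<= ``bond_cutoff`` A, single order) within and
    between residues; charges are taken as 0 and aromaticity as False —
    protein-side environments encode topology, not chemistry annotations.
    """
    import networkx as nx

    elements = [a.element for a in protein.atoms]
    heavy = [i for i, el in enumerate(elements) if el != "H"]
    coords = protein.coords()[heavy]
    n = len(heavy)
    bonds = []
    if n > 1:
        d = cdist(coords, coords)
        ii, jj = np.where((d <= bond_cutoff) & (d > 0.4))
        bonds = [(int(i), int(j), 1.0) for i, j in zip(ii, jj) if i < j]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in bonds)
    ring_atoms = set().union(*nx.cycle_basis(g)) if g.number_of_edges() else set()
    deg = dict(g.degree())
    atoms = tuple(
        (elements[heavy[k]], 0, False, int(deg.get(k, 0)), 0, k in ring_atoms)
        for k in range(n)
    )
    return MolecularGraph(atoms=atoms, bonds=tuple(bonds)), coords
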