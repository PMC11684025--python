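"""ECFP/PLEC fingerprints against brute-force enumeration oracles, plus
invariance and determinism properties.

The oracles recompute environment identifiers by independent recursive
subtree expansion (per atom, no shared layer iteration) and contacts by an
explicit O(n*m) double loop, then compare bit sets with the implementation.
"""

import numpy as np
import pytest
from rdkit import Chem

from kinodock.fingerprints import (
    ContactPair,
    Fingerprint,
    MolecularGraph,
    atom_environments,
    ecfp,
    find_contacts,
    fnv1a32,
    graph_from_pose,
    graph_from_protein,
    graph_from_rdkit,
    plec,
    _hash_tuple,
)

TOY_SMILES = [
    "C", "CC", "CCO", "CC(=O)O", "c1ccccc1", "c1ccncc1", "CC(N)C(=O)O",
    "C1CC1", "C1CCC1", "CC(C)C", "CCN(CC)CC", "c1ccc2ccccc2c1",
    "CC(=O)Nc1ccc(O)cc1", "O=S(=O)(N)c1ccccc1", "FC(F)(F)c1ccccc1",
    "C#N", "CC#CC", "OCC(O)CO", "c1cc[nH]c1", "CN1CCN(C)CC1",
]


# ---------------------------------------------------------------------------
# Independent oracles


def recursive_env(graph: MolecularGraph, atom: int, depth: int) -> int:
    """Environment identifier by direct recursion (independent of the
    implementation's shared layer-by-layer iteration)."""
    if depth == 0:
        return _hash_tuple("atom", graph.atoms[atom])
    adj = graph.neighbors()
    prev = recursive_env(graph, atom, depth - 1)
    neighbor_ids = tuple(
        sorted((order, recursive_env(graph, j, depth - 1)) for j, order in adj[atom])
    )
    return _hash_tuple("env", prev, neighbor_ids)


def oracle_ecfp(graph: MolecularGraph, radius: int, nbits: int) -> set[int]:
    return {
        recursive_env(graph, a, d) % nbits
        for a in range(len(graph.atoms))
        for d in range(radius + 1)
    }


def oracle_contacts(lig_el, lig_xyz, prot_el, prot_xyz, cutoff):
    pairs = set()
    for i, (el_i, xi) in enumerate(zip(lig_el, lig_xyz)):
        if el_i == "H":
            continue
        for j, (el_j, xj) in enumerate(zip(prot_el, prot_xyz)):
            if el_j == "H":
                continue
            if float(np.linalg.norm(np.asarray(xi) - np.asarray(xj))) <= cutoff:
                pairs.add((i, j))
    return pairs


def oracle_plec(lig_graph, lig_xyz, prot_graph, prot_xyz,
                depth_ligand, depth_protein, cutoff, nbits) -> set[int]:
    lig_el = [a[0] for a in lig_graph.atoms]
    prot_el = [a[0] for a in prot_graph.atoms]
    bits = set()
    for li, pj in oracle_contacts(lig_el, lig_xyz, prot_el, prot_xyz, cutoff):
        for i in range(depth_ligand + 1):
            for j in range(depth_protein + 1):
                lid = recursive_env(lig_graph, li, i)
                pid = recursive_env(prot_graph, pj, j)
                bits.add(_hash_tuple("plec", i, j, lid, pid) % nbits)
    return bits


def _graph(smiles: str) -> MolecularGraph:
    return graph_from_rdkit(Chem.MolFromSmiles(smiles))


# ---------------------------------------------------------------------------


class TestHash:
    def test_fnv1a_reference_vectors(self):
        # published FNV-1a 32-bit test vectors
        assert fnv1a32(b"") == 0x811C9DC5
        assert fnv1a32(b"a") == 0xE40C292C
        assert fnv1a32(b"foobar") == 0xBF9CF968


class TestAtomEnvironments:
    def test_isolated_atom_identifiers_depend_only_on_tuple(self):
        g = MolecularGraph(atoms=(("C", 0, False, 0, 4, False),), bonds=())
        envs = atom_environments(g, 0, max_depth=2)
        assert [d for d, _ in envs] == [0, 1, 2]

    def test_matches_recursive_oracle_on_ethanol(self):
        g = _graph("CCO")
        for atom in range(len(g.atoms)):
            for depth, ident in atom_environments(g, atom, max_depth=2):
                assert ident == recursive_env(g, atom, depth)

    def test_relabeling_preserves_identifier_multiset(self):
        g = _graph("CC(=O)O")
        perm = [2, 0, 3, 1]
        relabeled = MolecularGraph(
            atoms=tuple(g.atoms[perm.index(k)] for k in range(len(perm))),
            bonds=tuple((perm[i], perm[j], o) for i, j, o in g.bonds),
        )
        for depth in range(3):
            orig = sorted(atom_environments(g, a, depth)[-1][1]
                          for a in range(len(g.atoms)))
            new = sorted(atom_environments(relabeled, a, depth)[-1][1]
                         for a in range(len(relabeled.atoms)))
            assert orig == new

    def test_invalid_index_raises(self):
        g = _graph("CC")
        with pytest.raises(ValueError):
            atom_environments(g, 5, 2)


class TestEcfp:
    @pytest.mark.parametrize("smiles", TOY_SMILES)
    def test_matches_enumeration_oracle(self, smiles):
        g = _graph(smiles)
        fp = ecfp(g, radius=2, nbits=2048)
        assert set(fp.set_bits) == oracle_ecfp(g, radius=2, nbits=2048)

    def test_popcount_bounded_by_environment_count(self):
        for smiles in TOY_SMILES:
            g = _graph(smiles)
            fp = ecfp(g, radius=2, nbits=2048)
            assert fp.popcount() <= len(g.atoms) * 3

    def test_atom_reordering_invariance(self):
        g = _graph("CC(=O)Nc1ccc(O)cc1")
        rng = np.random.Generator(np.random.Philox(2))
        perm = list(rng.permutation(len(g.atoms)))
        relabeled = MolecularGraph(
            atoms=tuple(g.atoms[perm.index(k)] for k in range(len(perm))),
            bonds=tuple((perm[i], perm[j], o) for i, j, o in g.bonds),
        )
        assert ecfp(g).set_bits == ecfp(relabeled).set_bits

    def test_methane_vs_ethane_differ(self):
        assert ecfp(_graph("C")).set_bits != ecfp(_graph("CC")).set_bits

    def test_disconnected_graph_is_or_of_fragments(self):
        a, b = _graph("CCO"), _graph("c1ccccc1")
        combined = MolecularGraph(
            atoms=a.atoms + b.atoms,
            bonds=a.bonds + tuple((i + len(a.atoms), j + len(a.atoms), o)
                                  for i, j, o in b.bonds),
        )
        assert ecfp(combined).set_bits == (ecfp(a) | ecfp(b)).set_bits

    def test_non_power_of_two_nbits_rejected(self):
        with pytest.raises(ValueError):
            ecfp(_graph("CC"), nbits=1000)

    def test_agrees_with_rdkit_on_invariance_not_bits(self):
        """Independent cross-check: RDKit Morgan and our ECFP must agree on
        *equality structure* across molecules (same molecule -> same FP,
        different -> different), though bit positions differ by design."""
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        ours = [ecfp(_graph(s)).set_bits for s in TOY_SMILES]
        theirs = [tuple(gen.GetFingerprint(Chem.MolFromSmiles(s)).GetOnBits())
                  for s in TOY_SMILES]
        for i in range(len(TOY_SMILES)):
            for j in range(i + 1, len(TOY_SMILES)):
                assert (ours[i] == ours[j]) == (theirs[i] == theirs[j])


class TestContacts:
    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.Generator(np.random.Philox(3))
        lig_el = [str(rng.choice(["C", "N", "H"])) for _ in range(20)]
        prot_el = [str(rng.choice(["C", "O", "H"])) for _ in range(50)]
        lig_xyz = rng.uniform(-8, 8, (20, 3))
        prot_xyz = rng.uniform(-8, 8, (50, 3))
        got = {(c.ligand_atom, c.protein_atom)
               for c in find_contacts(lig_el, lig_xyz, prot_el, prot_xyz, 4.5)}
        assert got == oracle_contacts(lig_el, lig_xyz, prot_el, prot_xyz, 4.5)

    def test_exact_cutoff_included(self):
        pairs = find_contacts(["C"], [(0, 0, 0)], ["C"], [(4.5, 0, 0)], cutoff=4.5)
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(4.5)

    def test_no_atoms_in_range(self):
        assert find_contacts(["C"], [(0, 0, 0)], ["C"], [(50, 0, 0)]) == []

    def test_hydrogens_excluded(self):
        assert find_contacts(["H"], [(0, 0, 0)], ["C"], [(1, 0, 0)]) == []


class TestPlec:
    def _toy_complex(self, seed=0, n_prot=12):
        rng = np.random.Generator(np.random.Philox(seed))
        lig = _graph("CCO")
        lig_xyz = rng.uniform(-2, 2, (len(lig.atoms), 3))
        prot_atoms = tuple(
            (str(rng.choice(["C", "N", "O"])), 0, False, 1, 0, False)
            for _ in range(n_prot)
        )
        prot = MolecularGraph(
            atoms=prot_atoms,
            bonds=tuple((i, i + 1, 1.0) for i in range(n_prot - 1)),
        )
        prot_xyz = rng.uniform(-4, 4, (n_prot, 3))
        return lig, lig_xyz, prot, prot_xyz

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        lig, lx, prot, px = self._toy_complex(seed)
        fp = plec(lig, lx, prot, px, nbits=65536)
        assert set(fp.set_bits) == oracle_plec(lig, lx, prot, px, 2, 4, 4.5, 65536)

    def test_no_contacts_all_zero(self):
        lig, lx, prot, px = self._toy_complex(1)
        fp = plec(lig, lx, prot, px + 1000.0)
        assert fp.popcount() == 0

    def test_rigid_motion_invariance(self):
        lig, lx, prot, px = self._toy_complex(4)
        rng = np.random.Generator(np.random.Philox(9))
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        t = rng.uniform(-30, 30, 3)
        fp1 = plec(lig, lx, prot, px)
        fp2 = plec(lig, lx @ q.T + t, prot, px @ q.T + t)
        assert fp1.set_bits == fp2.set_bits

    def test_single_contact_popcount_bounded_by_depth_product(self):
        lig = MolecularGraph(atoms=(("C", 0, False, 0, 4, False),), bonds=())
        prot = MolecularGraph(atoms=(("N", 0, False, 0, 0, False),), bonds=())
        fp = plec(lig, [(0, 0, 0)], prot, [(2.0, 0, 0)],
                  depth_ligand=2, depth_protein=4)
        assert 0 < fp.popcount() <= 15
        oracle = oracle_plec(lig, [(0.0, 0.0, 0.0)], prot, [(2.0, 0.0, 0.0)],
                             2, 4, 4.5, 65536)
        assert set(fp.set_bits) == oracle

    def test_adding_contact_only_grows_bits(self):
        lig, lx, prot, px = self._toy_complex(6)
        base = set(plec(lig, lx, prot, px).set_bits)
        # append one more protein atom in contact range
        prot2 = MolecularGraph(
            atoms=prot.atoms + (("S", 0, False, 0, 0, False),),
            bonds=prot.bonds,
        )
        px2 = np.vstack([px, lx[0] + 0.5])
        grown = set(plec(lig, lx, prot2, px2).set_bits)
        # bits from untouched atoms' environments persist only when the graph
        # is unchanged for them; the appended atom is isolated, so they do
        assert base <= grown

    def test_determinism_across_runs(self):
        lig, lx, prot, px = self._toy_complex(8)
        assert plec(lig, lx, prot, px).set_bits == plec(lig, lx, prot, px).set_bits


class TestGraphAdapters:
    def test_pose_adapter_folds_hydrogens(self):
        from kinodock.complexes import AtomSite, LigandPose

        pose = LigandPose(
            pose_id="p", isomer_id="i", structure_id="s", engine="mock",
            rank=1, engine_score=0.0,
            atoms=[AtomSite("C", (0, 0, 0)), AtomSite("H", (1, 0, 0)),
                   AtomSite("O", (0, 1.4, 0))],
            bonds=[(0, 1, 1.0), (0, 2, 1.0)],
        )
        g, xyz = graph_from_pose(pose)
        assert len(g.atoms) == 2  # heavy atoms only
        assert g.atoms[0][4] == 1  # one attached H on the carbon
        assert xyz.shape == (2, 3)

    def test_protein_adapter_infers_bonds_by_distance(self):
        from kinodock.synthetic import toy_pdb_text
        from kinodock.complexes import read_protein_pdb

        protein = read_protein_pdb(toy_pdb_text(seed=2, n_atoms=20))
        g, xyz = graph_from_protein(protein)
        assert len(g.atoms) == 20
        assert xyz.shape == (20, 3)
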