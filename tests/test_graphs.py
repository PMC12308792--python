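"""Molecular graph parsing, featurization, and k-hop retrieval."""

import numpy as np
import pytest
from rdkit import Chem

import molorb as mo
from molorb.graphs import (
    ATOM_DIM,
    BOND_DIM,
    ELEMENTS,
    MAX_DEGREE,
    SmilesParseError,
)


@pytest.mark.parametrize(
    "smiles,n_atoms,n_bonds",
    [
        ("CC(=O)O", 4, 3),   # acetic acid, heavy atoms only
        ("C", 1, 0),
        ("C1CC1", 3, 3),     # cyclopropane
        ("c1ccccc1", 6, 6),  # benzene
    ],
)
def test_parse_counts(smiles, n_atoms, n_bonds):
    g = mo.parse_smiles(smiles)
    assert g.n_atoms == n_atoms
    assert g.n_bonds == n_bonds
    assert g.atoms.shape == (n_atoms, ATOM_DIM)
    assert g.bond_features.shape == (n_bonds, BOND_DIM)


@pytest.mark.parametrize("bad", ["", "   ", "not-a-smiles", "C1CC"])
def test_parse_errors_name_input(bad):
    with pytest.raises(SmilesParseError):
        mo.parse_smiles(bad)


def test_ring_bonds_flagged():
    g = mo.parse_smiles("C1CC1")
    # ring-membership is the last bond feature slot
    assert np.all(g.bond_features[:, 5] == 1.0)
    chain = mo.parse_smiles("CCC")
    assert np.all(chain.bond_features[:, 5] == 0.0)


def test_neighbor_symmetry_and_bond_validity(random_graphs):
    for g in random_graphs:
        for a, nbrs in enumerate(g.neighbors):
            for b, bond_idx in nbrs:
                assert (a, b) in [g.bonds[bond_idx], g.bonds[bond_idx][::-1]]
                assert any(x == a for x, _ in g.neighbors[b])
        for i, j in g.bonds:
            assert i != j
            assert 0 <= i < g.n_atoms and 0 <= j < g.n_atoms


def test_one_hot_blocks_sum_to_at_most_one(random_graphs):
    n_el = len(ELEMENTS) + 1
    for g in random_graphs:
        el = g.atoms[:, :n_el]
        deg = g.atoms[:, n_el:n_el + MAX_DEGREE + 1]
        assert np.all(el.sum(axis=1) <= 1)
        assert np.all(deg.sum(axis=1) <= 1)


def test_featurization_deterministic():
    a = mo.parse_smiles("CC(=O)OC1=CC=CC=C1C(=O)O")  # aspirin
    b = mo.parse_smiles("CC(=O)OC1=CC=CC=C1C(=O)O")
    assert np.array_equal(a.atoms, b.atoms)
    assert np.array_equal(a.bond_features, b.bond_features)
    assert a.smiles == b.smiles


def _bfs_oracle(g, center, k):
    """Independent breadth-first distances over the adjacency lists."""
    dist = {center: 0}
    frontier = [center]
    for depth in range(1, k + 1):
        nxt = []
        for a in frontier:
            for nbr, _ in g.neighbors[a]:
                if nbr not in dist:
                    dist[nbr] = depth
                    nxt.append(nbr)
        frontier = nxt
    return set(dist)


def test_khop_matches_bfs_oracle():
    """Neighborhood retrieval equals an independent BFS on 200 graphs."""
    ds = mo.generate_synthetic_dataset(200, seed=77)
    graphs = [mo.parse_smiles(s) for s in ds.df["smiles"] if
              mo.parse_smiles(s).n_atoms <= 30]
    for g in graphs:
        for center in range(g.n_atoms):
            for k in range(5):
                sub = mo.khop_neighborhood(g, center, k)
                assert set(sub.atom_indices) == _bfs_oracle(g, center, k)
                for b in sub.bond_indices:
                    i, j = g.bonds[b]
                    assert i in sub.atom_indices and j in sub.atom_indices


def test_khop_monotone_growth(random_graphs):
    for g in random_graphs[:5]:
        for center in range(g.n_atoms):
            prev = mo.khop_neighborhood(g, center, 0)
            assert set(prev.atom_indices) == {center}
            assert not prev.bond_indices
            for k in range(1, 5):
                cur = mo.khop_neighborhood(g, center, k)
                assert prev.atom_indices <= cur.atom_indices
                assert prev.bond_indices <= cur.bond_indices
                prev = cur


def test_khop_range_errors():
    g = mo.parse_smiles("CCO")
    with pytest.raises(ValueError):
        mo.khop_neighborhood(g, 0, 5)
    with pytest.raises(IndexError):
        mo.khop_neighborhood(g, 9, 1)


def test_acetic_acid_carbonyl_one_hop():
    """1-hop around the carbonyl carbon covers the whole heavy-atom skeleton."""
    g = mo.parse_smiles("CC(=O)O")
    carbonyl = max(range(g.n_atoms), key=g.degree)  # the degree-3 carbon
    sub = mo.khop_neighborhood(g, carbonyl, 1)
    assert len(sub.atom_indices) == 4
    assert len(sub.bond_indices) == 3


class TestFragments:
    def test_single_atom(self):
        g = mo.parse_smiles("C")
        sub = mo.khop_neighborhood(g, 0, 0)
        assert mo.substructure_to_fragment(g, sub) == "C"

    def test_carbonyl_fragment_reparses(self):
        g = mo.parse_smiles("CC(=O)O")
        carbonyl = max(range(g.n_atoms), key=g.degree)
        frag = mo.substructure_to_fragment(
            g, mo.khop_neighborhood(g, carbonyl, 1)
        )
        # fragment covers the full heavy-atom skeleton here: 4 atoms, 3 bonds,
        # one C=O among them
        m = Chem.MolFromSmiles(frag)
        assert m is not None and m.GetNumAtoms() == 4 and m.GetNumBonds() == 3
        assert any(b.GetBondType() == Chem.BondType.DOUBLE for b in m.GetBonds())

    def test_full_molecule_roundtrip_isomorphic(self, random_graphs):
        for g in random_graphs[:8]:
            sub = mo.Substructure(
                frozenset(range(g.n_atoms)), frozenset(range(g.n_bonds)), 0, 4
            )
            frag = mo.substructure_to_fragment(g, sub)
            m = Chem.MolFromSmiles(frag)
            assert m is not None
            orig = Chem.MolFromSmiles(g.smiles)
            assert m.GetNumAtoms() == orig.GetNumAtoms()
            assert m.GetNumBonds() == orig.GetNumBonds()
            assert orig.HasSubstructMatch(m) and m.HasSubstructMatch(orig)
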