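"""SMILES parsing and featurized molecular graphs.

A :class:`MoleculeGraph` is the substrate of every graph convolution in the
package: heavy atoms only (hydrogens are folded into atom features), with a
fixed-length feature vector per atom and per bond, plus symmetric adjacency
lists.  Feature vectors follow the standard neural-fingerprint convention:

* atom — element one-hot over ``{C, N, O, S, F, Cl, Br, I, P, other}``,
  heavy-atom degree one-hot 0..5, formal charge (clipped to [-2, +2]),
  aromaticity flag, attached-hydrogen count one-hot 0..4;
* bond — bond-order one-hot ``{single, double, triple, aromatic}``,
  conjugation flag, ring-membership flag.

Degrees above 5 are rejected at parse time because the convolutions use
degree-indexed weight matrices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
MAX_DEGREE = 5
MAX_H_COUNT = 4

#: length of an atom feature vector: 10 element slots (9 named + other),
#: 6 degree slots, 1 formal charge, 1 aromatic flag, 5 H-count slots
ATOM_DIM = len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + 1 + 1 + (MAX_H_COUNT + 1)
#: length of a bond feature vector: 4 order slots + conjugation + ring
BOND_DIM = 6


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or featurized."""


@dataclass
class MoleculeGraph:
    """Featurized heavy-atom molecular graph.

    Attributes
    ----------
    id : str
        Free-text label.
    smiles : str
        Canonical SMILES as produced by RDKit.
    atoms : ndarray, shape (n_atoms, ATOM_DIM)
    bonds : list of (int, int)
        Endpoint atom indices of each bond.
    bond_features : ndarray, shape (n_bonds, BOND_DIM)
    neighbors : list of list of (int, int)
        For each atom, ``(neighbor_atom_index, bond_index)`` pairs.
    """

    id: str
    smiles: str
    atoms: np.ndarray
    bonds: list[tuple[int, int]]
    bond_features: np.ndarray
    neighbors: list[list[tuple[int, int]]]
    mol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, atom_index: int) -> int:
        return len(self.neighbors[atom_index])


@dataclass(frozen=True)
class Substructure:
    """A connected induced subgraph centered on an atom.

    ``radius`` is the hop count used to build it; every bond's endpoints lie
    inside ``atom_indices`` and ``center_atom`` is always a member.
    """

    atom_indices: frozenset[int]
    bond_indices: frozenset[int]
    center_atom: int
    radius: int


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    if 0 <= value < size:
        v[value] = 1.0
    return v


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    symbol = atom.GetSymbol()
    try:
        elem_idx = ELEMENTS.index(symbol)
    except ValueError:
        elem_idx = len(ELEMENTS)  # "other" slot
    parts = [
        _one_hot(elem_idx, len(ELEMENTS) + 1),
        _one_hot(atom.GetDegree(), MAX_DEGREE + 1),
        np.array([float(np.clip(atom.GetFormalCharge(), -2, 2))]),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
        _one_hot(min(atom.GetTotalNumHs(), MAX_H_COUNT), MAX_H_COUNT + 1),
    ]
    return np.concatenate(parts)


_BOND_ORDER_SLOT = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    v = np.zeros(BOND_DIM)
    slot = _BOND_ORDER_SLOT.get(bond.GetBondType())
    if slot is not None:
        v[slot] = 1.0
    v[4] = 1.0 if bond.GetIsConjugated() else 0.0
    v[5] = 1.0 if bond.IsInRing() else 0.0
    return v


def parse_smiles(text: str, id: str | None = None) -> MoleculeGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Hydrogens are implicit: they appear only as the attached-H-count atom
    feature.  Raises :class:`SmilesParseError` for unparseable SMILES or for
    molecules with a heavy-atom degree above 5.
    """
    if not text or not text.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {text!r}")
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES parses to an empty molecule: {text!r}")
    for atom in mol.GetAtoms():
        if atom.GetDegree() > MAX_DEGREE:
            raise SmilesParseError(
                f"atom {atom.GetIdx()} in {text!r} has degree "
                f"{atom.GetDegree()} > supported maximum {MAX_DEGREE}"
            )
    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()])
    bonds: list[tuple[int, int]] = []
    bond_feats = []
    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        b_idx = len(bonds)
        bonds.append((i, j))
        bond_feats.append(_bond_features(bond))
        neighbors[i].append((j, b_idx))
        neighbors[j].append((i, b_idx))
    bond_features = (
        np.array(bond_feats) if bond_feats else np.zeros((0, BOND_DIM))
    )
    return MoleculeGraph(
        id=id if id is not None else text,
        smiles=Chem.MolToSmiles(mol),
        atoms=atoms,
        bonds=bonds,
        bond_features=bond_features,
        neighbors=neighbors,
        mol=mol,
    )


def khop_neighborhood(
    graph: MoleculeGraph, center: int, k: int, max_radius: int = 4
) -> Substructure:
    """Atoms within graph distance ``k`` of ``center`` plus all internal bonds.

    ``k`` must lie in ``[0, max_radius]``; the default cap of 4 hops matches
    the largest substructure radius the attribution analysis reports.
    """
    if not 0 <= center < graph.n_atoms:
        raise IndexError(f"center atom {center} out of range")
    if k < 0 or k > max_radius:
        raise ValueError(f"k={k} outside supported range [0, {max_radius}]")
    dist = {center: 0}
    queue = deque([center])
    while queue:
        a = queue.popleft()
        if dist[a] == k:
            continue
        for nbr, _ in graph.neighbors[a]:
            if nbr not in dist:
                dist[nbr] = dist[a] + 1
                queue.append(nbr)
    atom_set = frozenset(dist)
    bond_set = frozenset(
        b for b, (i, j) in enumerate(graph.bonds)
        if i in atom_set and j in atom_set
    )
    return Substructure(atom_set, bond_set, center, k)


def substructure_to_fragment(graph: MoleculeGraph, sub: Substructure) -> str:
    """Render a substructure as a SMILES fragment of the induced subgraph."""
    if not sub.atom_indices <= set(range(graph.n_atoms)):
        raise ValueError("substructure references atoms outside the graph")
    mol = graph.mol if graph.mol is not None else Chem.MolFromSmiles(graph.smiles)
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(sub.atom_indices),
        bondsToUse=sorted(sub.bond_indices) or None,
        canonical=True,
    )
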