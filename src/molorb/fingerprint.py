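"""Differentiable substructure-based neural fingerprints.

A fingerprint of length ``F`` is accumulated over ``n_layers + 1`` write
steps.  At step 0 every atom writes ``softmax(atom_features @ O_0)`` into the
fingerprint; after each graph-convolution layer ``l`` every atom writes
``softmax(state_l @ O_l)``.  A convolution layer updates each atom's state
from its own state plus the sum over neighbors of the neighbor state
concatenated with the incident bond features, passed through a weight matrix
indexed by the atom's degree, then a ``tanh`` nonlinearity.  Sum-pooling over
neighbors and degree-indexed weights make the fingerprint invariant to atom
relabeling, and because every write is a softmax the fingerprint entries sum
exactly to ``n_atoms * (n_layers + 1)``.

The per-atom, per-step write vectors are retained as an
:class:`ActivationTrace`; summing the trace reproduces the fingerprint
exactly, which is what makes maximal-activation substructure attribution
possible.

Everything here is plain NumPy with hand-derived gradients; the batched
forward/backward pair (:func:`forward_batch` / :func:`backward_batch`) is
what the trainer uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import ATOM_DIM, BOND_DIM, MAX_DEGREE, MoleculeGraph

SUPPORTED_N_LAYERS = (1, 2, 3, 4)
SUPPORTED_FP_LENGTHS = (8, 16, 32, 64, 128)


@dataclass(frozen=True)
class FingerprintConfig:
    """Architecture of the fingerprint network.

    ``n_layers`` graph-convolution layers (writes happen at steps
    ``0..n_layers`` inclusive), fingerprint length ``fp_length``, and hidden
    atom-state width ``hidden_width``.
    """

    n_layers: int = 3
    fp_length: int = 32
    hidden_width: int = 32
    atom_dim: int = ATOM_DIM
    bond_dim: int = BOND_DIM
    max_degree: int = MAX_DEGREE

    def validate(self) -> None:
        if self.n_layers not in SUPPORTED_N_LAYERS:
            raise ValueError(
                f"n_layers={self.n_layers} not in {SUPPORTED_N_LAYERS}"
            )
        if self.fp_length not in SUPPORTED_FP_LENGTHS:
            raise ValueError(
                f"fp_length={self.fp_length} not in {SUPPORTED_FP_LENGTHS}"
            )
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be positive")

    def state_dim(self, step: int) -> int:
        """Dimension of the atom state at write step ``step``."""
        return self.atom_dim if step == 0 else self.hidden_width


@dataclass
class FingerprintParams:
    """Weights of the fingerprint network.

    ``weights`` maps string keys to arrays:

    * ``conv:{l}:{d}`` — convolution matrix for layer ``l`` (1-based) and
      atom degree ``d`` in ``0..max_degree``, shape
      ``(state_dim(l-1) + bond_dim, hidden_width)``;
    * ``convb:{l}`` — per-layer bias, shape ``(hidden_width,)``;
    * ``out:{s}`` — write matrix at step ``s`` in ``0..n_layers``, shape
      ``(state_dim(s), fp_length)``;
    * ``outb:{s}`` — write bias, shape ``(fp_length,)``.
    """

    config: FingerprintConfig
    weights: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Fingerprint:
    """A fingerprint vector with non-negative entries."""

    values: np.ndarray


@dataclass
class ActivationTrace:
    """Per-step, per-atom write contributions.

    ``writes[s]`` has shape ``(n_atoms, fp_length)``; row ``a`` is the
    softmax vector atom ``a`` wrote at step ``s`` (each row sums to 1).
    """

    writes: list[np.ndarray]

    def total(self) -> np.ndarray:
        return sum(w.sum(axis=0) for w in self.writes)


def init_fingerprint_params(
    config: FingerprintConfig, seed: int
) -> FingerprintParams:
    """Reproducible small random initialization (scaled by 1/sqrt(fan-in))."""
    config.validate()
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {}
    for layer in range(1, config.n_layers + 1):
        in_dim = config.state_dim(layer - 1) + config.bond_dim
        for deg in range(config.max_degree + 1):
            w[f"conv:{layer}:{deg}"] = rng.normal(
                0.0, 1.0 / np.sqrt(in_dim), (in_dim, config.hidden_width)
            )
        w[f"convb:{layer}"] = np.zeros(config.hidden_width)
    for step in range(config.n_layers + 1):
        in_dim = config.state_dim(step)
        w[f"out:{step}"] = rng.normal(
            0.0, 1.0 / np.sqrt(in_dim), (in_dim, config.fp_length)
        )
        w[f"outb:{step}"] = np.zeros(config.fp_length)
    return FingerprintParams(config=config, weights=w)


# ---------------------------------------------------------------------------
# Batched forward / backward over a pack of graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphPack:
    """A batch of graphs flattened into index arrays for vectorized ops."""

    graphs: list[MoleculeGraph]
    atom_features: np.ndarray          # (N, atom_dim)
    bond_features: np.ndarray          # (M, bond_dim)
    mol_index: np.ndarray              # (N,) owning-molecule index per atom
    atom_offsets: np.ndarray           # (G+1,) atom-range per molecule
    # per degree d: (atom_idx (n_d,), nbr_atoms (n_d, d), nbr_bonds (n_d, d))
    degree_groups: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)


def pack_graphs(graphs: list[MoleculeGraph]) -> GraphPack:
    if not graphs:
        raise ValueError("empty graph batch")
    atom_feats = np.concatenate([g.atoms for g in graphs])
    bond_feats = np.concatenate([g.bond_features for g in graphs])
    offsets = np.zeros(len(graphs) + 1, dtype=np.int64)
    np.cumsum([g.n_atoms for g in graphs], out=offsets[1:])
    mol_index = np.repeat(np.arange(len(graphs)), [g.n_atoms for g in graphs])
    by_degree: dict[int, list[tuple[int, list[int], list[int]]]] = {}
    bond_offset = 0
    for gi, g in enumerate(graphs):
        a0 = offsets[gi]
        for a, nbrs in enumerate(g.neighbors):
            d = len(nbrs)
            if d == 0:
                continue
            by_degree.setdefault(d, []).append((
                a0 + a,
                [a0 + n for n, _ in nbrs],
                [bond_offset + b for _, b in nbrs],
            ))
        bond_offset += g.n_bonds
    groups = {}
    for d, rows in by_degree.items():
        idx = np.array([r[0] for r in rows], dtype=np.int64)
        nbr_a = np.array([r[1] for r in rows], dtype=np.int64)
        nbr_b = np.array([r[2] for r in rows], dtype=np.int64)
        groups[d] = (idx, nbr_a, nbr_b)
    return GraphPack(
        graphs=graphs,
        atom_features=atom_feats,
        bond_features=bond_feats,
        mol_index=mol_index,
        atom_offsets=offsets,
        degree_groups=groups,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ForwardCache:
    """Intermediates retained for the backward pass."""

    states: list[np.ndarray]        # per step s: (N, state_dim(s))
    pooled: list[np.ndarray]        # per layer: self+neighbor input (N, dim+bond)
    writes: list[np.ndarray]        # per step: softmax rows (N, F)


def forward_batch(
    pack: GraphPack, params: FingerprintParams
) -> tuple[np.ndarray, ForwardCache]:
    """Compute fingerprints for all graphs in a pack.

    Returns ``(fingerprints, cache)`` with fingerprints of shape
    ``(n_graphs, fp_length)``.
    """
    cfg = params.config
    if pack.atom_features.shape[1] != cfg.atom_dim:
        raise ValueError(
            f"atom feature dim {pack.atom_features.shape[1]} does not match "
            f"config atom_dim {cfg.atom_dim}"
        )
    w = params.weights
    H = pack.atom_features
    states = [H]
    pooled_list = []
    writes = []
    fp = np.zeros((pack.n_graphs, cfg.fp_length))

    def write(step: int, state: np.ndarray) -> None:
        logits = state @ w[f"out:{step}"] + w[f"outb:{step}"]
        soft = _softmax(logits)
        writes.append(soft)
        np.add.at(fp, pack.mol_index, soft)

    write(0, H)
    for layer in range(1, cfg.n_layers + 1):
        dim = H.shape[1]
        total = np.concatenate(
            [H, np.zeros((pack.n_atoms, cfg.bond_dim))], axis=1
        )
        for d, (idx, nbr_a, nbr_b) in pack.degree_groups.items():
            nbr_states = H[nbr_a]                      # (n_d, d, dim)
            nbr_bonds = pack.bond_features[nbr_b]      # (n_d, d, bond_dim)
            pooled = np.concatenate([nbr_states, nbr_bonds], axis=2).sum(axis=1)
            total[idx] += pooled
        z = np.empty((pack.n_atoms, cfg.hidden_width))
        z[:] = w[f"convb:{layer}"]
        deg0_mask = np.ones(pack.n_atoms, dtype=bool)
        for d, (idx, _, _) in pack.degree_groups.items():
            z[idx] += total[idx] @ w[f"conv:{layer}:{d}"]
            deg0_mask[idx] = False
        if deg0_mask.any():
            z[deg0_mask] += total[deg0_mask] @ w[f"conv:{layer}:0"]
        H = np.tanh(z)
        states.append(H)
        pooled_list.append(total)
        write(layer, H)
    return fp, ForwardCache(states=states, pooled=pooled_list, writes=writes)


def backward_batch(
    pack: GraphPack,
    params: FingerprintParams,
    cache: ForwardCache,
    d_fp: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. fingerprint weights.

    ``d_fp`` is the loss gradient w.r.t. the fingerprints,
    shape ``(n_graphs, fp_length)``.
    """
    cfg = params.config
    w = params.weights
    grads = {k: np.zeros_like(v) for k, v in w.items()}
    # accumulated gradient w.r.t. each step's atom state
    d_states = [np.zeros_like(s) for s in cache.states]

    for step in range(cfg.n_layers + 1):
        soft = cache.writes[step]
        d_soft = d_fp[pack.mol_index]                  # (N, F)
        inner = (d_soft * soft).sum(axis=1, keepdims=True)
        d_logits = soft * (d_soft - inner)
        grads[f"out:{step}"] += cache.states[step].T @ d_logits
        grads[f"outb:{step}"] += d_logits.sum(axis=0)
        d_states[step] += d_logits @ w[f"out:{step}"].T

    for layer in range(cfg.n_layers, 0, -1):
        H = cache.states[layer]
        d_z = d_states[layer] * (1.0 - H * H)
        total = cache.pooled[layer - 1]
        dim = cache.states[layer - 1].shape[1]
        d_total = np.zeros_like(total)
        grads[f"convb:{layer}"] += d_z.sum(axis=0)
        deg0_mask = np.ones(pack.n_atoms, dtype=bool)
        for d, (idx, _, _) in pack.degree_groups.items():
            grads[f"conv:{layer}:{d}"] += total[idx].T @ d_z[idx]
            d_total[idx] = d_z[idx] @ w[f"conv:{layer}:{d}"].T
            deg0_mask[idx] = False
        if deg0_mask.any():
            grads[f"conv:{layer}:0"] += total[deg0_mask].T @ d_z[deg0_mask]
            d_total[deg0_mask] = d_z[deg0_mask] @ w[f"conv:{layer}:0"].T
        # self contribution
        d_states[layer - 1] += d_total[:, :dim]
        # neighbor-pooling contribution
        for d, (idx, nbr_a, _) in pack.degree_groups.items():
            d_pooled = d_total[idx][:, None, :dim]     # (n_d, 1, dim)
            np.add.at(
                d_states[layer - 1],
                nbr_a,
                np.broadcast_to(d_pooled, (len(idx), d, dim)),
            )
    return grads


def compute_fingerprint(
    graph: MoleculeGraph, params: FingerprintParams
) -> tuple[Fingerprint, ActivationTrace]:
    """Fingerprint and full activation trace for a single molecule.

    The fingerprint is accumulated from the trace in a fixed order, so
    ``trace.total()`` reproduces ``fingerprint.values`` bit-exactly.
    """
    pack = pack_graphs([graph])
    _, cache = forward_batch(pack, params)
    trace = ActivationTrace(writes=cache.writes)
    return Fingerprint(values=trace.total()), trace
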