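"""Maximal-activation substructure attribution.

Each fingerprint index accumulates softmax write contributions from every
atom at every degree step across a set of molecules.  The substructure a
given index has learned is read off by finding the single largest write at
that index — the *maximal activation* — and retrieving the k-hop
neighborhood of the writing atom, where k is the degree step at which the
write occurred (substructure radii run from 1 to a maximum of 4).

Step-0 writes come from raw atom features before any pooling; they describe
a lone atom rather than a substructure.  By default they are excluded from
the report; ``include_atom_only=True`` makes them eligible, reported at
radius 0 with ``atom_only=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import FingerprintParams, compute_fingerprint
from .graphs import (
    MoleculeGraph,
    Substructure,
    khop_neighborhood,
    substructure_to_fragment,
)

MAX_RADIUS = 4


@dataclass
class ActivationRecord:
    """Provenance of one fingerprint index's maximal activation."""

    fp_index: int
    molecule_id: str
    molecule_pos: int
    atom_index: int
    k: int
    radius: int
    activation: float
    substructure: Substructure
    fragment: str
    atom_only: bool = False


def extract_maximal_activations(
    model,
    molecules: list[MoleculeGraph],
    include_atom_only: bool = False,
    max_radius: int = MAX_RADIUS,
) -> list[ActivationRecord]:
    """One :class:`ActivationRecord` per fingerprint index.

    ``model`` is a :class:`~molorb.fingerprint.FingerprintParams` or any
    object exposing one as ``.fp_params`` (e.g. a trained model).  Ties are
    broken by first occurrence in (molecule order, step order, atom order).
    """
    params: FingerprintParams = getattr(model, "fp_params", model)
    if not molecules:
        raise ValueError("empty molecule set")
    F = params.config.fp_length
    best: list[ActivationRecord | None] = [None] * F
    first_step = 0 if include_atom_only else 1
    for pos, graph in enumerate(molecules):
        _, trace = compute_fingerprint(graph, params)
        # (n_atoms, n_steps, F) with C-order flattening over (atom, step) so
        # argmax tie-breaks by atom order first, then step order
        stack = np.stack(trace.writes[first_step:], axis=1)
        n_steps = stack.shape[1]
        flat = stack.reshape(-1, F)
        arg = flat.argmax(axis=0)
        for i in range(F):
            a = int(arg[i] // n_steps)
            step = first_step + int(arg[i] % n_steps)
            val = float(flat[arg[i], i])
            if best[i] is None or val > best[i].activation:
                radius = min(max(step, 1), max_radius) if step > 0 else 0
                sub = khop_neighborhood(
                    graph, a, min(step, max_radius), max_radius=max_radius
                )
                best[i] = ActivationRecord(
                    fp_index=i,
                    molecule_id=graph.id,
                    molecule_pos=pos,
                    atom_index=a,
                    k=step,
                    radius=radius,
                    activation=val,
                    substructure=sub,
                    fragment=substructure_to_fragment(graph, sub),
                    atom_only=step == 0,
                )
    return [r for r in best if r is not None]


def records_to_table(records: list[ActivationRecord]) -> str:
    """Delimited-text report (tab-separated, one record per line)."""
    lines = ["fp_index\tmolecule\tfragment\tradius\tactivation"]
    for r in records:
        lines.append(
            f"{r.fp_index}\t{r.molecule_id}\t{r.fragment}\t{r.radius}"
            f"\t{r.activation:.6g}"
        )
    return "\n".join(lines)
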