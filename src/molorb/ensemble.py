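"""Ensembling independently trained GCN-ANN models.

Ten (by default) models with hyperparameters sampled without replacement
from the grid are trained separately; their scalar outputs are then combined
by a minimally trained linear layer (identity output activation), fitted on
the validation set with the member weights frozen.  The combiner starts at
uniform averaging (weights 1/K, bias 0).  Because it is linear in its
parameters, each training epoch applies an exact Gauss-Newton least-squares
step, so the combiner reaches the normal-equation optimum after the first of
its 3-5 epochs; the remaining epochs are fixed points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fingerprint import pack_graphs
from .regressor import (
    ANN_LAYER_GRID,
    BATCH_SIZE_GRID,
    FP_LENGTH_GRID,
    GCN_LAYER_GRID,
    L2_GRID,
    LEARNING_RATE_GRID,
    Hyperparameters,
    TrainedModel,
    _as_graphs_and_targets,
    _coerce_graphs,
    model_forward,
)
from .metrics import EvalReport, evaluate


def full_hyperparameter_grid() -> list[Hyperparameters]:
    """Every combination of the grid values (exhaustive enumeration)."""
    grid = []
    combos = itertools.product(
        GCN_LAYER_GRID, ANN_LAYER_GRID, BATCH_SIZE_GRID,
        LEARNING_RATE_GRID, L2_GRID, FP_LENGTH_GRID,
    )
    for gcn, ann, bs, lr, l2, fp in combos:
        grid.append(Hyperparameters(
            gcn_layers=gcn, ann_layers=ann, batch_size=bs,
            learning_rate=lr, l2=l2, fp_length=fp,
        ))
    return grid


def sample_model_grid(n: int = 10, seed: int = 0) -> list[Hyperparameters]:
    """``n`` distinct hyperparameter settings drawn without replacement."""
    grid = full_hyperparameter_grid()
    if n > len(grid):
        raise ValueError(f"n={n} exceeds grid size {len(grid)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=n, replace=False)
    return [grid[i] for i in idx]


@dataclass
class Ensemble:
    """Frozen member models plus a fitted linear combiner."""

    members: list[TrainedModel]
    combiner_weights: np.ndarray  # (K,)
    combiner_bias: float
    combiner_epochs: int
    target: str = field(default="")

    def member_predictions(self, molecules) -> np.ndarray:
        """(n_molecules, K) matrix of member outputs in eV."""
        graphs = _coerce_graphs(molecules)
        pack = pack_graphs(graphs)
        return np.column_stack(
            [model_forward(pack, m) for m in self.members]
        )

    def predict(self, molecules) -> np.ndarray:
        """Linear combination of member predictions (identity activation)."""
        return (
            self.member_predictions(molecules) @ self.combiner_weights
            + self.combiner_bias
        )

    def evaluate(self, data, target: str | None = None) -> EvalReport:
        graphs, y_true = _as_graphs_and_targets(data, target or self.target)
        pack = pack_graphs(graphs)
        preds = np.column_stack([model_forward(pack, m) for m in self.members])
        y_hat = preds @ self.combiner_weights + self.combiner_bias
        return evaluate(y_hat, y_true)


def fit_combiner(
    members: list[TrainedModel], val_set, epochs: int = 3
) -> Ensemble:
    """Fit the linear combiner on a validation set, members frozen.

    ``epochs`` full-batch Gauss-Newton steps from the uniform-averaging
    start; for this linear least-squares problem one step already reaches
    the optimum.
    """
    if not members:
        raise ValueError("need at least one member model")
    if not 1 <= epochs <= 5:
        raise ValueError("combiner is minimally trained: epochs in [1, 5]")
    targets = {m.target for m in members}
    if len(targets) != 1:
        raise ValueError(f"members have mixed targets: {sorted(targets)}")
    target = members[0].target
    graphs, y_true = _as_graphs_and_targets(val_set, target)
    pack = pack_graphs(graphs)
    preds = np.column_stack([model_forward(pack, m) for m in members])
    k = len(members)
    w = np.full(k, 1.0 / k)
    b = 0.0
    X = np.column_stack([preds, np.ones(len(y_true))])
    for _ in range(epochs):
        theta = np.concatenate([w, [b]])
        resid = X @ theta - y_true
        # Gauss-Newton step == exact normal-equation solve for a linear model
        step, *_ = np.linalg.lstsq(X, resid, rcond=None)
        theta = theta - step
        w, b = theta[:k], float(theta[k])
    return Ensemble(
        members=members,
        combiner_weights=w,
        combiner_bias=b,
        combiner_epochs=epochs,
        target=target,
    )


class EnsembleRegression:
    """Model-object facade over :func:`fit_combiner`.

    Build from trained members and a validation set; ``fit()`` returns the
    :class:`Ensemble` (which plays the results role: it predicts and
    evaluates).
    """

    def __init__(self, members: list[TrainedModel], val_data):
        self.members = members
        self.val_data = val_data

    def fit(self, epochs: int = 3) -> Ensemble:
        return fit_combiner(self.members, self.val_data, epochs=epochs)
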