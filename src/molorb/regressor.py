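"""GCN-ANN regression of orbital energies.

The model maps a molecule's neural fingerprint through a small feed-forward
network (ReLU hidden layers, linear scalar output) to a HOMO or LUMO energy
in eV.  Training minimizes mean squared error plus an L2 penalty on the
weight matrices by minibatch adaptive-moment (Adam) gradient descent, on
targets standardized to zero mean and unit variance over the training split.
Early stopping triggers once the last 20 validation losses all lie within a
band of 0.01 (in standardized loss units); otherwise training runs to
``max_epochs`` (default 200).

The public surface follows the statsmodels convention: build a
:class:`NeuralFingerprintRegression` from data, call :meth:`fit`, and work
with the returned :class:`NeuralFingerprintResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fingerprint as fpm
from .fingerprint import (
    FingerprintConfig,
    FingerprintParams,
    GraphPack,
    pack_graphs,
)
from .graphs import MoleculeGraph, parse_smiles
from .metrics import EvalReport, evaluate

TARGETS = ("homo", "lumo", "surrogate")

GCN_LAYER_GRID = (3, 4)
ANN_LAYER_GRID = (2, 3, 4)
BATCH_SIZE_GRID = (128, 256)
LEARNING_RATE_GRID = (0.001, 0.0003, 0.0001)
L2_GRID = (0.0, 0.0001)
FP_LENGTH_GRID = (32, 64, 128)


@dataclass(frozen=True)
class Hyperparameters:
    """One cell of the hyperparameter grid.

    The grid values are ``gcn_layers`` in {3, 4}, ``ann_layers`` (number of
    hidden ReLU layers) in {2, 3, 4}, ``batch_size`` in {128, 256},
    ``learning_rate`` in {0.001, 0.0003, 0.0001}, ``l2`` in {0, 0.0001} and
    ``fp_length`` in {32, 64, 128}.  ``hidden_width`` (GCN atom state) and
    ``ann_width`` are architectural constants outside the grid.
    """

    gcn_layers: int = 3
    ann_layers: int = 2
    batch_size: int = 128
    learning_rate: float = 0.001
    l2: float = 0.0
    fp_length: int = 32
    hidden_width: int = 32
    ann_width: int = 64
    max_epochs: int = 200
    seed: int = 0

    def validate(self, strict_grid: bool = False) -> None:
        if strict_grid:
            checks = [
                (self.gcn_layers, GCN_LAYER_GRID, "gcn_layers"),
                (self.ann_layers, ANN_LAYER_GRID, "ann_layers"),
                (self.batch_size, BATCH_SIZE_GRID, "batch_size"),
                (self.learning_rate, LEARNING_RATE_GRID, "learning_rate"),
                (self.l2, L2_GRID, "l2"),
                (self.fp_length, FP_LENGTH_GRID, "fp_length"),
            ]
            for value, grid, name in checks:
                if value not in grid:
                    raise ValueError(f"{name}={value} not in grid {grid}")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")

    def fingerprint_config(self) -> FingerprintConfig:
        return FingerprintConfig(
            n_layers=self.gcn_layers,
            fp_length=self.fp_length,
            hidden_width=self.hidden_width,
        )


@dataclass
class TrainingHistory:
    """Per-epoch train/validation losses in standardized (unitless) MSE."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    stop_reason: str = "max_epochs"

    def __len__(self) -> int:
        return len(self.val_loss)


@dataclass
class TrainedModel:
    """A trained (or initialized) GCN-ANN for one target.

    ``params`` holds both fingerprint weights (see
    :class:`~molorb.fingerprint.FingerprintParams`) and the ANN head weights
    ``ann:{i}:W`` / ``ann:{i}:b`` for hidden layers and ``annout:W`` /
    ``annout:b`` for the linear output.  Predictions are un-standardized with
    ``y_mean``/``y_std`` so the model outputs eV.
    """

    target: str
    hyper: Hyperparameters
    fp_params: FingerprintParams
    y_mean: float = 0.0
    y_std: float = 1.0
    history: TrainingHistory = field(default_factory=TrainingHistory)

    @property
    def weights(self) -> dict[str, np.ndarray]:
        return self.fp_params.weights


def early_stop_check(
    history: TrainingHistory | list[float], window: int = 20, band: float = 0.01
) -> bool:
    """True iff the last ``window`` validation losses span at most ``band``.

    The band comparison is inclusive; a history shorter than ``window``
    cannot stop yet and returns False.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    losses = history.val_loss if isinstance(history, TrainingHistory) else history
    if len(losses) < window:
        return False
    tail = losses[-window:]
    # inclusive boundary, robust to float representation of the band
    return (max(tail) - min(tail)) - band <= 1e-12


def _init_ann_weights(
    weights: dict[str, np.ndarray], hyper: Hyperparameters, rng: np.random.Generator
) -> None:
    in_dim = hyper.fp_length
    for i in range(hyper.ann_layers):
        weights[f"ann:{i}:W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_dim), (in_dim, hyper.ann_width)
        )
        weights[f"ann:{i}:b"] = np.zeros(hyper.ann_width)
        in_dim = hyper.ann_width
    weights["annout:W"] = rng.normal(0.0, np.sqrt(1.0 / in_dim), (in_dim, 1))
    weights["annout:b"] = np.zeros(1)


def init_model(hyper: Hyperparameters, target: str, seed: int) -> TrainedModel:
    """Random model with the given architecture; predicts ``y_mean`` offsets."""
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}, got {target!r}")
    fp_params = fpm.init_fingerprint_params(hyper.fingerprint_config(), seed)
    rng = np.random.default_rng((seed, 1))
    _init_ann_weights(fp_params.weights, hyper, rng)
    return TrainedModel(target=target, hyper=hyper, fp_params=fp_params)


# ---------------------------------------------------------------------------
# Forward / backward through fingerprint + ANN
# ---------------------------------------------------------------------------

def _ann_forward(
    fp: np.ndarray, weights: dict[str, np.ndarray], n_hidden: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    hs = [fp]
    h = fp
    for i in range(n_hidden):
        h = np.maximum(0.0, h @ weights[f"ann:{i}:W"] + weights[f"ann:{i}:b"])
        hs.append(h)
    y = (h @ weights["annout:W"] + weights["annout:b"])[:, 0]
    return y, hs


def _ann_backward(
    d_y: np.ndarray,
    hs: list[np.ndarray],
    weights: dict[str, np.ndarray],
    n_hidden: int,
    grads: dict[str, np.ndarray],
) -> np.ndarray:
    grads["annout:W"] += hs[-1].T @ d_y[:, None]
    grads["annout:b"] += np.array([d_y.sum()])
    d_h = d_y[:, None] * weights["annout:W"][:, 0][None, :]
    for i in range(n_hidden - 1, -1, -1):
        d_h = d_h * (hs[i + 1] > 0)
        grads[f"ann:{i}:W"] += hs[i].T @ d_h
        grads[f"ann:{i}:b"] += d_h.sum(axis=0)
        d_h = d_h @ weights[f"ann:{i}:W"].T
    return d_h  # gradient w.r.t. the fingerprints


def model_forward(
    pack: GraphPack, model: TrainedModel, standardized: bool = False
) -> np.ndarray:
    """Predicted energies (eV, or standardized units if requested)."""
    fp, _ = fpm.forward_batch(pack, model.fp_params)
    y, _ = _ann_forward(fp, model.weights, model.hyper.ann_layers)
    if standardized:
        return y
    return y * model.y_std + model.y_mean


def loss_and_grads(
    pack: GraphPack, model: TrainedModel, y_true_std: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE + L2 loss (standardized units) and its analytic gradients."""
    weights = model.weights
    n_hidden = model.hyper.ann_layers
    fp, cache = fpm.forward_batch(pack, model.fp_params)
    y, hs = _ann_forward(fp, weights, n_hidden)
    resid = y - y_true_std
    n = len(y)
    loss = float(resid @ resid / n)
    grads = {k: np.zeros_like(v) for k, v in weights.items()}
    d_y = 2.0 * resid / n
    d_fp = _ann_backward(d_y, hs, weights, n_hidden, grads)
    fp_grads = fpm.backward_batch(pack, model.fp_params, cache, d_fp)
    for k, g in fp_grads.items():
        grads[k] += g
    l2 = model.hyper.l2
    if l2 > 0:
        for k, v in weights.items():
            if ":W" in k or k.startswith(("conv:", "out:")):
                loss += l2 * float((v * v).sum())
                grads[k] += 2.0 * l2 * v
    return loss, grads


class AdamState:
    """Adaptive-moment gradient descent (Kingma & Ba defaults)."""

    def __init__(self, weights: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def gradient_check(
    pack: GraphPack,
    model: TrainedModel,
    y_true_std: np.ndarray,
    eps: float = 1e-4,
    n_per_array: int = 5,
    seed: int = 0,
) -> float:
    """Worst relative error of analytic vs central finite-difference
    gradients over a random sample of coordinates of every weight array.
    Diagnostic used to validate the hand-derived backpropagation."""
    _, grads = loss_and_grads(pack, model, y_true_std)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for key, W in model.weights.items():
        for _ in range(n_per_array):
            idx = tuple(int(rng.integers(0, s)) for s in W.shape)
            orig = W[idx]
            W[idx] = orig + eps
            lp, _ = loss_and_grads(pack, model, y_true_std)
            W[idx] = orig - eps
            lm, _ = loss_and_grads(pack, model, y_true_std)
            W[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[key][idx]
            worst = max(worst, abs(fd - an) / max(abs(fd), abs(an), 1e-8))
    return worst


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

def _as_graphs_and_targets(
    data, target: str
) -> tuple[list[MoleculeGraph], np.ndarray]:
    """Accept a Dataset or DataFrame with smiles + target columns."""
    df = data.df if hasattr(data, "df") else data
    col = {"homo": "e_homo", "lumo": "e_lumo", "surrogate": "surrogate_target"}[
        target
    ]
    if col not in df.columns:
        raise ValueError(f"target column {col!r} missing from data")
    graphs = []
    for rec_id, smi in zip(df["id"], df["smiles"]):
        graphs.append(parse_smiles(smi, id=str(rec_id)))
    y = df[col].to_numpy(dtype=float)
    if len(graphs) == 0:
        raise ValueError("empty dataset")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in target column {col!r}")
    return graphs, y


class NeuralFingerprintRegression:
    """GCN-ANN orbital-energy regression model.

    Parameters
    ----------
    train_data, val_data : Dataset or DataFrame
        Records with ``id``, ``smiles`` and the target column
        (``e_homo``, ``e_lumo`` or ``surrogate_target``).  Validation data
        drives early stopping; if omitted, a trailing 10% of the training
        data is held out.
    target : {"homo", "lumo", "surrogate"}
    hyper : Hyperparameters
    """

    def __init__(self, train_data, val_data=None, target: str = "homo",
                 hyper: Hyperparameters | None = None):
        if target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {target!r}")
        self.hyper = hyper if hyper is not None else Hyperparameters()
        self.hyper.validate()
        self.target = target
        self.train_graphs, self.train_y = _as_graphs_and_targets(train_data, target)
        if val_data is not None:
            self.val_graphs, self.val_y = _as_graphs_and_targets(val_data, target)
        else:
            n_val = max(1, len(self.train_graphs) // 10)
            if n_val >= len(self.train_graphs):
                raise ValueError("training set too small to hold out validation")
            self.val_graphs = self.train_graphs[-n_val:]
            self.val_y = self.train_y[-n_val:]
            self.train_graphs = self.train_graphs[:-n_val]
            self.train_y = self.train_y[:-n_val]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "homo",
                       hyper: Hyperparameters | None = None,
                       val_df: pd.DataFrame | None = None):
        return cls(df, val_data=val_df, target=target, hyper=hyper)

    def fit(self, seed: int | None = None,
            verbose: bool = False) -> "NeuralFingerprintResults":
        """Train with minibatch Adam, MSE + L2 loss and early stopping."""
        hyper = self.hyper
        seed = hyper.seed if seed is None else seed
        model = init_model(hyper, self.target, seed)
        y_mean = float(np.mean(self.train_y))
        y_std = float(np.std(self.train_y))
        if y_std < 1e-12:
            y_std = 1.0  # constant-target data: keep targets at zero
        model.y_mean, model.y_std = y_mean, y_std
        y_tr = (self.train_y - y_mean) / y_std
        y_va = (self.val_y - y_mean) / y_std

        rng = np.random.default_rng((seed, 2))
        opt = AdamState(model.weights, hyper.learning_rate)
        val_pack = pack_graphs(self.val_graphs)
        history = model.history
        n = len(self.train_graphs)
        for epoch in range(1, hyper.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, hyper.batch_size):
                idx = order[start:start + hyper.batch_size]
                if len(idx) == 0:
                    raise ValueError("empty minibatch")
                pack = pack_graphs([self.train_graphs[i] for i in idx])
                loss, grads = loss_and_grads(pack, model, y_tr[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lr={hyper.learning_rate}); aborting"
                    )
                opt.step(model.weights, grads)
                epoch_loss += loss * len(idx)
            y_hat = model_forward(val_pack, model, standardized=True)
            val_loss = float(np.mean((y_hat - y_va) ** 2))
            history.train_loss.append(epoch_loss / n)
            history.val_loss.append(val_loss)
            history.stopped_epoch = epoch
            if verbose:
                print(f"epoch {epoch:4d}  train {epoch_loss / n:.5f}  "
                      f"val {val_loss:.5f}")
            if early_stop_check(history):
                history.stop_reason = "early"
                break
        else:
            history.stop_reason = "max_epochs"
        return NeuralFingerprintResults(self, model)


class NeuralFingerprintResults:
    """Results of fitting a :class:`NeuralFingerprintRegression`."""

    def __init__(self, model_spec: NeuralFingerprintRegression | None,
                 model: TrainedModel):
        self.model_spec = model_spec
        self.model = model
        self.history = model.history

    @property
    def target(self) -> str:
        return self.model.target

    def predict(self, molecules) -> np.ndarray:
        """Predict energies (eV) for SMILES strings, graphs, or a Dataset."""
        graphs = _coerce_graphs(molecules)
        return model_forward(pack_graphs(graphs), self.model)

    def evaluate(self, data, target: str | None = None) -> EvalReport:
        graphs, y_true = _as_graphs_and_targets(data, target or self.target)
        y_pred = model_forward(pack_graphs(graphs), self.model)
        return evaluate(y_pred, y_true)

    def summary(self) -> str:
        m, h = self.model, self.model.history
        lines = [
            "Neural fingerprint regression results",
            "=" * 45,
            f"target:            {m.target.upper()}",
            f"GCN layers:        {m.hyper.gcn_layers}",
            f"ANN hidden layers: {m.hyper.ann_layers}",
            f"fingerprint len:   {m.hyper.fp_length}",
            f"batch size:        {m.hyper.batch_size}",
            f"learning rate:     {m.hyper.learning_rate}",
            f"L2:                {m.hyper.l2}",
            f"epochs run:        {h.stopped_epoch} ({h.stop_reason})",
            f"final train loss:  {h.train_loss[-1]:.5f}" if h.train_loss else
            "final train loss:  n/a",
            f"final val loss:    {h.val_loss[-1]:.5f}" if h.val_loss else
            "final val loss:    n/a",
            f"target mean/sd:    {m.y_mean:.3f} / {m.y_std:.3f} eV",
        ]
        return "\n".join(lines)


def _coerce_graphs(molecules) -> list[MoleculeGraph]:
    if hasattr(molecules, "df"):
        return [parse_smiles(s, id=str(i))
                for i, s in zip(molecules.df["id"], molecules.df["smiles"])]
    if isinstance(molecules, MoleculeGraph):
        return [molecules]
    if isinstance(molecules, str):
        return [parse_smiles(molecules)]
    return [m if isinstance(m, MoleculeGraph) else parse_smiles(m)
            for m in molecules]


# Functional wrappers -------------------------------------------------------

def train_model(train_set, val_set, hyper: Hyperparameters,
                target: str) -> TrainedModel:
    """Train one GCN-ANN; functional wrapper over the Model/Results API."""
    spec = NeuralFingerprintRegression(train_set, val_set, target, hyper)
    return spec.fit(seed=hyper.seed).model


def predict_energy(graph: MoleculeGraph | str, model: TrainedModel) -> float:
    """Predicted energy (eV) of one molecule under one trained model."""
    graphs = _coerce_graphs(graph)
    return float(model_forward(pack_graphs(graphs), model)[0])
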