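"""Regression evaluation: RMSE, MAE, R², SMAPE and residual outliers.

SMAPE here uses the bounded form

    SMAPE = (100 / N) * sum_i |y_i - x_i| / (|y_i| + |x_i|)

whose per-pair term is at most 1 by the triangle inequality, so the metric
lives in [0, 100] percent.  (This is deliberately not the common variant
with denominator (|y|+|x|)/2, which is bounded at 200.)  A pair with
``y == x == 0`` contributes 0 by the perfect-prediction limit convention;
``zero_rule="strict"`` raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EvalReport:
    """Evaluation metrics for one prediction set (energies in eV)."""

    rmse: float
    mae: float
    r2: float
    smape: float
    n: int
    outlier_indices: list[int] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"n {self.n}",
            f"rmse_eV {self.rmse:.6g}",
            f"mae_eV {self.mae:.6g}",
            f"r2 {self.r2:.6g}",
            f"smape_pct {self.smape:.6g}",
            f"outliers {' '.join(map(str, self.outlier_indices)) or '-'}",
        ]
        return "\n".join(lines)


def _check_pair(pred, true) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction set")
    return pred, true


def smape(pred, true, zero_rule: str = "zero") -> float:
    """Symmetric mean absolute percentage error, in percent, bounded at 100."""
    pred, true = _check_pair(pred, true)
    num = np.abs(pred - true)
    den = np.abs(pred) + np.abs(true)
    zero_pairs = den == 0
    if zero_pairs.any():
        if zero_rule == "strict":
            raise ZeroDivisionError(
                "pair with |pred| + |true| == 0; no SMAPE contribution defined"
            )
        den = np.where(zero_pairs, 1.0, den)  # numerator is 0 there too
    return float(100.0 * np.mean(num / den))


def evaluate(pred, true, outlier_threshold_sd: float = 3.0) -> EvalReport:
    """Full evaluation report; residual outliers flagged beyond 3 sd."""
    pred, true = _check_pair(pred, true)
    resid = pred - true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_res = float((resid**2).sum())
    ss_tot = float(((true - true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    out = (
        flag_outliers(pred, true, outlier_threshold_sd) if len(pred) >= 3 else []
    )
    return EvalReport(
        rmse=rmse,
        mae=mae,
        r2=r2,
        smape=smape(pred, true),
        n=int(len(pred)),
        outlier_indices=out,
    )


def flag_outliers(pred, true, threshold_sd: float = 3.0) -> list[int]:
    """Indices whose residual lies more than ``threshold_sd`` standard
    deviations from the mean residual.

    Zero residual variance (all residuals identical) yields no outliers.
    """
    pred, true = _check_pair(pred, true)
    if len(pred) < 3:
        raise ValueError("need at least 3 points to flag residual outliers")
    resid = pred - true
    sd = float(np.std(resid))
    if sd == 0:
        return []
    z = np.abs(resid - resid.mean()) / sd
    return [int(i) for i in np.nonzero(z > threshold_sd)[0]]
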