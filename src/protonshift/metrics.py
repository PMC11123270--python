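"""Evaluation statistics: MAE, R^2, through-origin slope, cosine similarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvalResult:
    mae: float                   # ppm
    r2: float
    slope_through_origin: float
    n_shifts: int


def _paired(pred, obs):
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return pred, obs


def mae(pred, obs) -> float:
    """Mean absolute difference, ppm."""
    pred, obs = _paired(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot, with obs as reference."""
    pred, obs = _paired(pred, obs)
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observations are constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def slope_through_origin(pred, obs) -> float:
    """Least-squares slope A of obs = A * pred through the origin:
    A = sum(x*y) / sum(x^2)."""
    x, y = _paired(pred, obs)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all predictions zero; slope undefined")
    return float(np.sum(x * y)) / sxx


def cosine_similarity(class_counts_a, class_counts_b) -> float:
    """Cosine of percentage-normalized class-count vectors (same vocabulary)."""
    a = np.asarray(class_counts_a, dtype=float)
    b = np.asarray(class_counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("class vocabularies differ in size")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero class-count vector")
    pa = 100.0 * a / a.sum()
    pb = 100.0 * b / b.sum()
    return float(pa @ pb / (np.linalg.norm(pa) * np.linalg.norm(pb)))


def evaluate(pred, obs) -> EvalResult:
    return EvalResult(mae=mae(pred, obs), r2=r_squared(pred, obs),
                      slope_through_origin=slope_through_origin(pred, obs),
                      n_shifts=int(np.asarray(pred).size))
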