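"""Goodness-of-fit and model-comparison statistics.

Fit quality between a model's mean investment-ratio curve and a cohort's
mean curve is measured two ways:

* per round: ``SSD1`` (mean squared per-round deviation) and ``R**2`` (the
  squared Pearson correlation of the two curves), combined into the
  complexity-penalized ``AIC1 = T * ln(SSD1) + 2p`` with T rounds and p
  free parameters;
* on grand means over participants and rounds: ``SSD2`` (squared
  difference) and ``AIC2 = ln(SSD2) + 2p``.

Note the deliberate literalism of ``R**2``: squaring the correlation
rewards anti-trending curves just as much as trending ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .rl_agents import n_free_params

__all__ = [
    "ssd1",
    "r_squared",
    "aic1",
    "ssd2_aic2",
    "block_means",
    "objective_value",
    "ComparisonRow",
    "comparison_table",
]

#: below this SSD1 two curves are treated as identical in the degenerate
#: zero-variance branch of R**2
_DEGENERATE_TOL = 1e-12


def _as_curves(model_curve, human_curve) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(model_curve, dtype=float)
    h = np.asarray(human_curve, dtype=float)
    if m.shape != h.shape or m.ndim != 1:
        raise ValueError(f"curves must be 1-D and equal length, got {m.shape} vs {h.shape}")
    return m, h


def ssd1(model_curve, human_curve) -> float:
    """Mean over rounds of the squared per-round difference of mean curves."""
    m, h = _as_curves(model_curve, human_curve)
    return float(np.mean((m - h) ** 2))


def r_squared(model_curve, human_curve) -> float:
    """Square of the Pearson correlation between the two mean curves.

    With a zero-variance curve the correlation is undefined; by convention
    the result is 1 when the curves are (numerically) identical and 0
    otherwise, keeping the calibration objective continuous.
    """
    m, h = _as_curves(model_curve, human_curve)
    if len(m) < 2:
        raise ValueError("curves must have length >= 2")
    if np.ptp(m) == 0.0 or np.ptp(h) == 0.0:
        return 1.0 if ssd1(m, h) < _DEGENERATE_TOL else 0.0
    r = np.corrcoef(m, h)[0, 1]
    return float(r * r)


def aic1(ssd1_value: float, p: int, n_rounds: int = 30) -> float:
    """Per-round AIC: ``n_rounds * ln(SSD1) + 2p``.

    A zero SSD1 is reported as ``-inf`` with a warning rather than an error:
    it arises only from exactly identical curves.
    """
    if ssd1_value < 0:
        raise ValueError("ssd1 must be non-negative")
    if ssd1_value == 0:
        warnings.warn("SSD1 = 0: AIC1 reported as -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n_rounds * math.log(ssd1_value) + 2 * p


def ssd2_aic2(model_grand_mean: float, human_grand_mean: float, p: int) -> tuple[float, float]:
    """Grand-mean statistics: ``SSD2 = (Xm - Xh)**2``, ``AIC2 = ln(SSD2) + 2p``."""
    for name, v in (("model_grand_mean", model_grand_mean),
                    ("human_grand_mean", human_grand_mean)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    ssd2 = (model_grand_mean - human_grand_mean) ** 2
    if ssd2 == 0:
        warnings.warn("SSD2 = 0: AIC2 reported as -inf", RuntimeWarning, stacklevel=2)
        return 0.0, -math.inf
    return ssd2, math.log(ssd2) + 2 * p


def block_means(curve) -> np.ndarray:
    """Means of consecutive 5-round blocks (length-30 curve -> 6 blocks)."""
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1 or len(c) % 5 != 0:
        raise ValueError("curve length must be a multiple of 5")
    return c.reshape(-1, 5).mean(axis=1)


def objective_value(model_curve, human_curve) -> float:
    """The calibration loss ``SSD1 + (1 - R**2)`` for one pair of curves."""
    return ssd1(model_curve, human_curve) + (1.0 - r_squared(model_curve, human_curve))


@dataclass(frozen=True)
class ComparisonRow:
    """One model's fit statistics in one condition (a table row)."""

    model_id: str
    condition_id: str
    ssd1: float
    r_squared: float
    aic1: float
    ssd2: float
    aic2: float
    p_free_params: int

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id, "condition_id": self.condition_id,
            "SSD1": self.ssd1, "R2": self.r_squared, "AIC1": self.aic1,
            "SSD2": self.ssd2, "AIC2": self.aic2, "p": self.p_free_params,
        }


def comparison_row(model_id: str, condition_id: str, model_curve, human_curve,
                   model_grand_mean: float | None = None,
                   human_grand_mean: float | None = None) -> ComparisonRow:
    """Compute the full statistics row for one model curve vs one cohort."""
    m, h = _as_curves(model_curve, human_curve)
    p = n_free_params(model_id)
    s1 = ssd1(m, h)
    xm = float(np.mean(m)) if model_grand_mean is None else model_grand_mean
    xh = float(np.mean(h)) if human_grand_mean is None else human_grand_mean
    s2, a2 = ssd2_aic2(xm, xh, p)
    return ComparisonRow(
        model_id=model_id, condition_id=condition_id, ssd1=s1,
        r_squared=r_squared(m, h), aic1=aic1(s1, p, n_rounds=len(m)),
        ssd2=s2, aic2=a2, p_free_params=p)


def comparison_table(rows: list[ComparisonRow]) -> list[ComparisonRow]:
    """Sort rows by AIC1 ascending (best model first)."""
    conditions = {r.condition_id for r in rows}
    if len(conditions) > 1:
        raise ValueError(f"rows mix conditions: {sorted(conditions)}")
    return sorted(rows, key=lambda r: r.aic1)
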