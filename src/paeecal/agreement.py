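"""Agreement between criterion and predicted PAEE.

Implements the method-comparison statistics used to validate wearable
energy-expenditure predictions against indirect calorimetry:

* Pearson correlation r and R² between criterion and predicted series;
* standard error of the estimate, SEE = sqrt(Σd² / (n − p));
* Bland–Altman bias and 95% limits of agreement, bias ± 1.96·SD(d) with
  differences d = predicted − criterion (so a method that underestimates
  shows a negative bias);
* per-task error tables: MAE, MAPE, mean signed error and RMSE, with MAPE
  restricted to stages whose criterion is positive (rest has criterion
  PAEE = 0, making a percentage error undefined);
* the normal-approximation paired sample-size formula behind the study's
  a-priori power computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Limits-of-agreement multiplier for nominal 95% coverage of differences.
LOA_MULTIPLIER = 1.96


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the given inputs (e.g. zero variance)."""


@dataclass(frozen=True)
class AgreementReport:
    """Correlation, SEE and Bland–Altman agreement for one method/group."""

    r: float
    r_squared: float
    see: float
    bias: float
    loa_half_width: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to a paired-difference sample-size computation."""

    d: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("effect size d must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def _pair(criterion, predicted) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(criterion, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if c.shape != p.shape:
        raise ValueError("criterion and predicted must have equal length")
    return c, p


def correlation_stats(criterion, predicted) -> tuple[float, float]:
    """Pearson r and R² between criterion and predicted series."""
    c, p = _pair(criterion, predicted)
    if len(c) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(c) == 0 or np.ptp(p) == 0:
        raise UndefinedStatisticError("correlation undefined: a series has zero variance")
    r = float(stats.pearsonr(c, p)[0])
    return r, r * r


def standard_error_estimate(criterion, predicted, n_params: int = 3) -> float:
    """SEE = sqrt(Σ(criterion − predicted)² / (n − n_params)).

    ``n_params`` counts the intercept: 3 for the PAC+HR equation, 2 for the
    HR-only comparator.
    """
    c, p = _pair(criterion, predicted)
    n = len(c)
    if n <= n_params:
        raise ValueError(f"need n > n_params ({n_params}), got n = {n}")
    d = c - p
    return float(np.sqrt(d @ d / (n - n_params)))


def bland_altman(criterion, predicted) -> tuple[float, float, np.ndarray]:
    """Bias, 95% limits-of-agreement half-width, and per-pair differences.

    Differences are predicted − criterion; the half-width is
    1.96 × sample SD (ddof=1) of the differences.
    """
    c, p = _pair(criterion, predicted)
    if len(c) < 2:
        raise ValueError("need at least 2 pairs")
    d = p - c
    bias = float(np.mean(d))
    half = float(LOA_MULTIPLIER * np.std(d, ddof=1))
    return bias, half, d


def agreement_report(criterion, predicted, n_params: int = 3) -> AgreementReport:
    """Bundle r/R², SEE and Bland–Altman statistics for one comparison."""
    r, r2 = correlation_stats(criterion, predicted)
    see = standard_error_estimate(criterion, predicted, n_params=n_params)
    bias, half, _ = bland_altman(criterion, predicted)
    return AgreementReport(r=r, r_squared=r2, see=see, bias=bias,
                           loa_half_width=half, n=len(np.asarray(criterion)))


def error_stats(
    pairs: pd.DataFrame,
    task_col: str = "task",
    criterion_col: str = "criterion_paee",
    predicted_col: str = "predicted_paee",
    exclude_zero_criterion: bool = True,
) -> pd.DataFrame:
    """Per-task and overall MAE, MAPE, mean signed error and RMSE.

    MAPE averages |d|/criterion·100 over pairs with positive criterion; when
    ``exclude_zero_criterion`` is False and a task has no positive-criterion
    pair, MAPE is emitted as NaN with a warning rather than raising. The
    returned frame has one row per task plus an ``overall`` row.
    """
    need = [task_col, criterion_col, predicted_col]
    missing = [c for c in need if c not in pairs.columns]
    if missing:
        raise KeyError(f"pairs missing columns: {missing}")

    def _one(df: pd.DataFrame, label: str) -> dict:
        if df.empty:
            raise ValueError(f"task group '{label}' is empty")
        c = df[criterion_col].to_numpy(float)
        p = df[predicted_col].to_numpy(float)
        d = p - c
        pos = c > 0
        if pos.any():
            mape = float(np.mean(np.abs(d[pos]) / c[pos]) * 100.0)
        else:
            if not exclude_zero_criterion:
                warnings.warn(
                    f"MAPE undefined for '{label}': no positive criterion values",
                    stacklevel=3,
                )
            mape = float("nan")
        return {
            task_col: label,
            "n": len(df),
            "mae": float(np.mean(np.abs(d))),
            "mape_pct": mape,
            "signed_error": float(np.mean(d)),
            "rmse": float(np.sqrt(np.mean(d * d))),
        }

    rows = [_one(g, str(task)) for task, g in pairs.groupby(task_col, sort=True)]
    rows.append(_one(pairs, "overall"))
    return pd.DataFrame(rows)


def bland_altman_plot(criterion, predicted, ax=None, title: str | None = None):
    """Bland–Altman plot: differences against pair means, with bias and
    95% limits-of-agreement lines. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    c, p = _pair(criterion, predicted)
    bias, half, d = bland_altman(c, p)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((c + p) / 2.0, d, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(bias, color="k", lw=1.2)
    for y in (bias - half, bias + half):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of criterion and predicted PAEE (kcal·min$^{-1}$)")
    ax.set_ylabel("predicted − criterion (kcal·min$^{-1}$)")
    if title:
        ax.set_title(title)
    return ax


def power_sample_size(spec: PowerSpec) -> int:
    """Minimum paired sample size via the normal approximation.

    n = ceil(((z_{1−α/2} + z_{1−β}) / d)²) for a two-sided paired (or
    one-sample) comparison at effect size d.
    """
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    z_beta = stats.norm.ppf(spec.power)
    return max(1, math.ceil(((z_alpha + z_beta) / spec.d) ** 2))
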