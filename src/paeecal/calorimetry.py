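"""Criterion energy expenditure from respiratory gas exchange.

Indirect calorimetry converts oxygen uptake (V̇O₂) and carbon-dioxide
production (V̇CO₂), both in L·min⁻¹, to an energy expenditure rate with the
abbreviated Weir equation (urinary nitrogen / protein oxidation neglected):

    EE (kcal·min⁻¹) = 3.941·V̇O₂ + 1.106·V̇CO₂

Physical-activity energy expenditure (PAEE) is total expenditure minus the
per-minute resting metabolic rate; metabolic equivalents (METs) are
expenditure expressed as a multiple of resting expenditure, so rest is
exactly 1.0 MET. Steady-state values are means over the final window
(default 2 min) of each task stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Abbreviated Weir coefficients, kcal per litre of gas exchanged.
WEIR_KCAL_PER_L_O2 = 3.941
WEIR_KCAL_PER_L_CO2 = 1.106

MIN_PER_DAY = 1440.0


class IncompleteTaskError(ValueError):
    """Stream does not cover the steady-state averaging window."""


@dataclass(frozen=True)
class RestingProfile:
    """Resting physiology of one participant.

    Parameters
    ----------
    rmr : float
        Resting metabolic rate, kcal·day⁻¹ (must be positive).
    rest_hr : float
        Resting heart rate, bpm.
    """

    rmr: float
    rest_hr: float

    def __post_init__(self) -> None:
        if not self.rmr > 0:
            raise ValueError(f"rmr must be positive, got {self.rmr}")


@dataclass(frozen=True)
class ActivitySummary:
    """Steady-state summary of one participant-task stage."""

    task: str
    tee: float
    paee: float
    mets: float
    rer: float
    mean_hr: float
    mean_pac: float
    pci: float | None
    n_epochs_averaged: int


def weir_ee(vo2, vco2):
    """Energy expenditure (kcal·min⁻¹) from gas exchange via abbreviated Weir.

    Accepts scalars or arrays; negative inputs are rejected.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas exchange rates must be non-negative")
    out = WEIR_KCAL_PER_L_O2 * vo2 + WEIR_KCAL_PER_L_CO2 * vco2
    return float(out) if out.ndim == 0 else out


def invert_weir(tee: float, rer: float) -> tuple[float, float]:
    """(V̇O₂, V̇CO₂) in L·min⁻¹ that reproduce ``tee`` at respiratory exchange
    ratio ``rer``; the exact inverse of :func:`weir_ee` given V̇CO₂ = RER·V̇O₂."""
    if tee < 0:
        raise ValueError("tee must be non-negative")
    if rer <= 0:
        raise ValueError("rer must be positive")
    vo2 = tee / (WEIR_KCAL_PER_L_O2 + WEIR_KCAL_PER_L_CO2 * rer)
    return vo2, rer * vo2


def rmr_per_min(rmr: float) -> float:
    """Convert a daily resting metabolic rate (kcal·day⁻¹) to kcal·min⁻¹."""
    if not rmr > 0:
        raise ValueError(f"rmr must be positive, got {rmr}")
    return rmr / MIN_PER_DAY


def steady_state_mean(
    stream: pd.DataFrame,
    duration_min: float,
    window_min: float = 2.0,
    time_col: str = "t_s",
) -> pd.Series:
    """Mean of every numeric column over the final ``window_min`` of a stage.

    Samples with ``t_s >= (duration_min - window_min) * 60`` are averaged; the
    sample count is returned under ``n_epochs_averaged``. An empty window
    raises :class:`IncompleteTaskError` (the participant did not complete the
    stage).
    """
    cutoff = (duration_min - window_min) * 60.0
    tail = stream.loc[stream[time_col] >= cutoff]
    if tail.empty:
        raise IncompleteTaskError(
            f"no samples at t >= {cutoff:g} s; stage incomplete"
        )
    means = tail.drop(columns=[time_col]).mean(numeric_only=True)
    means["n_epochs_averaged"] = len(tail)
    return means


def compute_paee(tee: float, resting: RestingProfile) -> float:
    """Physical-activity energy expenditure: TEE minus per-minute RMR.

    A negative result (expenditure below rest) is reported with a warning,
    not clipped — clipping would bias downstream agreement statistics.
    """
    if tee < 0:
        raise ValueError("tee must be non-negative")
    paee = tee - rmr_per_min(resting.rmr)
    if paee < 0:
        warnings.warn(
            f"PAEE is negative ({paee:.3f} kcal/min): TEE below resting rate",
            stacklevel=2,
        )
    return paee


def compute_rer(vo2: float, vco2: float) -> float:
    """Respiratory exchange ratio V̇CO₂/V̇O₂; undefined when V̇O₂ is zero."""
    if vo2 <= 0:
        raise ValueError("RER undefined: vo2 must be positive")
    return vco2 / vo2


def compute_mets(tee: float, resting: RestingProfile) -> float:
    """Metabolic equivalents referenced to the participant's measured RMR.

    Defined as TEE divided by per-minute RMR, so the resting stage is 1.0 by
    construction (the 3.5 mL·kg⁻¹·min⁻¹ population convention is deliberately
    not used; the cohort's measured RMRs are available and individual).
    """
    if tee < 0:
        raise ValueError("tee must be non-negative")
    return tee / rmr_per_min(resting.rmr)


def summarize_task(
    gas: pd.DataFrame,
    epochs: pd.DataFrame,
    resting: RestingProfile,
    task: str,
    duration_min: float = 5.0,
    velocity: float = 0.0,
    window_min: float = 2.0,
) -> ActivitySummary:
    """Steady-state :class:`ActivitySummary` for one participant-task stage.

    ``gas`` needs columns ``t_s, vo2_l_min, vco2_l_min``; ``epochs`` needs
    ``t_s, pac_counts_min, hr_bpm``. PCI is computed for walking stages
    (velocity > 0) only.
    """
    from .gait import pci as _pci  # local import: avoid cycle at module load

    g = steady_state_mean(gas, duration_min, window_min)
    e = steady_state_mean(epochs, duration_min, window_min)
    tee = weir_ee(g["vo2_l_min"], g["vco2_l_min"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative PAEE surfaced via the value
        paee = compute_paee(tee, resting)
    return ActivitySummary(
        task=task,
        tee=tee,
        paee=paee,
        mets=compute_mets(tee, resting),
        rer=compute_rer(g["vo2_l_min"], g["vco2_l_min"]),
        mean_hr=e["hr_bpm"],
        mean_pac=e["pac_counts_min"],
        pci=_pci(e["hr_bpm"], resting.rest_hr, velocity) if velocity > 0 else None,
        n_epochs_averaged=int(e["n_epochs_averaged"]),
    )
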