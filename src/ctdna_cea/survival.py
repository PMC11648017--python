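"""Survival summaries → per-cycle cause-specific transition probabilities.

Trial PFS/OS enter the model as medians (exponential approximation) or as
piecewise-constant hazards. Within a cycle the competing risks (progression,
death, supportive-care entry) are treated as cause-specific constant hazards,
so per-cycle probabilities are the standard multistate conversion

    p_event = 1 - exp(-Λ·t),   p_cause_i = p_event · λ_i / Λ,   Λ = Σ λ_i,

which can never go negative (unlike subtracting probabilities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterError, SurvivalSpec

__all__ = [
    "DAYS_PER_MONTH",
    "CycleGrid",
    "CycleHazards",
    "median_to_rate",
    "cause_specific_cycle_probs",
    "competing_risk_probs",
    "average_hazard",
    "piecewise_cycle_hazards",
]

logger = logging.getLogger(__name__)

#: months → days conversion (365.25 / 12)
DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class CycleGrid:
    """The model's irregular cycle grid: one 4-week cycle, then 3-week cycles.

    ``boundaries`` are days from model entry, starting at 0; the last partial
    cycle beyond the horizon is dropped so every cycle is full length.
    """

    boundaries: np.ndarray

    @classmethod
    def build(
        cls, cycle1_days: float = 28.0, cycle_days: float = 21.0,
        horizon_years: float = 5.0,
    ) -> "CycleGrid":
        horizon_days = horizon_years * 365.25
        if horizon_days <= cycle1_days:
            raise ParameterError("horizon must exceed the first cycle")
        n_later = int(np.floor((horizon_days - cycle1_days) / cycle_days))
        b = np.concatenate(
            [[0.0, cycle1_days], cycle1_days + cycle_days * np.arange(1, n_later + 1)]
        )
        return cls(boundaries=b)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.boundaries)


@dataclass(frozen=True)
class CycleHazards:
    """Per-cycle progression and death hazards (per day) for one line."""

    lam_prog: np.ndarray
    lam_death: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lam_prog < 0) or np.any(self.lam_death < 0):
            raise ParameterError("cycle hazards must be >= 0")


def median_to_rate(median_months: float) -> float:
    """Daily hazard of an exponential with the given median (months)."""
    if median_months <= 0:
        raise ParameterError(f"median must be > 0, got {median_months}")
    return np.log(2.0) / (median_months * DAYS_PER_MONTH)


def competing_risk_probs(hazards, interval_days: float) -> np.ndarray:
    """Probabilities for each cause plus staying, under constant hazards.

    Returns an array of ``len(hazards) + 1``: one entry per cause-specific
    hazard, with the stay probability appended. Entries sum to 1.
    """
    lam = [float(h) for h in hazards]
    if any(h < 0 for h in lam) or interval_days < 0:
        raise ParameterError("hazards and interval must be >= 0")
    total = sum(lam)
    out = np.empty(len(lam) + 1)
    if total == 0.0:
        out[:-1] = 0.0
        out[-1] = 1.0
        return out
    p_event = -math.expm1(-total * interval_days)
    out[:-1] = [p_event * h / total for h in lam]
    out[-1] = 1.0 - p_event
    return out


def cause_specific_cycle_probs(
    lam_pfs_event: float, lam_death: float, interval_days: float
) -> tuple[float, float, float]:
    """Split a PFS event hazard into progression vs death over one cycle.

    PFS events include deaths, so the progression hazard is
    ``lam_pfs_event - lam_death``; requires ``lam_pfs_event >= lam_death``.
    Returns ``(p_prog, p_death, p_stay)`` summing to 1.
    """
    if lam_death < 0 or lam_pfs_event < 0:
        raise ParameterError("hazards must be >= 0")
    if lam_death > lam_pfs_event + 1e-15:
        raise ParameterError(
            f"inconsistent survival inputs: death hazard {lam_death:g} exceeds "
            f"PFS event hazard {lam_pfs_event:g}"
        )
    lam_prog = max(lam_pfs_event - lam_death, 0.0)
    p_prog, p_death, p_stay = competing_risk_probs([lam_prog, lam_death], interval_days)
    return float(p_prog), float(p_death), float(p_stay)


def average_hazard(spec: SurvivalSpec, t0_days: float, t1_days: float) -> float:
    """Duration-weighted mean daily hazard of ``spec`` over ``[t0, t1)``.

    For an exponential-median spec this is the constant rate. For a piecewise
    spec the last piece is extended beyond its coverage (logged once).
    """
    if t1_days <= t0_days:
        raise ParameterError("need t1 > t0")
    if spec.form == "exponential_median":
        return median_to_rate(spec.median)
    breaks = np.asarray(spec.breakpoints, dtype=float) * DAYS_PER_MONTH
    rates = np.asarray(spec.hazards, dtype=float) / DAYS_PER_MONTH
    edges = np.append(breaks, np.inf)
    if t1_days > breaks[-1] and len(breaks) > 1:
        logger.debug("piecewise spec extended beyond last breakpoint (%.0f d)", breaks[-1])
    total = 0.0
    for lo, hi, rate in zip(edges[:-1], edges[1:], rates):
        a, b = max(lo, t0_days), min(hi, t1_days)
        if b > a:
            total += rate * (b - a)
    return total / (t1_days - t0_days)


def read_piecewise_csv(path) -> SurvivalSpec:
    """Read a piecewise-hazard table from CSV.

    Expects columns ``time_months`` (interval start, first row 0) and
    ``hazard_per_month``; rows may be unordered.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"time_months", "hazard_per_month"} - set(df.columns)
    if missing:
        raise ParameterError(f"piecewise CSV {path} lacks columns: {sorted(missing)}")
    df = df.sort_values("time_months")
    return SurvivalSpec(
        form="piecewise_hazard",
        breakpoints=[float(v) for v in df["time_months"]],
        hazards=[float(v) for v in df["hazard_per_month"]],
    )


def piecewise_cycle_hazards(
    pfs: SurvivalSpec, os: SurvivalSpec, grid: CycleGrid
) -> CycleHazards:
    """Per-cycle (progression, death) hazards on the model grid.

    Hazards are time-weighted means of the cause-specific rates over each
    cycle interval; the progression hazard is the PFS event hazard minus the
    death hazard, clipped at 0 with an error if materially negative.
    """
    b = grid.boundaries
    lam_pfs = np.array([average_hazard(pfs, b[i], b[i + 1]) for i in range(grid.n_cycles)])
    lam_os = np.array([average_hazard(os, b[i], b[i + 1]) for i in range(grid.n_cycles)])
    if np.any(lam_os > lam_pfs + 1e-12):
        raise ParameterError(
            "death hazard exceeds PFS event hazard on at least one cycle "
            "(inconsistent PFS/OS inputs)"
        )
    return CycleHazards(lam_prog=np.maximum(lam_pfs - lam_os, 0.0), lam_death=lam_os)
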