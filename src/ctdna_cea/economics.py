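"""Deterministic and probabilistic cost-effectiveness outputs.

The incremental cost-effectiveness ratio (ICER) is ΔC/ΔE between the
ctDNA-guided arm and standard of care; quadrants where the ratio is not
interpretable return dominance labels instead of numbers. The incremental
net monetary benefit is iNMB = WTP·ΔE − ΔC.

The probabilistic sensitivity analysis re-runs both arms per iteration on a
common random draw of the parameter set (exact common random numbers — see
:mod:`ctdna_cea.parameters`), and summarizes the iteration cloud as a mean
ICER (ratio of mean increments, the stable estimator; mean-of-ratios is
available as an option), percentile confidence intervals (order statistics,
no normal approximation), the probability of cost-effectiveness at the
willingness-to-pay threshold, and the acceptability curve (CEAC) on a WTP
grid. Iteration seeds are spawned from the master seed with
``SeedSequence(seed).spawn(n)``, so iteration i is reproducible for any
``n > i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import ArmResult, run_cohort
from .parameters import ParameterError, ParameterSet, sample_parameters

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "COST_SAVING_LESS_EFFECTIVE",
    "UNDEFINED",
    "icer",
    "inmb",
    "CEAResult",
    "PSAResult",
    "run_deterministic",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"
COST_SAVING_LESS_EFFECTIVE = "cost-saving-less-effective"
UNDEFINED = "undefined"

#: default CEAC grid: €0 to €200,000 in €1,000 steps
DEFAULT_WTP_GRID = tuple(float(w) for w in range(0, 200_001, 1000))


def icer(dc: float, de: float) -> float | str:
    """ΔC/ΔE in EUR per QALY, or a dominance label when the ratio is not one.

    ``de > 0`` returns the ratio (negative ⇒ intervention dominates on cost);
    ``de < 0`` returns ``dominated`` (costlier) or
    ``cost-saving-less-effective``; ``de == 0`` is ``undefined``.
    """
    if de > 0:
        return DOMINANT if dc < 0 else dc / de
    if de < 0:
        return DOMINATED if dc > 0 else COST_SAVING_LESS_EFFECTIVE
    return UNDEFINED


def inmb(dc: float, de: float, wtp: float) -> float:
    """Incremental net monetary benefit, ``wtp*de - dc``."""
    if wtp < 0:
        raise ParameterError("wtp must be >= 0")
    return wtp * de - dc


@dataclass
class CEAResult:
    """Deterministic cost-effectiveness comparison of the two arms."""

    soc: ArmResult
    intervention: ArmResult
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.intervention.total_cost_disc - self.soc.total_cost_disc

    @property
    def delta_qalys(self) -> float:
        return self.intervention.qalys_disc - self.soc.qalys_disc

    @property
    def delta_life_years(self) -> float:
        return self.intervention.life_years_disc - self.soc.life_years_disc

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_qalys)

    @property
    def inmb(self) -> float:
        return inmb(self.delta_cost, self.delta_qalys, self.wtp)

    def summary(self) -> dict:
        return {
            "soc_cost": self.soc.total_cost_disc,
            "soc_qalys": self.soc.qalys_disc,
            "soc_life_years": self.soc.life_years_disc,
            "intervention_cost": self.intervention.total_cost_disc,
            "intervention_qalys": self.intervention.qalys_disc,
            "intervention_life_years": self.intervention.life_years_disc,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "inmb": self.inmb,
            "wtp": self.wtp,
        }


def run_deterministic(
    ps: ParameterSet, ps_intervention: ParameterSet | None = None
) -> CEAResult:
    """Run both arms at point estimates.

    ``ps_intervention`` allows arm-specific scenario overlays; by default both
    arms read the same parameter set.
    """
    psi = ps_intervention or ps
    return CEAResult(
        soc=run_cohort("standard_of_care", ps),
        intervention=run_cohort("ctdna_guided", psi),
        wtp=ps.wtp,
    )


@dataclass
class PSAResult:
    """Per-iteration (cost, QALY) pairs per arm and derived summaries."""

    seed: int
    wtp: float
    costs: np.ndarray        # (n, 2): [soc, intervention]
    qalys: np.ndarray        # (n, 2)
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    failed_iterations: list[int] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return self.costs.shape[0]

    @property
    def delta_costs(self) -> np.ndarray:
        return self.costs[:, 1] - self.costs[:, 0]

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qalys[:, 1] - self.qalys[:, 0]

    @property
    def inmbs(self) -> np.ndarray:
        return self.wtp * self.delta_qalys - self.delta_costs

    @property
    def mean_icer(self) -> float | str:
        """Ratio of mean increments (stable when ΔE crosses zero)."""
        return icer(float(self.delta_costs.mean()), float(self.delta_qalys.mean()))

    @property
    def mean_icer_of_ratios(self) -> float:
        """Mean of per-iteration ratios; unstable near ΔE = 0, use with care."""
        de = self.delta_qalys
        return float(np.mean(self.delta_costs[de != 0] / de[de != 0]))

    @property
    def mean_inmb(self) -> float:
        return float(self.inmbs.mean())

    @property
    def prob_cost_effective(self) -> float:
        return float(np.mean(self.inmbs > 0.0))

    def percentile_intervals(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Order-statistic (percentile) intervals per arm per outcome."""
        q = [100 * (1 - level) / 2, 100 * (1 + level) / 2]
        out = {}
        for label, col in (("soc", 0), ("intervention", 1)):
            out[f"{label}_cost"] = tuple(np.percentile(self.costs[:, col], q))
            out[f"{label}_qalys"] = tuple(np.percentile(self.qalys[:, col], q))
        out["delta_cost"] = tuple(np.percentile(self.delta_costs, q))
        out["delta_qalys"] = tuple(np.percentile(self.delta_qalys, q))
        return out

    @property
    def ceac(self) -> dict[float, float]:
        return ceac(self, self.wtp_grid)

    def ce_plane(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_qalys": self.delta_qalys, "delta_cost": self.delta_costs})

    def summary(self) -> dict:
        ci = self.percentile_intervals()
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "wtp": self.wtp,
            "soc_cost": float(self.costs[:, 0].mean()),
            "soc_qalys": float(self.qalys[:, 0].mean()),
            "intervention_cost": float(self.costs[:, 1].mean()),
            "intervention_qalys": float(self.qalys[:, 1].mean()),
            "delta_cost": float(self.delta_costs.mean()),
            "delta_qalys": float(self.delta_qalys.mean()),
            "mean_icer": self.mean_icer,
            "mean_inmb": self.mean_inmb,
            "prob_cost_effective": self.prob_cost_effective,
            "ci95": {k: list(v) for k, v in ci.items()},
        }


def ceac(psa: PSAResult, wtp_grid) -> dict[float, float]:
    """Fraction of iterations with positive iNMB at each WTP value."""
    grid = [float(w) for w in wtp_grid]
    if not grid or any(w < 0 for w in grid):
        raise ParameterError("wtp grid must be nonempty with values >= 0")
    dc, de = psa.delta_costs, psa.delta_qalys
    return {w: float(np.mean(w * de - dc > 0.0)) for w in grid}


def run_psa(
    ps: ParameterSet,
    n: int,
    seed: int,
    ps_intervention: ParameterSet | None = None,
    wtp_grid=DEFAULT_WTP_GRID,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` common-random-draw iterations of both arms.

    Each iteration samples every distributed parameter once (both arms see
    the identical draw of shared parameters) and runs the full cohort model
    per arm. Iterations whose draw violates a schema invariant are logged
    and skipped.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    psi = ps_intervention or ps
    children = np.random.SeedSequence(seed).spawn(n)
    costs, qalys, failed = [], [], []
    for i in range(n):
        try:
            drawn_soc = sample_parameters(ps, np.random.default_rng(children[i]))
            if psi is ps:
                drawn_int = drawn_soc
            else:
                drawn_int = sample_parameters(psi, np.random.default_rng(children[i]))
            soc = run_cohort("standard_of_care", drawn_soc)
            itv = run_cohort("ctdna_guided", drawn_int)
        except ParameterError as exc:
            logger.warning("PSA iteration %d skipped: %s", i, exc)
            failed.append(i)
            continue
        costs.append([soc.total_cost_disc, itv.total_cost_disc])
        qalys.append([soc.qalys_disc, itv.qalys_disc])
    if not costs:
        raise ParameterError("every PSA iteration failed")
    return PSAResult(
        seed=seed, wtp=ps.wtp, costs=np.asarray(costs), qalys=np.asarray(qalys),
        wtp_grid=tuple(float(w) for w in wtp_grid), failed_iterations=failed,
    )
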