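"""Cohort state-transition engine on the expanded 25-state space.

The seven clinical health states — first-line ARPI, second-line docetaxel,
third-line cabazitaxel, no-progression-after-docetaxel/-cabazitaxel, best
supportive care (BSC), and death — are expanded to 25 Markov states by giving
each chemotherapy line ten tunnel sub-states (one per administered cycle), so
time-on-chemotherapy is encoded in the state index and per-cycle transition
probabilities can depend on time-in-line (clock reset at line entry).

The cohort is evolved in occupancy fractions by repeated vector–matrix
products. Occupancy is valued at cycle start, with discount factors evaluated
at cycle start (no half-cycle correction); one-off costs attached to a
transition (adverse-event management and diagnostic work-up on entering a
chemotherapy line, the ctDNA assay at the week-4 boundary) are charged to the
flow entering the triggering state and discounted at the arrival boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterError, ParameterSet, SurvivalSpec
from .survival import (
    DAYS_PER_MONTH,
    CycleGrid,
    average_hazard,
    competing_risk_probs,
)

__all__ = [
    "N_STATES",
    "STATE_NAMES",
    "ARPI",
    "DOC_1",
    "DOC_NP",
    "CAB_1",
    "CAB_NP",
    "BSC",
    "DEATH",
    "SubCohort",
    "CohortTrace",
    "ArmResult",
    "CATEGORIES",
    "discount_factor",
    "build_transition_matrix",
    "compile_subcohort",
    "run_subcohort",
    "run_cohort",
]

# --- state space -----------------------------------------------------------

ARPI = 0
DOC_1 = 1          # DOC_1..DOC_10 occupy indices 1..10
DOC_NP = 11
CAB_1 = 12         # CAB_1..CAB_10 occupy indices 12..21
CAB_NP = 22
BSC = 23
DEATH = 24
N_STATES = 25
N_TUNNEL = 10

STATE_NAMES = (
    ["ARPI"]
    + [f"DOC_{i}" for i in range(1, 11)]
    + ["DOC_NP"]
    + [f"CAB_{i}" for i in range(1, 11)]
    + ["CAB_NP", "BSC", "DEATH"]
)

#: cost accounting categories
CATEGORIES = ("drug", "administration", "visits_diagnostics", "adverse_events",
              "ctdna", "bsc")


@dataclass(frozen=True)
class SubCohort:
    """One homogeneous slice of a strategy arm.

    The ARPI health state of a sub-cohort is tied to a single drug (cost and
    utility) and to a pair of survival specs: one for the initial 4-week
    cycle (pre ctDNA read-out) and one thereafter (durable-responder curves
    in the guided arm). ``switch_fraction`` of ARPI stayers is moved to the
    first docetaxel tunnel state at the end of cycle 0; ARPI progression is
    suppressed (mass held in ARPI) for cycles ending on or before
    ``hold_until_day``.
    """

    weight: float
    drug: str
    arpi_pfs_cycle0: SurvivalSpec
    arpi_os_cycle0: SurvivalSpec
    arpi_pfs_later: SurvivalSpec
    arpi_os_later: SurvivalSpec
    hold_until_day: float = 0.0
    switch_fraction: float = 0.0
    charge_assay: bool = False


@dataclass
class CohortTrace:
    """Occupancy at every cycle boundary plus per-cycle valued increments."""

    boundaries: np.ndarray                  # (n_cycles + 1,)
    occupancy: np.ndarray                   # (n_cycles + 1, N_STATES)
    qalys_disc: np.ndarray                  # (n_cycles,)
    costs_disc: np.ndarray                  # (n_cycles, len(CATEGORIES))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_NAMES)
        df.insert(0, "day", self.boundaries)
        return df


@dataclass
class ArmResult:
    """Discounted/undiscounted life-years, QALYs, and costs for one arm."""

    life_years: float
    life_years_disc: float
    qalys: float
    qalys_disc: float
    costs_disc: dict[str, float]
    costs_undisc: dict[str, float]
    trace: CohortTrace
    extras: dict = field(default_factory=dict)

    @property
    def total_cost_disc(self) -> float:
        return float(sum(self.costs_disc.values()))

    @property
    def total_cost_undisc(self) -> float:
        return float(sum(self.costs_undisc.values()))

    def to_dict(self) -> dict:
        """JSON-serializable summary (the full trace is exported as CSV)."""
        return {
            "life_years": self.life_years,
            "life_years_disc": self.life_years_disc,
            "qalys": self.qalys,
            "qalys_disc": self.qalys_disc,
            "costs_disc": dict(self.costs_disc),
            "costs_undisc": dict(self.costs_undisc),
            "total_cost_disc": self.total_cost_disc,
            "total_cost_undisc": self.total_cost_undisc,
            "extras": dict(self.extras),
        }


def discount_factor(days_elapsed: float, annual_rate: float) -> float:
    """Discrete annual discounting, ``(1 + r)^(-t/365.25)``."""
    if days_elapsed < 0 or annual_rate < 0:
        raise ParameterError("days and rate must be >= 0")
    return float((1.0 + annual_rate) ** (-(days_elapsed / 365.25)))


# --- transition matrices ---------------------------------------------------


def _bsc_entry_hazard(ps: ParameterSet) -> float:
    p = ps.bsc_entry_monthly_prob.mean
    if p >= 1.0:
        raise ParameterError("bsc_entry_monthly_prob must be < 1")
    return -np.log1p(-p) / DAYS_PER_MONTH


def _line_hazards(ps: ParameterSet, key: str, t0: float, t1: float) -> tuple[float, float]:
    """(progression, death) daily hazards of a line over time-in-line [t0, t1)."""
    line = ps.lines[key]
    lam_pfs = average_hazard(line.pfs, t0, t1)
    lam_os = average_hazard(line.os, t0, t1)
    if lam_os > lam_pfs + 1e-12:
        raise ParameterError(
            f"lines.{key}: death hazard exceeds PFS event hazard on [{t0:g}, {t1:g}) d"
        )
    return max(lam_pfs - lam_os, 0.0), lam_os


def build_transition_matrix(
    cycle_index: int,
    ps: ParameterSet,
    sub: SubCohort,
    grid: CycleGrid | None = None,
) -> np.ndarray:
    """Row-stochastic 25x25 matrix for one cycle of one sub-cohort.

    Structural zeros (backward transitions, skipped tunnel stages, exits from
    death) are exactly 0; any negative entry raises.
    """
    if grid is None:
        grid = CycleGrid.build(ps.cycle1_days, ps.cycle_days, ps.horizon_years)
    if not 0 <= cycle_index < grid.n_cycles:
        raise ParameterError(f"cycle_index {cycle_index} outside grid")
    b = grid.boundaries
    dt = float(b[cycle_index + 1] - b[cycle_index])
    lam_bsc = _bsc_entry_hazard(ps)
    cd = ps.cycle_days

    P = np.zeros((N_STATES, N_STATES))

    # ARPI row: calendar-time hazards, optional hold and week-4 switch
    pfs = sub.arpi_pfs_cycle0 if cycle_index == 0 else sub.arpi_pfs_later
    osp = sub.arpi_os_cycle0 if cycle_index == 0 else sub.arpi_os_later
    lam_pfs = average_hazard(pfs, b[cycle_index], b[cycle_index + 1])
    lam_os = average_hazard(osp, b[cycle_index], b[cycle_index + 1])
    if lam_os > lam_pfs + 1e-12:
        raise ParameterError("ARPI death hazard exceeds PFS event hazard")
    p_prog, p_death, p_bsc, p_stay = competing_risk_probs(
        [max(lam_pfs - lam_os, 0.0), lam_os, lam_bsc], dt
    )
    if not b[cycle_index + 1] > sub.hold_until_day:
        p_stay += p_prog
        p_prog = 0.0
    if cycle_index == 0 and sub.switch_fraction > 0.0:
        moved = sub.switch_fraction * p_stay
        p_prog += moved
        p_stay -= moved
    P[ARPI, DOC_1] = p_prog
    P[ARPI, DEATH] = p_death
    P[ARPI, BSC] = p_bsc
    P[ARPI, ARPI] = p_stay

    # docetaxel tunnel + no-progression state: time-in-line hazards
    for i in range(N_TUNNEL):
        s = DOC_1 + i
        lam_p, lam_d = _line_hazards(ps, "docetaxel", i * cd, (i + 1) * cd)
        p_p, p_d, p_b, p_s = competing_risk_probs([lam_p, lam_d, lam_bsc], dt)
        nxt = s + 1 if i < N_TUNNEL - 1 else DOC_NP
        P[s, CAB_1] = p_p
        P[s, DEATH] = p_d
        P[s, BSC] = p_b
        P[s, nxt] = p_s
    lam_p, lam_d = _line_hazards(ps, "docetaxel", N_TUNNEL * cd, N_TUNNEL * cd + dt)
    p_p, p_d, p_b, p_s = competing_risk_probs([lam_p, lam_d, lam_bsc], dt)
    P[DOC_NP, CAB_1] = p_p
    P[DOC_NP, DEATH] = p_d
    P[DOC_NP, BSC] = p_b
    P[DOC_NP, DOC_NP] = p_s

    # cabazitaxel tunnel: progression exits to BSC (no fourth active line)
    for i in range(N_TUNNEL):
        s = CAB_1 + i
        lam_p, lam_d = _line_hazards(ps, "cabazitaxel", i * cd, (i + 1) * cd)
        p_p, p_d, p_b, p_s = competing_risk_probs([lam_p, lam_d, lam_bsc], dt)
        nxt = s + 1 if i < N_TUNNEL - 1 else CAB_NP
        P[s, BSC] = p_p + p_b
        P[s, DEATH] = p_d
        P[s, nxt] = p_s
    lam_p, lam_d = _line_hazards(ps, "cabazitaxel", N_TUNNEL * cd, N_TUNNEL * cd + dt)
    p_p, p_d, p_b, p_s = competing_risk_probs([lam_p, lam_d, lam_bsc], dt)
    P[CAB_NP, BSC] = p_p + p_b
    P[CAB_NP, DEATH] = p_d
    P[CAB_NP, CAB_NP] = p_s

    # BSC: death only
    lam_d = average_hazard(ps.lines["bsc"].os, b[cycle_index], b[cycle_index + 1])
    p_d, p_s = competing_risk_probs([lam_d], dt)
    P[BSC, DEATH] = p_d
    P[BSC, BSC] = p_s

    P[DEATH, DEATH] = 1.0

    if np.any(P < 0.0):
        raise ParameterError("negative transition probability after competing-risk split")
    rowsum = P.sum(axis=1)
    if not np.allclose(rowsum, 1.0, rtol=0, atol=1e-12):
        raise ParameterError(f"transition rows do not sum to 1 (max err {abs(rowsum - 1).max():g})")
    return P


# --- compilation and cohort evolution -------------------------------------


@dataclass
class CompiledSubcohort:
    """Everything needed to evolve/value one sub-cohort (shared with the
    individual-level microsimulation oracle)."""

    weight: float
    grid: CycleGrid
    matrices: np.ndarray            # (n_cycles, N_STATES, N_STATES)
    utility: np.ndarray             # (N_STATES,)
    cycle_costs: np.ndarray         # (len(CATEGORIES), N_STATES), per cycle
    entry_costs: np.ndarray         # (len(CATEGORIES), N_STATES), on arrival
    t0_costs: np.ndarray            # (len(CATEGORIES),), at model entry
    assay_amount: float             # EUR per patient alive at boundary 1


def _hazard_series(spec: SurvivalSpec, boundaries: np.ndarray) -> np.ndarray:
    """Per-cycle time-averaged daily hazard over each grid interval."""
    n = len(boundaries) - 1
    if spec.form == "exponential_median":
        return np.full(n, average_hazard(spec, 0.0, 1.0))
    return np.array(
        [average_hazard(spec, boundaries[i], boundaries[i + 1]) for i in range(n)]
    )


def compile_subcohort(ps: ParameterSet, sub: SubCohort) -> CompiledSubcohort:
    grid = CycleGrid.build(ps.cycle1_days, ps.cycle_days, ps.horizon_years)
    n = grid.n_cycles
    b = grid.boundaries
    dts = grid.intervals

    # rows other than ARPI depend only on the interval length: build one
    # template per distinct interval, then overwrite the ARPI row per cycle
    matrices = np.empty((n, N_STATES, N_STATES))
    templates: dict[float, np.ndarray] = {}
    for c in range(n):
        dt = float(dts[c])
        if dt not in templates:
            templates[dt] = build_transition_matrix(c, ps, sub, grid)
        matrices[c] = templates[dt]

    lam_bsc = _bsc_entry_hazard(ps)
    lam_pfs = _hazard_series(sub.arpi_pfs_later, b)
    lam_os = _hazard_series(sub.arpi_os_later, b)
    lam_pfs[0] = average_hazard(sub.arpi_pfs_cycle0, b[0], b[1])
    lam_os[0] = average_hazard(sub.arpi_os_cycle0, b[0], b[1])
    if np.any(lam_os > lam_pfs + 1e-12):
        raise ParameterError("ARPI death hazard exceeds PFS event hazard")
    lam_prog = np.maximum(lam_pfs - lam_os, 0.0)
    total = lam_prog + lam_os + lam_bsc
    p_event = -np.expm1(-total * dts)
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, p_event / np.where(total > 0, total, 1.0), 0.0)
    p_prog = lam_prog * frac
    p_death = lam_os * frac
    p_bsc = lam_bsc * frac
    p_stay = 1.0 - p_event
    held = ~(b[1:] > sub.hold_until_day)
    p_stay = np.where(held, p_stay + p_prog, p_stay)
    p_prog = np.where(held, 0.0, p_prog)
    if sub.switch_fraction > 0.0:
        moved = sub.switch_fraction * p_stay[0]
        p_prog[0] += moved
        p_stay[0] -= moved
    matrices[:, ARPI, :] = 0.0
    matrices[:, ARPI, DOC_1] = p_prog
    matrices[:, ARPI, DEATH] = p_death
    matrices[:, ARPI, BSC] = p_bsc
    matrices[:, ARPI, ARPI] = p_stay

    drug_line = ps.lines[sub.drug]
    doc = ps.lines["docetaxel"]
    cab = ps.lines["cabazitaxel"]
    bsc_line = ps.lines["bsc"]

    u = np.zeros(N_STATES)
    u[ARPI] = drug_line.utility.mean
    u[DOC_1:DOC_NP + 1] = doc.utility.mean
    u[CAB_1:CAB_NP + 1] = cab.utility.mean
    u[BSC] = bsc_line.utility.mean

    cyc = np.zeros((len(CATEGORIES), N_STATES))
    i_drug, i_admin, i_visit, i_ae, i_ctdna, i_bsc = range(len(CATEGORIES))
    cyc[i_drug, ARPI] = drug_line.drug_cost_per_cycle.mean
    cyc[i_admin, ARPI] = drug_line.admin_cost_per_cycle.mean
    cyc[i_drug, DOC_1:DOC_1 + N_TUNNEL] = doc.drug_cost_per_cycle.mean
    cyc[i_admin, DOC_1:DOC_1 + N_TUNNEL] = doc.admin_cost_per_cycle.mean
    cyc[i_drug, CAB_1:CAB_1 + N_TUNNEL] = cab.drug_cost_per_cycle.mean
    cyc[i_admin, CAB_1:CAB_1 + N_TUNNEL] = cab.admin_cost_per_cycle.mean
    visit = ps.visit_cost_per_cycle.mean
    cyc[i_visit, :BSC] = visit                       # every alive on-pathway state
    cyc[i_bsc, BSC] = ps.bsc_cost_per_cycle.mean

    entry = np.zeros((len(CATEGORIES), N_STATES))
    entry[i_ae, DOC_1] = doc.expected_ae_cost()
    entry[i_ae, CAB_1] = cab.expected_ae_cost()
    entry[i_visit, DOC_1] = ps.diagnostic_cost.mean
    entry[i_visit, CAB_1] = ps.diagnostic_cost.mean

    t0 = np.zeros(len(CATEGORIES))
    t0[i_ae] = drug_line.expected_ae_cost()

    assay = (
        ps.ctdna_n_samples * ps.ctdna_cost_per_sample.mean if sub.charge_assay else 0.0
    )
    return CompiledSubcohort(
        weight=sub.weight, grid=grid, matrices=matrices, utility=u,
        cycle_costs=cyc, entry_costs=entry, t0_costs=t0, assay_amount=assay,
    )


def run_subcohort(ps: ParameterSet, comp: CompiledSubcohort) -> ArmResult:
    grid = comp.grid
    n = grid.n_cycles
    b = grid.boundaries
    dt_years = grid.intervals / 365.25
    disc_c = (1.0 + ps.discount_rate_costs) ** (-(b / 365.25))
    disc_e = (1.0 + ps.discount_rate_effects) ** (-(b / 365.25))

    occ = np.zeros((n + 1, N_STATES))
    occ[0, ARPI] = 1.0
    for c in range(n):
        occ[c + 1] = occ[c] @ comp.matrices[c]
    if np.any(occ < -1e-12) or np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-10):
        raise ParameterError("cohort trace lost probability mass")

    alive = 1.0 - occ[:, DEATH]
    start = occ[:-1]                                   # occupancy at cycle starts
    ly = float(alive[:-1] @ dt_years)
    ly_disc = float((alive[:-1] * disc_e[:-1]) @ dt_years)
    q_per_cycle = start @ comp.utility * dt_years
    qalys = float(q_per_cycle.sum())
    q_disc_per_cycle = q_per_cycle * disc_e[:-1]
    qalys_disc = float(q_disc_per_cycle.sum())

    # recurring per-cycle costs, valued at cycle start
    recurring = start @ comp.cycle_costs.T             # (n, n_cat)
    # one-off costs on arrival, valued at the arrival boundary
    arrivals = occ[1:] @ comp.entry_costs.T            # (n, n_cat)
    cost_cycle = recurring * disc_c[:-1, None] + arrivals * disc_c[1:, None]
    cost_cycle_undisc = recurring + arrivals

    cat_disc = cost_cycle.sum(axis=0)
    cat_undisc = cost_cycle_undisc.sum(axis=0)
    cat_disc = cat_disc + comp.t0_costs
    cat_undisc = cat_undisc + comp.t0_costs
    i_ctdna = CATEGORIES.index("ctdna")
    if comp.assay_amount > 0.0:
        alive1 = 1.0 - occ[1, DEATH]
        cat_disc[i_ctdna] += comp.assay_amount * alive1 * disc_c[1]
        cat_undisc[i_ctdna] += comp.assay_amount * alive1
        cost_cycle[0, i_ctdna] += comp.assay_amount * alive1 * disc_c[1]

    trace = CohortTrace(
        boundaries=b.copy(), occupancy=occ,
        qalys_disc=q_disc_per_cycle, costs_disc=cost_cycle,
    )
    res = ArmResult(
        life_years=ly, life_years_disc=ly_disc, qalys=qalys, qalys_disc=qalys_disc,
        costs_disc=dict(zip(CATEGORIES, cat_disc.tolist())),
        costs_undisc=dict(zip(CATEGORIES, cat_undisc.tolist())),
        trace=trace,
    )
    _check_result(res, ps)
    return res


def _check_result(res: ArmResult, ps: ParameterSet) -> None:
    if not (0.0 <= res.qalys <= res.life_years + 1e-9):
        raise ParameterError("QALYs must lie in [0, life-years]")
    if res.life_years > ps.horizon_years + 1e-9:
        raise ParameterError("life-years exceed the horizon")
    if res.qalys_disc > res.qalys + 1e-9 or res.life_years_disc > res.life_years + 1e-9:
        raise ParameterError("discounted outcomes exceed undiscounted")


def _combine(results: list[ArmResult], weights: list[float]) -> ArmResult:
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError("sub-cohort weights must sum to 1")

    def avg(fn):
        return float(sum(wi * fn(r) for wi, r in zip(w, results)))

    trace = CohortTrace(
        boundaries=results[0].trace.boundaries,
        occupancy=sum(wi * r.trace.occupancy for wi, r in zip(w, results)),
        qalys_disc=sum(wi * r.trace.qalys_disc for wi, r in zip(w, results)),
        costs_disc=sum(wi * r.trace.costs_disc for wi, r in zip(w, results)),
    )
    return ArmResult(
        life_years=avg(lambda r: r.life_years),
        life_years_disc=avg(lambda r: r.life_years_disc),
        qalys=avg(lambda r: r.qalys),
        qalys_disc=avg(lambda r: r.qalys_disc),
        costs_disc={k: avg(lambda r: r.costs_disc[k]) for k in CATEGORIES},
        costs_undisc={k: avg(lambda r: r.costs_undisc[k]) for k in CATEGORIES},
        trace=trace,
    )


def run_cohort(arm, ps: ParameterSet) -> ArmResult:
    """Run one strategy arm through the cohort engine.

    ``arm`` may be a :class:`~ctdna_cea.strategies.StrategyArm` or one of the
    labels ``"standard_of_care"`` / ``"ctdna_guided"``.
    """
    if isinstance(arm, str):
        from .strategies import build_arm

        arm = build_arm(arm, ps)
    results = [run_subcohort(ps, compile_subcohort(ps, s)) for s in arm.subcohorts]
    combined = _combine(results, [s.weight for s in arm.subcohorts])
    combined.extras.update(arm.reporting_extras(ps))
    return combined
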