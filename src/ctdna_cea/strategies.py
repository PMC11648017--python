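"""The two comparator arms as cohort-splitting rules over the Markov engine.

Standard of care: patients start first-line ARPI (abiraterone or enzalutamide,
mixed by ``arpi_abi_share``) and can switch to docetaxel on progression, but
no earlier than the first cycle boundary at or after six months (day 196 on
the 28 + 21k grid) — earlier progression mass is held in the ARPI state.

ctDNA-guided: every patient is tested (baseline + week-4 + one germline
control sample); at the day-28 boundary a fraction ``ctdna_flag_fraction`` of
ARPI survivors — the test-positive, predicted non-durable responders — moves
straight to docetaxel. The remaining cohort is predicted durable and follows
durable-responder PFS/OS thereafter. Among switchers, ``ctdna_ppv`` are true
non-durable responders; false positives receive the same docetaxel outcome
curves (no separate data exist), the split is retained for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterError, ParameterSet
from .markov import SubCohort

__all__ = ["SIX_MONTHS_DAYS", "StrategyArm", "build_soc_arm", "build_ctdna_arm", "build_arm"]

#: six months in days (365.25 / 2); the hold releases at the first cycle
#: boundary strictly after this.
SIX_MONTHS_DAYS = 182.625


@dataclass(frozen=True)
class StrategyArm:
    """A labelled list of weighted sub-cohorts driving the cohort engine."""

    label: str
    subcohorts: tuple[SubCohort, ...]

    def __post_init__(self) -> None:
        total = sum(s.weight for s in self.subcohorts)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"sub-cohort weights must sum to 1, got {total}")

    def reporting_extras(self, ps: ParameterSet) -> dict:
        if self.label != "ctdna_guided":
            return {"label": self.label}
        flag = ps.ctdna_flag_fraction.mean
        ppv = ps.ctdna_ppv.mean
        return {
            "label": self.label,
            "flag_fraction": flag,
            "true_positive_switch_fraction": flag * ppv,
            "false_positive_switch_fraction": flag * (1.0 - ppv),
        }


def _arpi_drugs(ps: ParameterSet) -> list[tuple[str, float]]:
    share = ps.arpi_abi_share
    drugs = []
    if share > 0.0:
        drugs.append(("abiraterone", share))
    if share < 1.0:
        drugs.append(("enzalutamide", 1.0 - share))
    return drugs


def build_soc_arm(ps: ParameterSet) -> StrategyArm:
    """Standard of care: trial ARPI curves, six-month earliest switch."""
    subs = tuple(
        SubCohort(
            weight=w,
            drug=drug,
            arpi_pfs_cycle0=ps.lines[drug].pfs,
            arpi_os_cycle0=ps.lines[drug].os,
            arpi_pfs_later=ps.lines[drug].pfs,
            arpi_os_later=ps.lines[drug].os,
            hold_until_day=SIX_MONTHS_DAYS,
            switch_fraction=0.0,
            charge_assay=False,
        )
        for drug, w in _arpi_drugs(ps)
    )
    return StrategyArm(label="standard_of_care", subcohorts=subs)


def build_ctdna_arm(ps: ParameterSet) -> StrategyArm:
    """ctDNA-guided arm: week-4 switch of flagged patients, durable curves.

    During the initial 4-week cycle both arms behave identically (trial
    curves, progression held). At day 28, ``ctdna_flag_fraction`` of ARPI
    survivors moves to the first docetaxel tunnel state; the rest follows
    durable-responder PFS/OS — without the six-month hold unless
    ``durable_six_month_hold`` is set. The assay cost
    (``ctdna_n_samples x ctdna_cost_per_sample``) is charged once to every
    patient alive at the day-28 boundary.
    """
    flag = ps.ctdna_flag_fraction.mean
    ppv = ps.ctdna_ppv.mean
    if not 0.0 <= flag <= 1.0 or not 0.0 <= ppv <= 1.0:
        raise ParameterError("ctdna_flag_fraction and ctdna_ppv must lie in [0, 1]")
    durable_key = None if ps.durable_curves_equal_trial else "arpi_durable_responder"
    hold = SIX_MONTHS_DAYS if ps.durable_six_month_hold else ps.cycle1_days
    subs = tuple(
        SubCohort(
            weight=w,
            drug=drug,
            arpi_pfs_cycle0=ps.lines[drug].pfs,
            arpi_os_cycle0=ps.lines[drug].os,
            arpi_pfs_later=ps.lines[durable_key or drug].pfs,
            arpi_os_later=ps.lines[durable_key or drug].os,
            hold_until_day=hold,
            switch_fraction=flag,
            charge_assay=True,
        )
        for drug, w in _arpi_drugs(ps)
    )
    return StrategyArm(label="ctdna_guided", subcohorts=subs)


def build_arm(label: str, ps: ParameterSet) -> StrategyArm:
    if label == "standard_of_care":
        return build_soc_arm(ps)
    if label == "ctdna_guided":
        return build_ctdna_arm(ps)
    raise ParameterError(
        f"unknown strategy label {label!r}; expected 'standard_of_care' or 'ctdna_guided'"
    )
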