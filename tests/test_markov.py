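import math

import numpy as np
import pytest

from ctdna_cea.markov import (
    ARPI,
    BSC,
    CAB_1,
    CAB_NP,
    DEATH,
    DOC_1,
    DOC_NP,
    N_STATES,
    build_transition_matrix,
    compile_subcohort,
    discount_factor,
    run_cohort,
)
from ctdna_cea.parameters import ParameterError, ParameterSet
from ctdna_cea.strategies import build_ctdna_arm, build_soc_arm
from ctdna_cea.survival import CycleGrid, cause_specific_cycle_probs, median_to_rate

from conftest import strip_uncertainty


def _soc_sub(ps):
    return build_soc_arm(ps).subcohorts[0]


def _toy_absorbing_ps(base_ps, median_months=12.0) -> ParameterSet:
    """ARPI -> DEATH only: pfs == os (no progression), no supportive care."""
    d = strip_uncertainty(base_ps).model_dump()
    for key in ("abiraterone", "enzalutamide"):
        d["lines"][key]["pfs"] = {"form": "exponential_median", "median": median_months}
        d["lines"][key]["os"] = {"form": "exponential_median", "median": median_months}
    d["lines"]["arpi_durable_responder"]["pfs"] = {
        "form": "exponential_median", "median": median_months}
    d["lines"]["arpi_durable_responder"]["os"] = {
        "form": "exponential_median", "median": median_months}
    d["bsc_entry_monthly_prob"] = 0.0
    return ParameterSet.model_validate(d)


class TestDiscounting:
    def test_time_zero(self):
        assert discount_factor(0.0, 0.04) == 1.0

    def test_one_year_definition(self):
        assert discount_factor(365.25, 0.04) == pytest.approx(1 / 1.04, rel=1e-12)

    def test_five_year_effects_rate(self):
        assert discount_factor(1826.25, 0.015) == pytest.approx(1.015**-5, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            discount_factor(-1.0, 0.04)
        with pytest.raises(ParameterError):
            discount_factor(1.0, -0.04)


class TestTransitionMatrix:
    def test_rows_sum_to_one_every_cycle(self, base_ps):
        grid = CycleGrid.build()
        for arm in (build_soc_arm(base_ps), build_ctdna_arm(base_ps)):
            for sub in arm.subcohorts:
                comp = compile_subcohort(base_ps, sub)
                assert np.allclose(comp.matrices.sum(axis=2), 1.0, atol=1e-12)
                assert comp.matrices.min() >= 0.0
                assert comp.matrices.shape == (grid.n_cycles, N_STATES, N_STATES)

    def test_death_row_is_unit_vector(self, base_ps):
        P = build_transition_matrix(5, base_ps, _soc_sub(base_ps))
        expected = np.zeros(N_STATES)
        expected[DEATH] = 1.0
        assert np.array_equal(P[DEATH], expected)

    def test_structural_zeros(self, base_ps):
        P = build_transition_matrix(20, base_ps, _soc_sub(base_ps))
        # no backward transitions into ARPI
        assert np.all(P[ARPI + 1:, ARPI] == 0.0)
        # tunnel states advance one stage only
        for i in range(9):
            s = DOC_1 + i
            allowed = {s + 1, CAB_1, BSC, DEATH}
            assert set(np.nonzero(P[s])[0]) <= allowed
        assert set(np.nonzero(P[DOC_1 + 9])[0]) <= {DOC_NP, CAB_1, BSC, DEATH}
        for i in range(9):
            s = CAB_1 + i
            assert set(np.nonzero(P[s])[0]) <= {s + 1, BSC, DEATH}
        assert set(np.nonzero(P[CAB_1 + 9])[0]) <= {CAB_NP, BSC, DEATH}
        assert set(np.nonzero(P[BSC])[0]) <= {BSC, DEATH}

    def test_zero_hazard_structure(self, base_ps):
        """With all hazards 0 the matrix is the identity except tunnel advance."""
        d = strip_uncertainty(base_ps).model_dump()
        for line in d["lines"].values():
            line["pfs"] = {"form": "exponential_median", "median": 1e12}
            line["os"] = {"form": "exponential_median", "median": 1e12}
        d["bsc_entry_monthly_prob"] = 0.0
        ps = ParameterSet.model_validate(d)
        P = build_transition_matrix(30, ps, _soc_sub(ps))
        expected = np.eye(N_STATES)
        for i in range(10):
            s = DOC_1 + i
            expected[s, s] = 0.0
            expected[s, s + 1 if i < 9 else DOC_NP] = 1.0
            s = CAB_1 + i
            expected[s, s] = 0.0
            expected[s, s + 1 if i < 9 else CAB_NP] = 1.0
        assert np.allclose(P, expected, atol=1e-9)

    def test_arpi_row_matches_competing_risk_oracle(self, fixed_ps):
        """Cross-module check: the ARPI row of a post-hold cycle equals the
        two-risk split composed with the supportive-care hazard."""
        sub = _soc_sub(fixed_ps)
        c = 40  # well past the six-month hold
        P = build_transition_matrix(c, fixed_ps, sub)
        line = fixed_ps.lines[sub.drug]
        lam_pfs = median_to_rate(line.pfs.median)
        lam_os = median_to_rate(line.os.median)
        lam_bsc = -math.log1p(-fixed_ps.bsc_entry_monthly_prob.mean) / (365.25 / 12)
        lam_tot = lam_pfs + lam_bsc
        p_event = 1 - math.exp(-lam_tot * 21.0)
        assert P[ARPI, DOC_1] == pytest.approx(p_event * (lam_pfs - lam_os) / lam_tot, rel=1e-10)
        assert P[ARPI, DEATH] == pytest.approx(p_event * lam_os / lam_tot, rel=1e-10)
        assert P[ARPI, BSC] == pytest.approx(p_event * lam_bsc / lam_tot, rel=1e-10)
        # and the pure two-risk split is recovered when the BSC hazard is off
        d = fixed_ps.model_dump()
        d["bsc_entry_monthly_prob"] = 0.0
        ps0 = ParameterSet.model_validate(d)
        P0 = build_transition_matrix(c, ps0, _soc_sub(ps0))
        p_prog, p_death, p_stay = cause_specific_cycle_probs(lam_pfs, lam_os, 21.0)
        assert P0[ARPI, DOC_1] == pytest.approx(p_prog, rel=1e-12)
        assert P0[ARPI, DEATH] == pytest.approx(p_death, rel=1e-12)
        assert P0[ARPI, ARPI] == pytest.approx(p_stay, rel=1e-12)


class TestCohortRun:
    def test_trace_conservation_and_death_monotone(self, base_ps):
        for label in ("standard_of_care", "ctdna_guided"):
            res = run_cohort(label, base_ps)
            occ = res.trace.occupancy
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-12)
            assert occ.min() >= -1e-15 and occ.max() <= 1.0 + 1e-12
            assert np.all(np.diff(occ[:, DEATH]) >= -1e-15)

    def test_toy_closed_form_life_years(self, base_ps):
        """Absorbing two-state chain: survival at each boundary is the
        exponential exactly, so life-years are a closed-form sum."""
        ps = _toy_absorbing_ps(base_ps, median_months=12.0)
        res = run_cohort("standard_of_care", ps)
        grid = CycleGrid.build()
        lam = median_to_rate(12.0)
        expected_ly = sum(
            math.exp(-lam * grid.boundaries[c]) * float(grid.intervals[c]) / 365.25
            for c in range(grid.n_cycles)
        )
        assert res.life_years == pytest.approx(expected_ly, rel=1e-9)
        occ = res.trace.occupancy
        assert np.allclose(
            occ[:, ARPI], np.exp(-lam * grid.boundaries), rtol=1e-9
        )

    def test_unit_utility_identity(self, base_ps):
        d = strip_uncertainty(base_ps).model_dump()
        for line in d["lines"].values():
            line["utility"] = 1.0
        ps = ParameterSet.model_validate(d)
        for label in ("standard_of_care", "ctdna_guided"):
            res = run_cohort(label, ps)
            assert res.qalys == pytest.approx(res.life_years, rel=1e-12)
            assert res.qalys_disc == pytest.approx(res.life_years_disc, rel=1e-12)

    def test_zero_discount_identity(self, base_ps):
        d = strip_uncertainty(base_ps).model_dump()
        d["discount_rate_costs"] = 0.0
        d["discount_rate_effects"] = 0.0
        ps = ParameterSet.model_validate(d)
        res = run_cohort("ctdna_guided", ps)
        assert res.qalys_disc == pytest.approx(res.qalys, rel=1e-12)
        assert res.life_years_disc == pytest.approx(res.life_years, rel=1e-12)
        assert res.total_cost_disc == pytest.approx(res.total_cost_undisc, rel=1e-12)

    def test_result_orderings(self, base_ps):
        res = run_cohort("standard_of_care", base_ps)
        assert 0 < res.qalys <= res.life_years <= base_ps.horizon_years
        assert res.qalys_disc <= res.qalys
        assert res.life_years_disc <= res.life_years
        assert res.total_cost_disc <= res.total_cost_undisc

    def test_monotone_harm_of_death_hazard(self, fixed_ps):
        """Shorter OS anywhere weakly decreases life-years and QALYs."""
        base = run_cohort("standard_of_care", fixed_ps)
        d = fixed_ps.model_dump()
        d["lines"]["docetaxel"]["os"]["median"] = 12.0  # down from 24.3
        worse = run_cohort("standard_of_care", ParameterSet.model_validate(d))
        assert worse.life_years < base.life_years
        assert worse.qalys < base.qalys

    def test_tunnel_integrity(self, base_ps):
        """No mass can reach the post-docetaxel state before 10 tunnel cycles,
        and cabazitaxel is entered only from docetaxel-family states."""
        res = run_cohort("ctdna_guided", base_ps)
        occ = res.trace.occupancy
        # earliest docetaxel entry is boundary 1 (day 28): DOC_NP needs 10 more
        assert np.all(occ[:11, DOC_NP] == 0.0)
        assert np.all(occ[:2, CAB_1] == 0.0)
        soc = run_cohort("standard_of_care", base_ps)
        # SOC: docetaxel starts at day 196 (boundary 9) at the earliest
        assert np.all(soc.trace.occupancy[:9, DOC_1:CAB_NP + 1] == 0.0)

    def test_cost_categories_complete(self, base_ps):
        res = run_cohort("ctdna_guided", base_ps)
        assert set(res.costs_disc) == {
            "drug", "administration", "visits_diagnostics", "adverse_events",
            "ctdna", "bsc",
        }
        assert res.costs_disc["ctdna"] > 0.0
        soc = run_cohort("standard_of_care", base_ps)
        assert soc.costs_disc["ctdna"] == 0.0

    def test_trace_frame_layout(self, base_ps):
        df = run_cohort("standard_of_care", base_ps).trace.to_frame()
        assert list(df.columns)[:2] == ["day", "ARPI"]
        assert len(df) == CycleGrid.build().n_cycles + 1

    def test_arm_result_json_serializable(self, base_ps):
        import json

        d = run_cohort("ctdna_guided", base_ps).to_dict()
        assert json.loads(json.dumps(d))["total_cost_disc"] == d["total_cost_disc"]
        assert "ctdna" in d["costs_disc"]

    def test_unknown_label_rejected(self, base_ps):
        with pytest.raises(ParameterError, match="unknown strategy"):
            run_cohort("nonsense", base_ps)
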