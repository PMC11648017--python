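import math

import numpy as np
import pytest

from ctdna_cea.economics import run_deterministic
from ctdna_cea.markov import (
    ARPI,
    BSC,
    DEATH,
    DOC_1,
    compile_subcohort,
    run_cohort,
)
from ctdna_cea.parameters import ParameterError, ParameterSet
from ctdna_cea.strategies import SIX_MONTHS_DAYS, build_ctdna_arm, build_soc_arm
from ctdna_cea.survival import CycleGrid, competing_risk_probs, median_to_rate

from conftest import strip_uncertainty


def _with(ps, **updates) -> ParameterSet:
    d = ps.model_dump()
    for key, value in updates.items():
        d[key] = value
    return ParameterSet.model_validate(d)


class TestArmConstruction:
    def test_soc_mixture_weights(self, base_ps):
        arm = build_soc_arm(base_ps)
        assert [s.drug for s in arm.subcohorts] == ["abiraterone", "enzalutamide"]
        assert [s.weight for s in arm.subcohorts] == [0.5, 0.5]

    def test_degenerate_share_single_subcohort(self, base_ps):
        arm = build_soc_arm(_with(base_ps, arpi_abi_share=1.0))
        assert len(arm.subcohorts) == 1
        assert arm.subcohorts[0].drug == "abiraterone"

    def test_soc_has_no_switch_and_no_assay(self, base_ps):
        for sub in build_soc_arm(base_ps).subcohorts:
            assert sub.switch_fraction == 0.0
            assert not sub.charge_assay
            assert sub.hold_until_day == SIX_MONTHS_DAYS

    def test_six_month_boundary_is_day_196(self):
        grid = CycleGrid.build()
        b = grid.boundaries
        first_allowed = b[np.argmax(b >= SIX_MONTHS_DAYS)]
        assert first_allowed == 196.0

    def test_no_docetaxel_flow_before_six_months_in_soc(self, base_ps):
        occ = run_cohort("standard_of_care", base_ps).trace.occupancy
        grid = CycleGrid.build()
        before = grid.boundaries < 182.6
        assert np.all(occ[before, DOC_1] == 0.0)

    def test_ppv_reported_not_structural(self, base_ps):
        """PPV splits switchers for reporting; outcome curves are shared."""
        res = run_cohort("ctdna_guided", base_ps)
        flag = base_ps.ctdna_flag_fraction.mean
        ppv = base_ps.ctdna_ppv.mean
        assert res.extras["true_positive_switch_fraction"] == pytest.approx(flag * ppv)
        assert res.extras["false_positive_switch_fraction"] == pytest.approx(
            flag * (1 - ppv)
        )
        other = run_cohort("ctdna_guided", _with(base_ps, ctdna_ppv=0.65))
        assert other.qalys_disc == pytest.approx(res.qalys_disc, rel=1e-12)


class TestSwitchMechanics:
    def test_doc1_occupancy_after_cycle_one_hand_product(self, fixed_ps):
        """One-step product: DOC_1 mass at day 28 = flag x P(stay in ARPI)."""
        arm = build_ctdna_arm(fixed_ps)
        sub = arm.subcohorts[0]
        comp = compile_subcohort(fixed_ps, sub)
        occ1 = np.zeros(25)
        occ1[ARPI] = 1.0
        occ1 = occ1 @ comp.matrices[0]
        line = fixed_ps.lines[sub.drug]
        lam_pfs = median_to_rate(line.pfs.median)
        lam_os = median_to_rate(line.os.median)
        lam_bsc = -math.log1p(-fixed_ps.bsc_entry_monthly_prob.mean) / (365.25 / 12)
        p = competing_risk_probs([lam_pfs - lam_os, lam_os, lam_bsc], 28.0)
        p_stay_held = p[3] + p[0]  # progression held during cycle 0
        flag = fixed_ps.ctdna_flag_fraction.mean
        assert occ1[DOC_1] == pytest.approx(flag * p_stay_held, rel=1e-12)
        assert occ1[ARPI] == pytest.approx((1 - flag) * p_stay_held, rel=1e-12)

    def test_flag_zero_reduces_to_soc_with_durable_curves(self, fixed_ps):
        """flag = 0 & durable==trial & hold: the guided arm differs from SOC
        only by the assay cost; QALYs match exactly."""
        d = fixed_ps.model_dump()
        d["ctdna_flag_fraction"] = 0.0
        d["durable_curves_equal_trial"] = True
        d["durable_six_month_hold"] = True
        ps = ParameterSet.model_validate(d)
        res = run_deterministic(ps)
        assert res.delta_qalys == pytest.approx(0.0, abs=1e-12)
        alive1 = 1.0 - res.intervention.trace.occupancy[1, DEATH]
        disc1 = (1 + ps.discount_rate_costs) ** (-28.0 / 365.25)
        assert res.delta_cost == pytest.approx(
            ps.ctdna_n_samples * ps.ctdna_cost_per_sample.mean * alive1 * disc1,
            rel=1e-10,
        )

    def test_assay_cost_contribution(self, fixed_ps):
        """ctDNA category total = 3 x 350 x alive(day 28) x cycle-1 discount."""
        res = run_cohort("ctdna_guided", fixed_ps)
        alive1 = 1.0 - res.trace.occupancy[1, DEATH]
        disc1 = (1 + fixed_ps.discount_rate_costs) ** (-28.0 / 365.25)
        assert res.costs_disc["ctdna"] == pytest.approx(
            3 * 350.0 * alive1 * disc1, rel=1e-10
        )
        assert alive1 > 0.95  # nearly everyone survives the first 4 weeks


class TestMixtureProperties:
    def test_results_affine_in_abi_share(self, fixed_ps):
        runs = {}
        for share in (0.0, 0.5, 1.0):
            runs[share] = run_deterministic(_with(fixed_ps, arpi_abi_share=share))
        for attr in ("delta_cost", "delta_qalys", "inmb"):
            mid = getattr(runs[0.5], attr)
            avg = 0.5 * (getattr(runs[0.0], attr) + getattr(runs[1.0], attr))
            assert mid == pytest.approx(avg, rel=1e-9, abs=1e-9)

    def test_arm_totals_at_half_share_equal_mixture(self, fixed_ps):
        lo = run_cohort("standard_of_care", _with(fixed_ps, arpi_abi_share=0.0))
        hi = run_cohort("standard_of_care", _with(fixed_ps, arpi_abi_share=1.0))
        mid = run_cohort("standard_of_care", fixed_ps)
        assert mid.qalys_disc == pytest.approx(
            0.5 * (lo.qalys_disc + hi.qalys_disc), rel=1e-12
        )
        assert mid.total_cost_disc == pytest.approx(
            0.5 * (lo.total_cost_disc + hi.total_cost_disc), rel=1e-12
        )

    def test_inmb_linear_in_ctdna_price(self, fixed_ps):
        """Exact slope: -n_samples x alive(day 28) x cycle-1 cost discount."""
        from ctdna_cea.owsa import set_parameter

        prices = (100.0, 225.0, 350.0)
        inmbs = [
            run_deterministic(set_parameter(fixed_ps, "ctdna_cost_per_sample", p)).inmb
            for p in prices
        ]
        res = run_cohort("ctdna_guided", fixed_ps)
        alive1 = 1.0 - res.trace.occupancy[1, DEATH]
        disc1 = (1 + fixed_ps.discount_rate_costs) ** (-28.0 / 365.25)
        slope = -fixed_ps.ctdna_n_samples * alive1 * disc1
        assert inmbs[2] - inmbs[0] == pytest.approx(slope * 250.0, rel=1e-9)
        assert inmbs[1] == pytest.approx(0.5 * (inmbs[0] + inmbs[2]), rel=1e-9)


class TestArmsShareEverythingElse:
    def test_matrix_sequences_differ_only_in_arpi_row(self, base_ps):
        """Diff of the generated transition-matrix sequences: the arms may
        differ only in the ARPI row (switch rule + durable curves)."""
        soc = build_soc_arm(base_ps)
        guided = build_ctdna_arm(base_ps)
        for s_sub, g_sub in zip(soc.subcohorts, guided.subcohorts):
            assert s_sub.drug == g_sub.drug
            M_s = compile_subcohort(base_ps, s_sub).matrices
            M_g = compile_subcohort(base_ps, g_sub).matrices
            non_arpi = [i for i in range(25) if i != ARPI]
            assert np.array_equal(M_s[:, non_arpi, :], M_g[:, non_arpi, :])
            assert not np.array_equal(M_s[:, ARPI, :], M_g[:, ARPI, :])

    def test_invalid_flag_fraction_rejected(self, base_ps):
        d = base_ps.model_dump()
        d["ctdna_flag_fraction"] = 1.4
        with pytest.raises(ValueError):
            ParameterSet.model_validate(d)
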