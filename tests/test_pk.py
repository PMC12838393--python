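"""Dialyzer-clearance submodel and Runge-Kutta-Gill integrator."""

import numpy as np
import pytest

from helpers import adaptive_conc, bisect_koa, expm_conc
from vancohd.pk import (
    DoseEvent,
    HDSession,
    HDSettings,
    IndividualPKParams,
    InfeasibleMembraneError,
    dialyzer_clearance,
    dialyzer_forward_clearance,
    dialyzer_koa,
    simulate_profile,
    terminal_rate_constant,
    total_clearance,
    validate_sessions,
)

PARAMS = IndividualPKParams(cl_body=0.45, v1=14.4, q=6.5, v2=38.0)


class TestDialyzerKoa:
    def test_roundtrip_identity(self):
        koa = dialyzer_koa(120.0, 200.0, 500.0)
        assert dialyzer_forward_clearance(koa, 200.0, 500.0) == pytest.approx(
            120.0, rel=1e-8
        )

    def test_equal_flow_limit_roundtrip(self):
        koa = dialyzer_koa(90.0, 300.0, 300.0)
        # analytic inversion of CL = Qb*KoA/(Qb+KoA)
        assert koa == pytest.approx(90.0 * 300.0 / (300.0 - 90.0), rel=1e-8)

    def test_matches_bisection_oracle(self):
        koa = dialyzer_koa(100.0, 200.0, 500.0)
        oracle = bisect_koa(100.0, 200.0, 500.0, dialyzer_forward_clearance)
        assert koa == pytest.approx(oracle, abs=1e-6)

    def test_flow_limited_bound(self):
        assert dialyzer_forward_clearance(1e12, 200.0, 500.0) == pytest.approx(200.0)
        assert dialyzer_forward_clearance(1e12, 500.0, 200.0) == pytest.approx(200.0)

    @pytest.mark.parametrize("cl", [200.0, 250.0])
    def test_infeasible_baseline_rejected(self, cl):
        with pytest.raises(InfeasibleMembraneError):
            dialyzer_koa(cl, 200.0, 500.0)


class TestDialyzerClearance:
    def test_identity_at_reference_conditions(self):
        s = HDSettings(q_blood=200.0, q_dialysate=500.0, q_uf=0.0,
                       cl_b12_baseline=130.0)
        assert dialyzer_clearance(s) == pytest.approx(130.0 * 0.06, rel=1e-10)

    def test_formula_oracle_at_cohort_mean_flow(self):
        # independent two-formula evaluation at the actual flows
        s = HDSettings(q_blood=174.6, q_dialysate=500.0, q_uf=10.0,
                       cl_b12_baseline=100.0)
        koa = bisect_koa(100.0, 200.0, 500.0, dialyzer_forward_clearance)
        z = (koa / 174.6) * (1.0 - 174.6 / 500.0)
        cl_diff = 174.6 * np.expm1(z) / (np.exp(z) - 174.6 / 500.0)
        expected = (cl_diff + 10.0 * (1.0 - cl_diff / 174.6)) * 0.06
        assert dialyzer_clearance(s) == pytest.approx(expected, rel=1e-6)

    def test_zero_blood_flow_is_off(self):
        s = HDSettings(q_blood=0.0, q_dialysate=500.0, cl_b12_baseline=130.0)
        assert dialyzer_clearance(s) == 0.0

    @pytest.mark.parametrize(
        "field,lo,hi",
        [("q_blood", 120.0, 220.0), ("q_dialysate", 300.0, 700.0),
         ("q_uf", 0.0, 20.0), ("cl_b12_baseline", 90.0, 150.0)],
    )
    def test_monotone_nondecreasing(self, field, lo, hi):
        base = dict(q_blood=174.6, q_dialysate=500.0, q_uf=10.0,
                    cl_b12_baseline=130.0)
        values = [
            dialyzer_clearance(HDSettings(**{**base, field: x}))
            for x in np.linspace(lo, hi, 7)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_bounded_by_flows(self, settings):
        cl = dialyzer_clearance(settings)
        assert 0 < cl < (min(settings.q_blood, settings.q_dialysate) + settings.q_uf) * 0.06

    def test_mw_interpolation_below_b12_surrogate(self, settings):
        interp = settings.model_copy(update={"use_mw_interpolation": True})
        # vancomycin is heavier than B12, so log-MW extrapolation lowers KoA
        assert dialyzer_clearance(interp) < dialyzer_clearance(settings)


class TestTotalClearance:
    def test_gating(self, settings):
        sessions = [HDSession(start=39.3, duration=3.5)]
        cl_hd = dialyzer_clearance(settings)
        assert total_clearance(10.0, PARAMS, sessions, settings) == PARAMS.cl_body
        assert total_clearance(39.3, PARAMS, sessions, settings) == pytest.approx(
            PARAMS.cl_body + cl_hd
        )  # half-open inclusion at start
        assert total_clearance(42.8, PARAMS, sessions, settings) == PARAMS.cl_body

    def test_piecewise_constant_integral(self, settings):
        sessions = [HDSession(start=10.0, duration=3.0),
                    HDSession(start=30.0, duration=4.0)]
        cl_hd = dialyzer_clearance(settings)
        ts = np.linspace(0.0, 40.0, 400001)
        numeric = np.trapezoid(
            [total_clearance(t, PARAMS, sessions, settings) for t in ts], ts
        )
        overlap = 3.0 + 4.0
        expected = PARAMS.cl_body * 40.0 + cl_hd * overlap
        assert numeric == pytest.approx(expected, rel=1e-4)


class TestIntegrator:
    def test_no_doses_identically_zero(self):
        prof = simulate_profile([], PARAMS, t_end=24.0, step=0.1)
        assert np.all(prof.conc == 0.0)

    def test_one_compartment_infusion_closed_form(self):
        p = IndividualPKParams(cl_body=0.9, v1=15.0, q=1e-9, v2=38.0)
        dose = DoseEvent(time=0.0, amount=1000.0, t_inf=0.01)
        prof = simulate_profile([dose], p, t_end=24.0, step=0.01)
        k = p.cl_body / p.v1
        tau = dose.t_inf
        for t in (1.0, 6.0, 12.0, 24.0):
            exact = (dose.amount / (tau * p.cl_body)) * (
                1 - np.exp(-k * tau)
            ) * np.exp(-k * (t - tau))
            assert prof.value_at(t) == pytest.approx(exact, rel=1e-3)

    def test_matches_adaptive_oracle_full_scenario(self, hd_scenario):
        doses, sessions, settings = hd_scenario
        prof = simulate_profile(doses, PARAMS, sessions, settings,
                                t_end=90.8, step=0.05)
        mask = prof.grid >= 2.0  # skip the ramp-up where conc is tiny
        oracle = adaptive_conc(doses, PARAMS, sessions, settings, prof.grid[mask])
        rel = np.abs(prof.conc[mask] - oracle) / np.maximum(oracle, 1e-12)
        assert rel.max() < 0.005

    def test_fourth_order_convergence(self):
        dose = DoseEvent(time=0.0, amount=1000.0, t_inf=1.0)
        exact = expm_conc(dose, PARAMS, 10.0)
        errs = []
        for step in (0.5, 0.25):
            prof = simulate_profile([dose], PARAMS, t_end=10.0, step=step)
            errs.append(abs(prof.value_at(10.0) - exact))
        assert errs[0] / errs[1] > 8.0  # consistent with O(h^4)

    def test_mass_conservation_without_clearance(self):
        p = IndividualPKParams(cl_body=1e-12, v1=14.4, q=6.5, v2=38.0)
        dose = DoseEvent(time=0.0, amount=1500.0, t_inf=1.0)
        prof = simulate_profile([dose], p, t_end=48.0, step=0.05)
        total = prof.a1[-1] + prof.a2[-1]
        assert total == pytest.approx(1500.0, rel=1e-4)

    def test_auc_infinity_equals_dose_over_clearance(self):
        p = IndividualPKParams(cl_body=3.0, v1=14.4, q=6.5, v2=38.0)
        doses = [DoseEvent(time=0.0, amount=1000.0, t_inf=1.0),
                 DoseEvent(time=24.0, amount=500.0, t_inf=1.0)]
        lam = terminal_rate_constant(p)
        t_end = 24.0 + 12.0 / lam
        prof = simulate_profile(doses, p, t_end=t_end, step=0.05)
        auc = np.trapezoid(prof.conc, prof.grid) + prof.conc[-1] / lam
        assert auc == pytest.approx(1500.0 / p.cl_body, rel=1e-3)

    def test_grid_alignment_on_events(self, hd_scenario):
        doses, sessions, settings = hd_scenario
        prof = simulate_profile(doses, PARAMS, sessions, settings,
                                t_end=90.8, step=0.05)
        for t in (1.0, 39.3, 42.8, 43.8, 87.3):
            assert np.min(np.abs(prof.grid - t)) < 1e-9

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            IndividualPKParams(cl_body=-1.0, v1=14.4, q=6.5, v2=38.0)

    def test_overlapping_sessions_rejected(self):
        with pytest.raises(ValueError):
            validate_sessions([HDSession(start=0.0, duration=4.0),
                               HDSession(start=3.0, duration=3.0)])
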