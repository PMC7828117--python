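import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nanomsc_pkpd.model import (
    kill_rates,
    observed_lung_concentration,
    observed_plasma_concentration,
    radius_from_volume,
    rhs_nanomsc,
    rhs_pkpd,
    rhs_ptx_plga,
    rhs_ptx_solution,
    tumor_exchange_flux,
    volume_from_bioluminescence,
)
from nanomsc_pkpd.params import BioluminescenceCalibration, TumorGeometry


def biexponential_central(t, dose, CL, CLD, Vc, Vp):
    """Independent two-compartment oracle: central amount after an IV bolus
    with first-order elimination, from the classic alpha/beta macro rates."""
    k10, k12, k21 = CL / Vc, CLD / Vc, CLD / Vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    return dose * ((alpha - k21) * np.exp(-alpha * t)
                   - (beta - k21) * np.exp(-beta * t)) / (alpha - beta)


class TestExchangeFlux:
    def test_equilibrium_gives_zero_flux(self, params):
        geom = params.geometry
        assert tumor_exchange_flux(100.0, 100.0 * params.ptx.E, params.ptx,
                                   geom) == pytest.approx(0.0, abs=1e-9)

    def test_magnitude_at_published_constants(self, params):
        # direct arithmetic: [2*0.0875*0.0075/0.0008^2 + 6*0.01/0.42^2]
        #   * 0.3 * (100*0.44 - 0) ~ 2.708e4 ng/h
        geom = TumorGeometry(VT=0.3, Rtumor=0.42)
        flux = tumor_exchange_flux(100.0, 0.0, params.ptx, geom)
        assert flux == pytest.approx(2.708e4, rel=2e-3)

    @given(scale=st.floats(0.1, 10.0), cc=st.floats(0.0, 1e4),
           ct=st.floats(0.0, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_tumor_volume(self, scale, cc, ct):
        from nanomsc_pkpd.params import paper_2021
        p = paper_2021()
        geom = TumorGeometry(VT=0.3, Rtumor=0.42)
        geom2 = dataclasses.replace(geom, VT=0.3 * scale)  # radii fixed
        f1 = tumor_exchange_flux(cc, ct, p.ptx, geom)
        f2 = tumor_exchange_flux(cc, ct, p.ptx, geom2)
        assert f2 == pytest.approx(scale * f1, rel=1e-12, abs=1e-9)

    def test_nonfinite_and_degenerate_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            tumor_exchange_flux(float("nan"), 0.0, params.ptx, params.geometry)
        # zero radii are rejected as soon as the geometry is built
        with pytest.raises(ValueError):
            dataclasses.replace(params.geometry, Rtumor=0.0)
        with pytest.raises(ValueError):
            dataclasses.replace(params.geometry, RKrogh=0.0)


class TestLayerReductions:
    def test_zero_state_zero_derivative(self, params):
        assert np.allclose(rhs_ptx_solution(np.zeros(3), params.ptx,
                                            params.geometry), 0.0)
        assert np.allclose(rhs_nanomsc(np.zeros(9), params.np_, params.ptx,
                                       params.msc, params.transfer,
                                       params.geometry), 0.0)

    def test_two_compartment_biexponential_oracle(self, params):
        # with P = D = 0 the free layer reduces to a two-compartment model
        p = dataclasses.replace(params.ptx, P=1e-30, D=1e-30)
        dose = 5000.0

        def rhs(t, y):
            return rhs_ptx_solution(y, p, params.geometry)

        ts = np.linspace(0.0, 288.0, 30)
        sol = solve_ivp(rhs, (0, 288), [dose, 0.0, 0.0], t_eval=ts,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        expected = biexponential_central(ts, dose, p.CL, p.CLD, p.Vc, p.Vp)
        assert np.allclose(sol.y[0], expected, rtol=1e-6)

    def test_conservation_without_elimination(self, params):
        p = dataclasses.replace(params.ptx, CL=1e-30)

        def rhs(t, y):
            return rhs_ptx_solution(y, p, params.geometry)

        sol = solve_ivp(rhs, (0, 500), [1000.0, 0.0, 0.0], method="LSODA",
                        rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y.sum(axis=0), 1000.0, rtol=1e-8)

    def test_np_layer_decouples_when_release_off(self, params):
        tr = dataclasses.replace(params.transfer, Krel=1e-30)
        state = np.array([0.0, 0.0, 0.0, 800.0, 50.0, 20.0])
        d6 = rhs_ptx_plga(state, params.np_, params.ptx, tr, params.geometry)
        d3 = rhs_ptx_solution(state[3:], params.np_, params.geometry)
        assert np.allclose(d6[3:], d3, rtol=1e-12)
        assert np.allclose(d6[:3], 0.0, atol=1e-12)

    def test_first_order_transfer_closed_form(self, params):
        # exchange and distribution off, no elimination: free central grows
        # as Dose*(1-exp(-Krel*t))
        off = dict(P=1e-30, D=1e-30, CLD=1e-30, CL=1e-30)
        pP = dataclasses.replace(params.ptx, **off)
        pN = dataclasses.replace(params.np_, **off)
        dose, krel = 1000.0, params.transfer.Krel

        def rhs(t, y):
            return rhs_ptx_plga(y, pN, pP, params.transfer, params.geometry)

        ts = np.linspace(0, 400, 21)
        sol = solve_ivp(rhs, (0, 400), [0, 0, 0, dose, 0, 0], t_eval=ts,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[0], dose * (1 - np.exp(-krel * ts)), rtol=1e-7,
                           atol=1e-8)

    def test_msc_central_lumped_exponential(self, params):
        # published rates lump to 1.45 + 10.2 + 0.0085 + 0.081 per hour
        lam = 1.45 + 10.2 + 0.0085 + 0.081
        dose = 5000.0

        def rhs(t, y):
            return rhs_nanomsc(y, params.np_, params.ptx, params.msc,
                               params.transfer, params.geometry)

        y0 = np.zeros(9)
        y0[6] = dose
        ts = np.linspace(0, 2, 9)
        sol = solve_ivp(rhs, (0, 2), y0, t_eval=ts, method="LSODA",
                        rtol=1e-11, atol=1e-13)
        assert np.allclose(sol.y[6], dose * np.exp(-lam * ts), rtol=1e-6)

    def test_nine_compartment_conservation(self, params):
        p = params.with_(ptx=dataclasses.replace(params.ptx, CL=1e-30),
                         np_=dataclasses.replace(params.np_, CL=1e-30))

        def rhs(t, y):
            return rhs_nanomsc(y, p.np_, p.ptx, p.msc, p.transfer, p.geometry)

        y0 = np.zeros(9)
        y0[6] = 5000.0
        sol = solve_ivp(rhs, (0, 1000), y0, method="LSODA", rtol=1e-10,
                        atol=1e-12)
        assert np.allclose(sol.y.sum(axis=0), 5000.0, rtol=1e-7)


class TestKillRates:
    def test_zero_concentrations(self, params):
        assert kill_rates(0.0, 0.0, 0.0, params.pd) == (0.0, 0.0, 0.0)

    def test_half_maximal_at_ic50(self, params):
        kp, _, _ = kill_rates(params.pd.IC50_PTX, 0.0, 0.0, params.pd)
        assert kp == pytest.approx(params.pd.Kmax_PTX / 2.0, rel=1e-12)

    def test_linear_cell_form_kill(self, params):
        _, _, km = kill_rates(0.0, 0.0, 1000.0, params.pd)
        assert km == pytest.approx(4.35e-3, rel=1e-10)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            kill_rates(-1.0, 0.0, 0.0, params.pd)


class TestCoupledSystem:
    def test_untreated_growth_closed_form(self, params_dyn):
        state = np.zeros(10)
        state[9] = 0.360
        d = rhs_pkpd(0.0, state, params_dyn, arm="control")
        assert d[9] == pytest.approx(0.00339 * 0.360, rel=1e-12)
        # closed form at t=100 h
        assert 0.360 * math.exp(0.00339 * 100.0) == pytest.approx(0.5053, abs=5e-5)

    def test_stasis_when_kill_equals_growth(self, params_dyn):
        pdp = params_dyn.pd
        # pick the tumor free-PTX concentration at which the Emax kill
        # exactly equals the control growth rate
        c = pdp.IC50_PTX * pdp.Kg0["control"] / (pdp.Kmax_PTX - pdp.Kg0["control"])
        state = np.zeros(10)
        state[9] = 1.0
        VT = params_dyn.calibration.volume(1.0)
        state[1] = c * VT
        d = rhs_pkpd(0.0, state, params_dyn, arm="control")
        assert d[9] == pytest.approx(0.0, abs=1e-12)

    def test_static_geometry_reproduces_pk_rhs(self, params):
        state = np.zeros(10)
        state[:9] = [10, 5, 1, 200, 30, 8, 500, 100, 900]
        state[9] = 2.0
        d = rhs_pkpd(0.0, state, params, arm="nano_msc")
        dpk = rhs_nanomsc(state[:9], params.np_, params.ptx, params.msc,
                          params.transfer, params.geometry)
        assert np.allclose(d[:9], dpk, rtol=1e-12)

    def test_nonpositive_burden_rejected(self, params_dyn):
        state = np.zeros(10)
        state[9] = -1.0
        with pytest.raises(ValueError):
            rhs_pkpd(0.0, state, params_dyn)


class TestGeometryMaps:
    def test_volume_map_identity_and_constant(self):
        assert volume_from_bioluminescence(3.7, BioluminescenceCalibration(1, 1)) == 3.7
        assert volume_from_bioluminescence(3.7, BioluminescenceCalibration(2, 0)) == 2.0
        with pytest.raises(ValueError):
            volume_from_bioluminescence(0.0, BioluminescenceCalibration(1, 1))

    def test_sphere_radius(self):
        assert radius_from_volume(4.0 * math.pi / 3.0) == pytest.approx(1.0)
        assert round(radius_from_volume(0.3), 2) == 0.42
        assert radius_from_volume(8.0) == pytest.approx(2 * radius_from_volume(1.0))
        with pytest.raises(ValueError):
            radius_from_volume(0.0)


class TestObservationModel:
    def test_zero_state(self, params):
        assert observed_plasma_concentration(np.zeros(9), params.ptx,
                                             params.np_, params.msc,
                                             "nano_msc") == 0.0
        assert observed_lung_concentration(np.zeros(9), params.geometry) == 0.0

    def test_solution_arm_plasma_scaling(self, params):
        state = np.zeros(9)
        state[0] = 6640.0
        c = observed_plasma_concentration(state, params.ptx, params.np_,
                                          params.msc, "ptx_solution")
        assert c == pytest.approx(23.7, rel=1e-3)
        # NP/MSC compartments do not contribute to the solution arm
        state[3] = state[6] = 1e6
        assert observed_plasma_concentration(state, params.ptx, params.np_,
                                             params.msc, "ptx_solution") == c

    def test_lung_concentration_additivity(self, params):
        state = np.zeros(9)
        state[1] = state[4] = state[7] = 30.0
        assert observed_lung_concentration(state, params.geometry) == \
            pytest.approx(300.0, rel=1e-12)
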