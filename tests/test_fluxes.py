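"""Flux kernels: channel, pump, cotransporters, OSOR and the assembled balance.

The reference numbers come from the steady-state closure of the published
resting-cell parameter columns: at the printed membrane potential every
ion's pathway fluxes must sum to zero, which pins each kernel value.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pumpleak import (
    InfeasibleParameterError,
    MembraneParams,
    UndefinedPotentialError,
    channel_flux,
    charge_flux,
    cotransporter_fluxes,
    electrochemical_potentials,
    osor,
    preset,
    pump_fluxes,
    reference_column,
    total_fluxes,
)
from pumpleak.fluxes import IONS, PATHWAYS

from conftest import ALL_COLUMNS

U_A = -45.2 / 26.7  # dimensionless resting potential, cell A full set


class TestChannelFlux:
    @pytest.mark.parametrize(
        "kind, p, c_in, c_out, net_ref",
        [
            ("cation", 0.0019, 35.0, 140.0, 0.5263),   # Na, cell A
            ("cation", 0.01, 156.0, 5.8, -0.4760),     # K, cell A
            ("anion", 0.004, 70.0, 116.0, -0.4046),    # Cl, cell A
        ],
    )
    def test_resting_cell_kernels(self, kind, p, c_in, c_out, net_ref):
        influx, efflux, net = channel_flux(kind, p, U_A, c_in, c_out)
        assert influx >= 0 and efflux >= 0
        assert net == pytest.approx(influx - efflux, abs=1e-15)
        assert net == pytest.approx(net_ref, abs=2e-3)

    def test_k_unidirectional_influx(self):
        influx, _, _ = channel_flux("cation", 0.01, U_A, 156.0, 5.8)
        assert influx == pytest.approx(0.1205, abs=2e-3)

    @pytest.mark.parametrize("kind", ["cation", "anion"])
    def test_zero_potential_equal_concentrations(self, kind):
        assert channel_flux(kind, 0.0, 0.01, 100.0, 100.0)[2] == 0.0

    @pytest.mark.parametrize("kind", ["cation", "anion"])
    @pytest.mark.parametrize("u", [0.0, 1e-6, -1e-6])
    def test_small_potential_matches_fick_limit(self, kind, u):
        p, c_in, c_out = 0.01, 156.0, 5.8
        _, _, net = channel_flux(kind, p, u, c_in, c_out)
        assert net == pytest.approx(p * (c_out - c_in), rel=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.floats(1e-5, 0.1),
        c_out=st.floats(1.0, 200.0),
        u=st.floats(-6.0, 6.0),
    )
    def test_nernst_equilibrium_zero_net(self, p, c_out, u):
        """Net flux vanishes exactly at the ion's Nernst potential."""
        _, _, net_cat = channel_flux("cation", p, u, c_out * math.exp(-u), c_out)
        _, _, net_an = channel_flux("anion", p, u, c_out * math.exp(u), c_out)
        scale = p * c_out
        assert abs(net_cat) < 1e-10 * scale
        assert abs(net_an) < 1e-10 * scale

    @settings(derandomize=True, max_examples=80)
    @given(
        c_in=st.floats(1.0, 300.0),
        c_out=st.floats(1.0, 300.0),
        u=st.floats(-5.0, 5.0),
    )
    def test_net_flux_runs_down_the_gradient(self, c_in, c_out, u):
        """Channel net flux opposes the sign of the electrochemical gradient."""
        mu_cat = math.log(c_in / c_out) + u       # cation gradient (RT units)
        mu_an = math.log(c_in / c_out) - u        # anion (valence -1)
        _, _, net_cat = channel_flux("cation", 0.01, u, c_in, c_out)
        _, _, net_an = channel_flux("anion", 0.01, u, c_in, c_out)
        assert net_cat * mu_cat <= 1e-15
        assert net_an * mu_an <= 1e-15


class TestCotransporters:
    def test_cell_a_full_set_values(self, standard_medium):
        params = MembraneParams(p_na=0, p_k=0, p_cl=0, beta=0.039,
                                inc=7e-5, ikc=3e-5, inkcc=8e-9)
        j_nc, j_kc, j_nkcc = cotransporter_fluxes(
            params, (35.0, 156.0, 70.0), standard_medium)
        assert j_nc == pytest.approx(0.9653, abs=1e-4)
        assert j_kc == pytest.approx(-0.3074, abs=1e-4)
        assert j_nkcc == pytest.approx(-0.1266, abs=1e-4)

    def test_product_equilibrium_is_zero(self, standard_medium):
        # inside products equal to outside products -> no net transport
        params = MembraneParams(p_na=0, p_k=0, p_cl=0, beta=0.039,
                                inc=7e-5, ikc=3e-5, inkcc=8e-9)
        conc = (standard_medium.na_o, standard_medium.k_o, standard_medium.cl_o)
        assert cotransporter_fluxes(params, conc, standard_medium) == (0.0, 0.0, 0.0)

    def test_zero_coefficients(self, standard_medium):
        params = MembraneParams(p_na=0, p_k=0, p_cl=0, beta=0.039)
        assert cotransporter_fluxes(
            params, (35.0, 156.0, 70.0), standard_medium) == (0.0, 0.0, 0.0)


class TestPump:
    def test_resting_cell_fluxes(self):
        assert pump_fluxes(0.039, 35.0, 1.5) == pytest.approx((1.365, 0.91))

    def test_blocked_pump(self):
        assert pump_fluxes(0.0, 35.0, 1.5) == (0.0, 0.0)

    def test_fully_decayed_pump(self):
        assert pump_fluxes(0.039, 35.0, 1.5, t=1.0, kb=0.039) == (0.0, 0.0)

    def test_partial_decay(self):
        na_eff, k_in = pump_fluxes(0.04, 35.0, 1.5, t=0.5, kb=0.04)
        assert na_eff == pytest.approx(0.02 * 35.0)
        assert k_in == pytest.approx(0.02 * 35.0 / 1.5)


class TestElectrochemicalPotentials:
    def test_cell_a_full_set(self, standard_medium):
        mu = electrochemical_potentials((35.0, 156.0, 70.0), standard_medium, -45.2)
        assert mu == pytest.approx((-82.2, 42.7, 31.7), abs=0.1)

    def test_cell_b_full_set(self, standard_medium):
        mu = electrochemical_potentials((38.0, 147.0, 45.0), standard_medium, -45.0)
        assert mu[0] == pytest.approx(-79.9, abs=0.1)

    def test_all_zero_at_equilibrium(self, standard_medium):
        conc = (standard_medium.na_o, standard_medium.k_o, standard_medium.cl_o)
        assert electrochemical_potentials(conc, standard_medium, 0.0) == (0, 0, 0)

    def test_zero_concentration_rejected(self, standard_medium):
        with pytest.raises(UndefinedPotentialError):
            electrochemical_potentials((0.0, 156.0, 70.0), standard_medium, -45.2)


class TestOsor:
    def test_nc_only_reproduces_measurement(self, standard_medium):
        state, params, _ = preset("A", "NC")
        assert osor(state, params, standard_medium, -50.5) == pytest.approx(
            3.06, abs=0.01)

    def test_full_set_value(self, standard_medium):
        state, params, _ = preset("A", "NC+KC+NKCC")
        assert osor(state, params, standard_medium, -45.2) == pytest.approx(
            3.99, abs=0.01)

    def test_blocked_pump_is_undefined(self, standard_medium):
        state, params, _ = preset("A", "NC")
        blocked = MembraneParams(p_na=params.p_na, p_k=params.p_k,
                                 p_cl=params.p_cl, beta=0.0, inc=params.inc)
        with pytest.raises(InfeasibleParameterError):
            osor(state, blocked, standard_medium, -50.5)


class TestTotalFluxes:
    @pytest.mark.parametrize("cell,variant", ALL_COLUMNS)
    def test_published_columns_close_the_balance(self, cell, variant):
        """Every printed parameter column is a flux steady state (< 1% residual)."""
        state, params, medium = preset(cell, variant)
        row = reference_column(cell, variant)
        fb = total_fluxes(state, params, medium, row.U / 26.7)
        scale = fb.max_unidirectional()
        for ion in IONS:
            assert abs(fb.ion_total(ion)) < 0.01 * scale

    def test_net_is_influx_minus_efflux_exactly(self, cell_a_full, row_a_full):
        state, params, medium = cell_a_full
        fb = total_fluxes(state, params, medium, row_a_full.U / 26.7)
        for key, (influx, efflux) in fb.entries.items():
            assert fb.net(*key) == influx - efflux

    def test_pathways_not_carrying_an_ion_are_zero(self, cell_a_full, row_a_full):
        state, params, medium = cell_a_full
        fb = total_fluxes(state, params, medium, row_a_full.U / 26.7)
        for pathway, ion in [("NC", "K"), ("KC", "Na"), ("Pump", "Cl")]:
            assert fb.entries[(pathway, ion)] == (0.0, 0.0)

    def test_blocking_pump_unbalances_sodium(self, cell_a_full, row_a_full):
        state, params, medium = cell_a_full
        import dataclasses

        blocked = dataclasses.replace(params, beta=0.0)
        fb = total_fluxes(state, blocked, medium, row_a_full.U / 26.7)
        # the vanished pump efflux beta*[Na]i = 1.365 reappears as net influx
        assert fb.ion_total("Na") == pytest.approx(1.365, abs=1e-6)

    def test_all_zero_params_gives_all_zero_breakdown(self, standard_medium):
        from pumpleak import CellState

        state = CellState.from_concentrations(35.0, 156.0, 70.0, 49.0, -2.47)
        params = MembraneParams(p_na=0, p_k=0, p_cl=0, beta=0.0, gamma=1.5)
        fb = total_fluxes(state, params, standard_medium, -1.0)
        assert all(pair == (0.0, 0.0) for pair in fb.entries.values())


class TestChargeFlux:
    def test_zero_at_resting_potential(self, cell_a_full, row_a_full):
        state, params, medium = cell_a_full
        assert abs(charge_flux(state, params, medium, row_a_full.U / 26.7)) < 1e-12

    def test_cotransporters_carry_no_charge(self, standard_medium):
        from pumpleak import CellState

        state = CellState.from_concentrations(35.0, 156.0, 70.0, 49.0, -2.47)
        params = MembraneParams(p_na=0, p_k=0, p_cl=0, beta=0.0,
                                inc=7e-5, ikc=3e-5, inkcc=8e-9)
        for u in (-3.0, -1.0, 0.0, 2.0):
            assert charge_flux(state, params, medium=standard_medium, u=u) == 0.0

    def test_depolarization_reverses_charge_flow(self, cell_a_full):
        # at u = 0 the cation influx advantage of the resting potential is
        # lost and the net charge flux turns negative
        state, params, medium = cell_a_full
        assert charge_flux(state, params, medium, 0.0) < 0.0

    def test_breakdown_and_direct_kernel_agree(self, cell_b_full):
        state, params, medium = cell_b_full
        for u in (-2.5, -1.0, 0.5):
            fb = total_fluxes(state, params, medium, u)
            assert fb.charge_flux == pytest.approx(
                charge_flux(state, params, medium, u), abs=1e-12)
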