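"""Unit and property tests for the model algebra."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import anoxwave as aw
from anoxwave.model import STATE_FIELDS, steady_state_gating

from _oracle import derivatives_array

VGRID = np.linspace(-100.0, 40.0, 561)


def _state(**kw):
    base = dict(V=-68.0, h=0.98, n=0.07, Na_i=20.0, Na_o=144.0,
                K_i=139.0, K_o=3.8, Cl_i=6.0, Cl_o=130.0)
    base.update(kw)
    return aw.NeuronState(**base)


def _table2_state():
    _, h, n = steady_state_gating(-68.0)
    return _state(h=h, n=n)


class TestNernst:
    def test_symmetry_gives_zero(self):
        assert aw.nernst_potential(1, 10.0, 10.0, 310.0) == 0.0

    @pytest.mark.parametrize("z,c_in,c_out,expected", [
        (+1, 20.0, 144.0, 52.8),    # sodium gradient at body temperature
        (-1, 6.0, 130.0, -82.2),    # chloride: sign flips with valence
    ])
    def test_closed_form_values(self, z, c_in, c_out, expected):
        assert aw.nernst_potential(z, c_in, c_out, 310.0) == pytest.approx(expected, abs=0.1)

    def test_error_names_the_ion(self):
        with pytest.raises(aw.InvalidStateError, match="K"):
            aw.nernst_potential(1, -1.0, 4.0, 310.0, ion="K")

    def test_bad_valence_rejected(self):
        with pytest.raises(ValueError):
            aw.nernst_potential(2, 1.0, 1.0, 310.0)

    @given(st.floats(0.1, 500.0), st.floats(0.1, 500.0))
    def test_sign_follows_gradient(self, c_in, c_out):
        e = aw.nernst_potential(1, c_in, c_out, 310.0)
        assert np.sign(e) == np.sign(np.log(c_out / c_in))


class TestGating:
    def test_alpha_m_singularity_limit(self):
        am = aw.gating_rates(-30.0)[0]
        assert am == pytest.approx(1.0, abs=1e-9)
        # continuity across the removable singularity
        near = [aw.gating_rates(-30.0 + d)[0] for d in (-1e-5, 1e-5)]
        assert near == pytest.approx([am, am], abs=1e-5)

    def test_alpha_n_singularity_limit(self):
        an = aw.gating_rates(-34.0)[4]
        assert an == pytest.approx(0.1, abs=1e-9)

    def test_activation_monotone_and_saturating(self):
        m_inf, h_inf, _ = steady_state_gating(VGRID)
        assert np.all(np.diff(m_inf) > 0)
        assert m_inf[VGRID == -100.0] < 0.01
        assert m_inf[VGRID == 40.0] > 0.95
        assert np.all(np.diff(h_inf) < 0)  # inactivation closes with depolarization

    @given(st.floats(-200.0, 150.0))
    def test_rates_nonnegative(self, V):
        assert min(aw.gating_rates(V)) >= 0.0


class TestMembraneCurrents:
    def test_zero_driving_force(self, params):
        # concentration ratios tuned so every Nernst potential equals V
        VT = params.thermal_voltage_mV
        V = VT * np.log(2.0)
        s = _state(V=V, Na_i=72.0, Na_o=144.0, K_i=72.0, K_o=144.0,
                   Cl_i=144.0, Cl_o=72.0)
        fb = aw.membrane_currents(s, params)
        assert fb.I_Na == pytest.approx(0.0, abs=1e-12)
        assert fb.I_K == pytest.approx(0.0, abs=1e-12)
        assert fb.I_Cl == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_nearly_stationary(self, params):
        # the published steady-state values, rounded, leave |dV/dt| < 0.01 mV/ms
        d = aw.rhs_physiological(0.0, _table2_state(), params)
        assert abs(d[0]) < 0.01

    def test_raising_K_o_lowers_outward_K_current(self, params):
        s1, s2 = _table2_state(), _table2_state()
        s2.K_o *= 2
        f1 = aw.membrane_currents(s1, params)
        f2 = aw.membrane_currents(s2, params)
        assert f2.E_K > f1.E_K
        assert f2.I_K < f1.I_K

    def test_m_inf_bounded(self, params, random_states):
        for y in random_states[:50]:
            fb = aw.membrane_currents(aw.NeuronState.from_array(y), params)
            assert 0.0 <= fb.m_inf <= 1.0


class TestHomeostasis:
    def test_no_diffusion_at_bath_concentration(self, params):
        _, _, diff = aw.homeostasis_fluxes(_state(K_o=params.k_bath), params)
        assert diff == 0.0

    def test_pump_monotone_in_substrates(self, params):
        pumps_na = [aw.homeostasis_fluxes(_state(Na_i=c), params)[0]
                    for c in np.linspace(5, 60, 12)]
        pumps_ko = [aw.homeostasis_fluxes(_state(K_o=c), params)[0]
                    for c in np.linspace(1, 30, 12)]
        assert np.all(np.diff(pumps_na) > 0)
        assert np.all(np.diff(pumps_ko) > 0)

    def test_pump_starves_without_substrate(self, params):
        pump, _, _ = aw.homeostasis_fluxes(_state(Na_i=1e-6, K_o=1e-6), params)
        assert pump < 1e-3

    def test_fluxes_nonnegative(self, params, random_states):
        for y in random_states[:100]:
            pump, glia, _ = aw.homeostasis_fluxes(aw.NeuronState.from_array(y), params)
            assert pump >= 0.0
            assert glia >= 0.0


class TestRightHandSides:
    def test_matches_independent_oracle(self, params, random_states):
        pdict = dataclasses.asdict(params)
        for ogd in (False, True):
            rhs = aw.rhs_ogd if ogd else aw.rhs_physiological
            for y in random_states:
                got = rhs(0.0, aw.NeuronState.from_array(y), params)
                want = derivatives_array(y, pdict, ogd)
                np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-18)

    def test_total_sodium_conserved_in_both_modes(self, params, random_states):
        for rhs in (aw.rhs_physiological, aw.rhs_ogd):
            for y in random_states[:100]:
                d = rhs(0.0, aw.NeuronState.from_array(y), params)
                assert d[3] + d[4] / params.beta == pytest.approx(0.0, abs=1e-18)

    def test_ogd_conserves_potassium_and_chloride(self, params, random_states):
        iK_i, iK_o = STATE_FIELDS.index("K_i"), STATE_FIELDS.index("K_o")
        iCl_i, iCl_o = STATE_FIELDS.index("Cl_i"), STATE_FIELDS.index("Cl_o")
        for y in random_states[:100]:
            d = aw.rhs_ogd(0.0, aw.NeuronState.from_array(y), params)
            assert d[iK_i] + d[iK_o] / params.beta == pytest.approx(0.0, abs=1e-18)
            assert d[iCl_i] + d[iCl_o] / params.beta == pytest.approx(0.0, abs=1e-18)

    def test_chloride_clamped_under_physiology(self, params, random_states):
        for y in random_states[:100]:
            d = aw.rhs_physiological(0.0, aw.NeuronState.from_array(y), params)
            assert d[7] == 0.0 and d[8] == 0.0

    def test_energy_failure_releases_potassium(self, params):
        # without the pump, potassium leaks out from the start ...
        d = aw.rhs_ogd(0.0, _table2_state(), params)
        assert d[STATE_FIELDS.index("K_o")] > 0.0

    def test_energy_failure_depolarizes_within_a_second(self, params, rest_state):
        # ... and the membrane is measurably depolarized within a second
        tr = aw.run_ogd(aw.ModelParameters(), rest_state, 1.0)
        assert tr.V[-1] > tr.V[0] + 0.1

    def test_invalid_state_rejected(self, params):
        with pytest.raises(aw.InvalidStateError, match="h"):
            aw.rhs_physiological(0.0, _state(h=1.2), params)
        with pytest.raises(aw.InvalidStateError, match="Na_i"):
            aw.rhs_ogd(0.0, _state(Na_i=-5.0), params)


class TestParameters:
    def test_defaults_are_the_published_set(self):
        p = aw.ModelParameters()
        assert (p.C_m, p.g_Na, p.g_NaL, p.g_K, p.g_KL, p.g_ClL) == \
            (1.0, 100.0, 0.0175, 40.0, 0.05, 0.05)
        assert (p.phi, p.gamma, p.beta, p.rho) == (3.0, 0.044, 2.0, 28.1)
        assert (p.G_glia, p.eps, p.k_bath, p.T) == (66.0, 1.3, 4.0, 310.0)

    @pytest.mark.parametrize("field", ["C_m", "g_Na", "rho", "T", "beta"])
    def test_nonpositive_values_rejected(self, field):
        with pytest.raises(aw.InvalidParameterError, match=field):
            aw.ModelParameters(**{field: -1.0})
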