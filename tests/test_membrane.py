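"""Channel kinetics, calcium pool, Nernst reversal and the cable integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from retisim import membrane as mb
from retisim.morphology import segmentize

from conftest import A, S, T, build_cell


class TestGatingL:
    def test_alpha_removable_singularity(self):
        a, *_ = mb.gating_rates_L(63.0, "printed")
        assert a == pytest.approx(0.427 * 10.5, rel=1e-12)
        # continuous around the singularity
        a_eps, *_ = mb.gating_rates_L(63.0 + 1e-7, "printed")
        assert a_eps == pytest.approx(a, rel=1e-6)

    def test_hinf_half_at_zero(self):
        assert mb.gating_rates_L(0.0, "printed")[2] == pytest.approx(0.5)
        assert mb.gating_rates_L(0.0, "shifted")[2] == pytest.approx(0.5)

    def test_tau_h_constant(self):
        for v in (-100.0, -53.0, 0.0, 80.0):
            assert mb.gating_rates_L(v, "printed")[3] == 292.0

    def test_shifted_convention_closed_at_rest_open_depolarized(self):
        a, b, *_ = mb.gating_rates_L(-53.0, "shifted")
        assert a / (a + b) < 0.05
        a, b, *_ = mb.gating_rates_L(30.0, "shifted")
        assert a / (a + b) > 0.5

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            mb.gating_rates_L(0.0, "garbled")


class TestGatingT:
    def test_tau_h_at_80mV(self):
        *_, th = mb.gating_rates_T(80.0, "printed")
        assert th == pytest.approx(65.82 + 0.0023, rel=1e-12)

    def test_minf_half_activation(self):
        assert mb.gating_rates_T(37.55, "printed")[0] == pytest.approx(0.5)
        assert mb.gating_rates_T(-37.55, "shifted")[0] == pytest.approx(0.5)

    def test_tau_m_at_midpoint(self):
        _, tm, *_ = mb.gating_rates_T(39.96, "printed")
        assert tm == pytest.approx(1.36 + 21.68 / 2, rel=1e-12)

    def test_shifted_low_threshold(self):
        minf, *_ = mb.gating_rates_T(-53.0, "shifted")
        assert 0 < minf < 0.05
        minf_dep, *_ = mb.gating_rates_T(-20.0, "shifted")
        assert minf_dep > 0.9


class TestChannelCurrent:
    def test_closed_gate_no_current(self):
        p = mb.CaChannelParams("L")
        assert mb.channel_current(0.0, 1.0, -30.0, 120.0, p) == 0.0

    def test_reversal_potential(self):
        p = mb.CaChannelParams("T")
        assert mb.channel_current(0.5, 0.5, 120.0, 120.0, p) == 0.0

    def test_unit_arithmetic(self):
        p = mb.CaChannelParams("L", g_max=0.1)
        i = mb.channel_current(1.0, 1.0, 0.0, 100.0, p)
        assert i == pytest.approx(-0.01)  # mA/cm², inward

    def test_gating_exponents_differ(self):
        pl = mb.CaChannelParams("L")
        pt = mb.CaChannelParams("T")
        il = mb.channel_current(0.5, 1.0, 0.0, 100.0, pl)
        it = mb.channel_current(0.5, 1.0, 0.0, 100.0, pt)
        assert il == pytest.approx(0.5 * it)  # m²h vs mh


class TestNernst:
    def test_zero_at_equal_concentrations(self):
        assert mb.nernst_eca(1.8, 1.8) == 0.0

    def test_resting_value(self):
        assert mb.nernst_eca(1.0e-4, 1.8, 22.0) == pytest.approx(124.6, abs=0.05)

    def test_logarithm_law(self):
        base = mb.nernst_eca(1e-4, 1.8, 22.0)
        doubled = mb.nernst_eca(1e-4, 3.6, 22.0)
        rt2f = 1e3 * mb.GAS_CONSTANT * 295.15 / (2 * mb.FARADAY)
        assert doubled - base == pytest.approx(rt2f * np.log(2), rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mb.nernst_eca(0.0, 1.8)


class TestCaPool:
    def test_rest_is_fixed_point(self):
        pool = mb.CaPoolParams()
        out = mb.update_ca_pool(pool.ca_i_rest, 0.0, 0.01, pool)
        assert out == pytest.approx(pool.ca_i_rest, rel=1e-12)

    def test_relaxation_time_constant(self):
        pool = mb.CaPoolParams()
        dt = 1e-4
        c = 2 * pool.ca_i_rest
        for _ in range(int(round(pool.tau / dt))):  # integrate one τ
            c = mb.update_ca_pool(c, 0.0, dt, pool)
        expected = pool.ca_i_rest * (1 + np.exp(-1.0))
        assert c == pytest.approx(expected, rel=1e-3)

    def test_steady_state_balance(self):
        """Constant inward current: [Ca]ss = rest + τ·|i|/(2 F depth)."""
        pool = mb.CaPoolParams()
        i = -0.01  # mA/cm², inward
        c = pool.ca_i_rest
        for _ in range(5000):
            c = mb.update_ca_pool(c, i, 0.05, pool)
        depth_cm = pool.depth * 1e-4
        expected = pool.ca_i_rest + pool.tau * abs(i) / (2 * mb.FARADAY * depth_cm)
        assert c == pytest.approx(expected, rel=1e-9)

    def test_dt_validated(self):
        with pytest.raises(ValueError):
            mb.update_ca_pool(1e-4, 0.0, 0.0, mb.CaPoolParams())


class TestGateRelaxation:
    """Exponential-Euler gate updates follow the closed form exactly."""

    @pytest.mark.parametrize("kind,v", [("L", -20.0), ("L", 10.0),
                                        ("T", -40.0), ("T", -10.0)])
    def test_fixed_voltage_relaxation(self, kind, v):
        dt = 0.01
        if kind == "L":
            a, b, hinf, th = mb.gating_rates_L(v, "shifted")
            tau = 1.0 / (a + b)
            minf = a * tau
        else:
            minf, tau, hinf, th = mb.gating_rates_T(v, "shifted")
        m = 0.9
        m0 = m
        for k in range(1, 201):
            m = minf + (m - minf) * np.exp(-dt / tau)
            closed = minf + (m0 - minf) * np.exp(-k * dt / tau)
            assert abs(m - closed) < 1e-6

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-150.0, 150.0), min_size=1, max_size=50))
    def test_gates_stay_in_unit_interval(self, voltages):
        m, h = 0.5, 0.5
        for v in voltages:
            a, b, hinf, th = mb.gating_rates_L(v, "shifted")
            tau = 1.0 / (a + b)
            m = a * tau + (m - a * tau) * np.exp(-0.01 / tau)
            h = hinf + (h - hinf) * np.exp(-0.01 / th)
            assert 0.0 <= m <= 1.0 and 0.0 <= h <= 1.0


def two_comp_cell():
    """Soma sphere (10 μm) plus one 10 × 2 μm axon cylinder."""
    return build_cell([(S, 0, 0, 0, 10.0, -1), (A, 0, 0, -10, 2.0, 0)])


class TestCableIntegrator:
    def test_two_compartment_passive_matches_closed_form(self):
        """Backward Euler vs the matrix-exponential solution, within 0.5 %."""
        cell = two_comp_cell()
        mp = mb.MembraneParams()
        ch = mb.CaChannelParams("L", g_max=0.0)
        ve = np.array([0.0, 10.0])  # mV per unit drive
        dt, t_stop = 2e-4, 5.0
        n = int(round(t_stop / dt))
        wf = np.ones(n + 1)
        tr = mb.simulate(cell, mp, ch, mb.CaPoolParams(), ve, wf, dt, t_stop,
                         record_every=n // 10, record_full=True)

        # independent constants (hand arithmetic, same physical definitions)
        a_soma = np.pi * (10e-4) ** 2          # cm²
        a_axon = np.pi * (2e-4) * (10e-4)      # cm²
        c = mp.cm * np.array([a_soma, a_axon])              # μF
        gl = mp.g_leak * np.array([a_soma, a_axon])         # mS
        r_half_soma = mp.ri * (10e-4 / 2) / (np.pi * (5e-4) ** 2)
        r_half_axon = mp.ri * (10e-4 / 2) / (np.pi * (1e-4) ** 2)
        g_ax = 1e3 / (r_half_soma + r_half_axon)            # mS
        lap = np.array([[g_ax, -g_ax], [-g_ax, g_ax]])
        amat = -(np.diag(gl) + lap) / c[:, None]
        bvec = (gl * mp.e_leak - lap @ ve) / c
        v0 = np.full(2, mp.v_rest)
        vinf = np.linalg.solve(amat, -bvec)
        for k, t in enumerate(tr.t):
            exact = vinf + expm(amat * t) @ (v0 - vinf)
            np.testing.assert_allclose(tr.v_comp[k], exact, rtol=5e-3, atol=5e-3)

    def test_dt_halving_self_convergence(self, y_cell):
        cell = segmentize(y_cell, 1.0)
        mp = mb.MembraneParams()
        ch = mb.CaChannelParams("L")
        zmax = cell.xyz[:, 2].max()
        ve = 0.05 * (zmax - cell.xyz[:, 2])  # mV per μA, largest at the tips
        traces = {}
        for dt in (0.02, 0.01):
            n = int(round(20.0 / dt))
            wf = np.zeros(n + 1)
            wf[int(1 / dt):int(11 / dt)] = -100.0
            traces[dt] = mb.simulate(cell, mp, ch, mb.CaPoolParams(), ve, wf,
                                     dt, 20.0, record_every=int(0.1 / dt))
        v1 = traces[0.02].v_terminal_mean
        v2 = traces[0.01].v_terminal_mean
        t = traces[0.02].t
        # the samples landing exactly on the pulse edges see the discontinuous
        # jump resolved within a single (different-sized) step; compare the
        # smooth part of the response
        smooth = (np.abs(t - 1.0) > 1e-9) & (np.abs(t - 11.0) > 1e-9)
        scale = np.abs(v2 - v2[0]).max()
        assert np.abs(v1 - v2)[smooth].max() < 0.01 * scale

    def test_resting_cell_stays_at_rest(self, y_cell):
        tr = mb.simulate(y_cell, mb.MembraneParams(), mb.CaChannelParams("L"),
                         mb.CaPoolParams(), None, None, 0.05, 50.0,
                         record_every=20, record_full=True)
        assert np.abs(tr.v_comp + 53.0).max() < 0.05

    def test_linearity_with_channels_disabled(self, y_cell):
        mp = mb.MembraneParams()
        ch = mb.CaChannelParams("L", g_max=0.0)
        ve = -0.3 * y_cell.xyz[:, 2]
        out = []
        for amp in (1.0, 2.0):
            n = int(round(5.0 / 0.01))
            wf = np.full(n + 1, amp)
            tr = mb.simulate(y_cell, mp, ch, mb.CaPoolParams(), ve, wf, 0.01,
                             5.0, record_every=50)
            out.append(tr.v_terminal_mean - mp.v_rest)
        np.testing.assert_allclose(out[1], 2.0 * out[0], rtol=1e-9, atol=1e-9)

    def test_cathodic_pulse_polarity(self, on_cell):
        """Cathodic drive depolarizes the axon/terminals, hyperpolarizes the
        soma/dendrites (terminals see the most negative Ve)."""
        cell = segmentize(on_cell, 4.0)
        zmax = cell.xyz[:, 2].max()
        ve = 0.02 * (zmax - cell.xyz[:, 2])  # mV per μA: cathodic drive is most
        # negative at the terminals (smallest z)
        n = int(round(30.0 / 0.025))
        wf = np.zeros(n + 1)
        wf[int(1 / 0.025):] = -100.0
        tr = mb.simulate(cell, mb.MembraneParams(), mb.CaChannelParams("L"),
                         mb.CaPoolParams(), ve, wf, 0.025, 30.0, record_every=40)
        assert tr.v_sections["axon_terminal"][-1] > -53.0
        assert tr.v_sections["soma"][-1] < -53.0
        assert tr.v_sections["dendrite"][-1] < -53.0
        # and an inward (negative) terminal calcium current develops
        assert tr.i_ca_total.min() < 0.0

    def test_invalid_inputs_rejected(self, y_cell):
        mp, ch, pool = mb.MembraneParams(), mb.CaChannelParams("L"), mb.CaPoolParams()
        with pytest.raises(ValueError):
            mb.simulate(y_cell, mp, ch, pool, None, None, 0.0, 1.0)
        with pytest.raises(ValueError):
            mb.simulate(y_cell, mp, ch, pool, np.zeros(2), None, 0.01, 1.0)

    def test_nan_state_detected(self, y_cell):
        ve = np.full(y_cell.n, np.nan)
        wf = np.ones(101)
        with pytest.raises(FloatingPointError, match="t="):
            mb.simulate(y_cell, mb.MembraneParams(), mb.CaChannelParams("L"),
                        mb.CaPoolParams(), ve, wf, 0.01, 1.0)
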