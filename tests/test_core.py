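"""Gating algebra, Nernst potentials, channel currents, RHS assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apcontrib as ap
from apcontrib.core import ConfigurationError, DomainError


G = ap.GateSpec("g", 0.1, 4.0, ((1.0, 0.0, 0.0),))


class TestSteadyState:
    def test_exact_midpoint(self):
        # a1*V + a2 = 0 at V = -40 -> exactly 1/2
        assert ap.steady_state(G, -40.0) == 0.5

    def test_saturation_limits_are_finite(self):
        g = ap.GateSpec("g", 0.1, 0.0, ((1.0, 0.0, 0.0),))
        lo, hi = ap.steady_state(g, 1e6), ap.steady_state(g, -1e6)
        assert np.isfinite(lo) and lo == pytest.approx(0.0, abs=1e-100)
        assert np.isfinite(hi) and hi == 1.0

    def test_scalar_value(self):
        # 1/(1 + e^-3), checked against mpmath-style reference evaluation
        g = ap.GateSpec("g", -0.1, -3.0, ((1.0, 0.0, 0.0),))
        assert ap.steady_state(g, 0.0) == pytest.approx(0.9525741268224334, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        a1=st.floats(-1, 1, exclude_min=True).filter(lambda x: abs(x) > 1e-3),
        a2=st.floats(-20, 20),
    )
    def test_monotone_and_bounded(self, a1, a2):
        g = ap.GateSpec("g", a1, a2, ((1.0, 0.0, 0.0),))
        v = np.linspace(-120, 80, 201)
        x = ap.steady_state(g, v)
        assert np.all((x >= 0) & (x <= 1))
        dx = np.diff(x)
        assert np.all(dx <= 1e-12) if a1 > 0 else np.all(dx >= -1e-12)


class TestTimeConstant:
    @pytest.mark.parametrize(
        "terms, v, expected",
        [
            ((((1.0, 0.0, 0.0)),), 13.0, 1.0),
            (((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)), -55.0, 0.5),
            ((((2.0, 0.1, 0.0)),), 10.0, 1.0 / (2.0 * math.e)),
        ],
    )
    def test_examples(self, terms, v, expected):
        terms = (terms,) if isinstance(terms[0], float) else terms
        g = ap.GateSpec("g", 0.1, 0.0, terms)
        assert ap.time_constant(g, v) == pytest.approx(expected, rel=1e-12)

    def test_positive_for_all_bundled_gates(self, rat_model):
        v = np.linspace(-120, 80, 401)
        for gate in rat_model.gates:
            drv = v if gate.driver == "V" else np.linspace(1e-6, 2.0, 401)
            tau = ap.time_constant(gate, drv)
            assert np.all(tau > 0), gate.name

    def test_underflow_raises_domain_error(self):
        g = ap.GateSpec("g", 0.1, 0.0, ((0.0, 0.0, -500.0),))
        with pytest.raises(DomainError, match="g"):
            ap.time_constant(g, 0.0)


class TestGateDerivative:
    def test_zero_at_fixed_point(self):
        v = -20.0
        x = ap.steady_state(G, v)
        assert ap.gate_derivative(x, G, v) == 0.0

    def test_arithmetic(self):
        # x=0, x_inf=0.5, tau=2 -> 0.25/ms
        g = ap.GateSpec("g", 0.1, 4.0, ((0.5, 0.0, 0.0),))
        assert ap.gate_derivative(0.0, g, -40.0) == pytest.approx(0.25)

    def test_clamped_relaxation_matches_closed_form(self):
        # single gate at fixed V: x(t) = x_inf + (x0-x_inf) e^(-t/tau)
        from scipy.integrate import solve_ivp

        v = -30.0
        xinf = float(ap.steady_state(G, v))
        tau = float(ap.time_constant(G, v))
        sol = solve_ivp(
            lambda t, y: ap.gate_derivative(y, G, v), (0, 10), [0.0],
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        t = np.linspace(0, 10, 200)
        exact = xinf * (1.0 - np.exp(-t / tau))
        assert np.max(np.abs(sol.sol(t)[0] - exact)) < 1e-6


class TestNernst:
    C = ap.PhysicalConstants()

    def test_zero_at_equal_concentrations(self):
        assert ap.nernst(1, 5.4, 5.4, self.C) == 0.0

    def test_potassium(self):
        # Table-style K+ gradient: ~-86.9 mV at 310.15 K
        assert ap.nernst(1, 5.4, 139.275, self.C) == pytest.approx(-86.86, abs=0.05)

    def test_sodium(self):
        assert ap.nernst(1, 140.0, 10.735, self.C) == pytest.approx(68.63, abs=0.05)

    def test_divalent_halves_slope(self):
        e1 = ap.nernst(1, 10.0, 1.0, self.C)
        e2 = ap.nernst(2, 10.0, 1.0, self.C)
        assert e1 == pytest.approx(2.0 * e2)

    @pytest.mark.parametrize("out_, in_", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_concentration_raises(self, out_, in_):
        with pytest.raises(DomainError):
            ap.nernst(1, out_, in_, self.C)


class TestChannelCurrent:
    CH = ap.ChannelSpec("X", 6.2894, (("a", 2), ("b", 1)), e_fixed=0.0)

    def test_zero_at_reversal(self):
        assert ap.channel_current(self.CH, {"a": 0.7, "b": 0.3}, 0.0, 0.0) == 0.0

    def test_closed_gate_blocks(self):
        assert ap.channel_current(self.CH, {"a": 0.0, "b": 1.0}, 50.0, 0.0) == 0.0

    def test_table_conductance_passthrough(self):
        # all gates open, 1 mV driving force -> g itself
        assert ap.channel_current(self.CH, {"a": 1.0, "b": 1.0}, 1.0, 0.0) == 6.2894

    def test_linear_in_driving_force(self):
        g = {"a": 0.5, "b": 0.5}
        i1 = ap.channel_current(self.CH, g, 10.0, 0.0)
        i2 = ap.channel_current(self.CH, g, 20.0, 0.0)
        assert i2 == pytest.approx(2.0 * i1)

    def test_missing_gate_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="'b'"):
            ap.channel_current(self.CH, {"a": 1.0}, 10.0, 0.0)


class TestMembraneRhs:
    def test_no_currents_no_stimulus_is_flat(self):
        m = ap.toy_threshold_model(tau=1.0, x_inf=0.9, x0=0.1, theta=0.5, kappa=0.0)
        proto = ap.StimulusProtocol(amplitude=0.0, total_time=1.0)
        d = ap.simulate(m, proto, ap.SolverOptions(output_dt=0.1))
        assert np.allclose(d.V, d.V[0])

    def test_stimulus_scaling_by_capacitance(self):
        # 528 pA into 100 pF with no currents -> 5.28 mV/ms
        m = ap.CellModel(
            gates=[], channels=[], capacitance=100.0,
            constants=ap.PhysicalConstants(),
            concentrations=ap.IonConcentrations(external={}),
            state_layout=["V"], initial_state={"V": -80.0},
        )
        dv = m.rhs(0.0, np.array([-80.0]), i_app=528.0)
        assert dv[0] == pytest.approx(5.28)

    def test_rat_rhs_finite_at_printed_initial_state(self, rat_model):
        d = rat_model.rhs(0.0, rat_model.initial_vector())
        assert np.all(np.isfinite(d))

    def test_rat_gates_stationary_at_printed_initial_state(self, rat_model):
        # half-points are solved from the printed initial values, so every
        # gate must be exactly at steady state in the printed state
        d = rat_model.rhs(0.0, rat_model.initial_vector())
        for g in rat_model.gates:
            assert abs(d[rat_model.index[g.name]]) < 1e-12, g.name


class TestModelValidation:
    def test_duplicate_state_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            ap.CellModel(
                gates=[], channels=[], capacitance=1.0,
                constants=ap.PhysicalConstants(),
                concentrations=ap.IonConcentrations(external={}),
                state_layout=["V", "V"], initial_state={"V": 0.0},
            )

    def test_channel_with_unknown_gate_rejected(self):
        with pytest.raises(ConfigurationError, match="zz"):
            ap.CellModel(
                gates=[], channels=[ap.ChannelSpec("X", 1.0, (("zz", 1),), e_fixed=0.0)],
                capacitance=1.0, constants=ap.PhysicalConstants(),
                concentrations=ap.IonConcentrations(external={}),
                state_layout=["V"], initial_state={"V": 0.0},
            )
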