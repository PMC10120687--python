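"""Hill normalization, gate algebra, ODE assembly and steady states."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibrosex as fx
from fibrosex.exceptions import IntegrationError, ParameterError
from fibrosex.logic_ode_core import hill_constants
from fibrosex.synthetic_data import ToySpec, fixed_point_oracle, make_toy_network

unit = st.floats(min_value=0.0, max_value=1.0)


class TestHill:
    @pytest.mark.parametrize("n", [0.5, 1.0, 1.05, 2.0, 4.0])
    @pytest.mark.parametrize("ec50", [0.3, 0.4, 0.65, 0.8])
    def test_normalization_anchors(self, n, ec50):
        assert fx.hill(0.0, n, ec50) == pytest.approx(0.0, abs=1e-12)
        assert fx.hill(ec50, n, ec50) == pytest.approx(0.5, abs=1e-12)
        assert fx.hill(1.0, n, ec50) == pytest.approx(1.0, abs=1e-12)

    @given(n=st.floats(0.5, 4.0), ec50=st.floats(0.3, 0.8))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, n, ec50):
        try:
            hill_constants(n, ec50)
        except ParameterError:
            return  # degenerate ec50^n == 1/2 point, rejected by design
        x = np.linspace(0, 1, 101)
        y = fx.hill(x, n, ec50)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= -1e-12) & (y <= 1 + 1e-12))

    def test_parameter_domain_errors(self):
        with pytest.raises(ParameterError):
            fx.hill(0.5, 1.05, 1.2)
        with pytest.raises(ParameterError):
            fx.hill(0.5, -1.0, 0.65)
        with pytest.raises(ParameterError):  # ec50^n == 0.5 exactly
            fx.hill(0.5, 1.0, 0.5)


class TestGates:
    def test_worked_values(self):
        assert fx.gate_or(0.5, 0.5) == pytest.approx(0.75)
        assert fx.gate_and(0.5, 0.5) == pytest.approx(0.25)
        assert fx.gate_not(0.3) == pytest.approx(0.7)

    @given(a=unit, b=unit, c=unit)
    @settings(max_examples=100, deadline=None)
    def test_algebra_identities(self, a, b, c):
        assert fx.gate_or(a, 0.0) == pytest.approx(a, abs=1e-15)
        assert fx.gate_and(a, 1.0) == pytest.approx(a, abs=1e-15)
        assert fx.gate_or(a, b) == pytest.approx(fx.gate_or(b, a), abs=1e-15)
        assert fx.gate_and(a, b) == pytest.approx(fx.gate_and(b, a), abs=1e-15)
        assert fx.gate_or(fx.gate_or(a, b), c) == pytest.approx(
            fx.gate_or(a, fx.gate_or(b, c)), abs=1e-12)
        assert fx.gate_and(fx.gate_and(a, b), c) == pytest.approx(
            fx.gate_and(a, fx.gate_and(b, c)), abs=1e-12)
        assert fx.gate_not(fx.gate_not(a)) == pytest.approx(a, abs=1e-15)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ParameterError):
            fx.gate_not(1.5)
        with pytest.raises(ParameterError):
            fx.gate_and(-0.2, 0.5)


class TestBuildRhs:
    def test_source_reaction_closed_form(self):
        # dy/dt = (0.4 - y)/1  ->  y(t) = 0.4 (1 - e^{-t})
        model = fx.NetworkModel(
            species=[fx.SpeciesSpec(id="A")],
            reactions=[fx.ReactionSpec(rule="=> A", w=0.4)],
        )
        for t in (0.5, 2.0, 5.0):
            st_ = fx.simulate(model, settings=fx.SimulationSettings(t_end=t))
            assert st_["A"] == pytest.approx(0.4 * (1 - np.exp(-t)), abs=1e-5)
        ss = fx.steady_state(model)
        assert ss["A"] == pytest.approx(0.4, abs=1e-6)

    def test_unproduced_species_decays(self):
        # no producers: y(t) = y0 e^{-t/tau}
        model = fx.NetworkModel(
            species=[fx.SpeciesSpec(id="A", y0=0.8, tau=10.0)],
            reactions=[],
        )
        st_ = fx.simulate(model, settings=fx.SimulationSettings(t_end=10.0))
        assert st_["A"] == pytest.approx(0.8 * np.exp(-1.0), abs=1e-5)

    def test_two_sources_combine_by_or(self):
        rhs = fx.build_rhs(
            fx.NetworkModel(
                species=[fx.SpeciesSpec(id="A")],
                reactions=[
                    fx.ReactionSpec(rule="=> A", w=0.5),
                    fx.ReactionSpec(rule="=> A", w=0.5),
                ],
            )
        )
        # at y=0: dy/dt = OR(0.5, 0.5) * ymax = 0.75
        assert rhs(0.0, np.zeros(1))[0] == pytest.approx(0.75)

    def test_cascade_endpoint_is_sequential_hill(self, two_node_cascade):
        ss = fx.steady_state(two_node_cascade, {"up": 1.0})
        assert ss["up"] == pytest.approx(1.0, abs=1e-6)
        assert ss["down"] == pytest.approx(fx.hill(ss["up"], 1.05, 0.65), abs=1e-5)

    def test_ymax_zero_is_hard_knockout(self):
        model = fx.NetworkModel(
            species=[fx.SpeciesSpec(id="A", ymax=0.0), fx.SpeciesSpec(id="B")],
            reactions=[
                fx.ReactionSpec(rule="=> A", w=1.0),
                fx.ReactionSpec(rule="A => B"),
            ],
        )
        ss = fx.steady_state(model)
        assert ss["A"] == pytest.approx(0.0, abs=1e-8)
        assert ss["B"] == pytest.approx(0.0, abs=1e-6)


class TestSimulate:
    def test_unknown_input_id_errors(self, two_node_cascade):
        with pytest.raises(IntegrationError, match="unknown input"):
            fx.simulate(two_node_cascade, {"nonexistent": 1.0})

    def test_override_requires_source_reaction(self, two_node_cascade):
        with pytest.raises(IntegrationError, match="source reaction"):
            fx.simulate(two_node_cascade, {"down": 1.0})

    def test_zero_inputs_zero_start_stays_zero(self, mini):
        st_ = fx.simulate(mini, {k: 0.0 for k in mini.input_ids},
                          fx.SimulationSettings(t_end=50.0))
        assert np.allclose(st_.activities, 0.0, atol=1e-7)

    def test_chaining_equals_piecewise(self, mini):
        w = {"E2": 0.7, "AngII": 0.4, "tension": 0.65}
        one = fx.simulate(mini, w, fx.SimulationSettings(t_end=120.0))
        a = fx.simulate(mini, w, fx.SimulationSettings(t_end=40.0))
        b = fx.simulate(mini, w, fx.SimulationSettings(t_end=80.0), y_start=a)
        assert np.allclose(one.activities, b.activities, atol=1e-5)

    def test_boundedness_on_toy_networks(self):
        for seed in range(5):
            model = make_toy_network(
                ToySpec(n_nodes=8, topology="random_dag", seed=seed)
            )
            w = {k: 1.0 for k in model.input_ids}
            st_ = fx.simulate(model, w,
                              fx.SimulationSettings(t_end=60.0, record=True))
            ymax = np.array([s.ymax for s in model.species])
            assert np.all(st_.trajectory_y >= -1e-6)
            assert np.all(st_.trajectory_y <= ymax + 1e-6)

    def test_trajectory_recorded_when_requested(self, two_node_cascade):
        st_ = fx.simulate(two_node_cascade, {"up": 1.0},
                          fx.SimulationSettings(t_end=10.0, record=True))
        assert st_.trajectory_t is not None
        assert st_.trajectory_y.shape == (len(st_.trajectory_t), 2)


class TestSteadyState:
    @pytest.mark.parametrize("topology", ["chain", "fan_in", "fan_out",
                                          "random_dag"])
    def test_acyclic_matches_fixed_point_oracle(self, topology):
        model = make_toy_network(ToySpec(n_nodes=7, topology=topology, seed=3))
        w = {k: 0.8 for k in model.input_ids}
        ss = fx.steady_state(model, w, fx.SimulationSettings(t_end=600.0))
        oracle = fixed_point_oracle(model, w)
        assert ss.converged
        for sid in model.species_ids:
            assert ss[sid] == pytest.approx(oracle[sid], abs=1e-5)

    def test_negative_feedback_matches_damped_oracle(self):
        model = make_toy_network(
            ToySpec(n_nodes=5, topology="negative_feedback", seed=0)
        )
        w = {k: 1.0 for k in model.input_ids}
        ss = fx.steady_state(model, w, fx.SimulationSettings(t_end=600.0))
        oracle = fixed_point_oracle(model, w, damping=0.5)
        for sid in model.species_ids:
            assert ss[sid] == pytest.approx(oracle[sid], abs=1e-4)

    def test_source_node_alone_reaches_w_times_ymax(self):
        model = fx.NetworkModel(
            species=[fx.SpeciesSpec(id="A", ymax=0.6)],
            reactions=[fx.ReactionSpec(rule="=> A", w=0.5)],
        )
        ss = fx.steady_state(model)
        assert ss["A"] == pytest.approx(0.5 * 0.6, abs=1e-7)

    def test_monotone_in_source_weight_on_positive_paths(self):
        model = make_toy_network(ToySpec(n_nodes=6, topology="fan_out", seed=1))
        lo = fx.steady_state(model, {"X0": 0.3})
        hi = fx.steady_state(model, {"X0": 0.9})
        assert np.all(hi.activities >= lo.activities - 1e-7)
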