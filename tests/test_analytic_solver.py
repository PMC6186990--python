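"""Propagator matrices, update schemes and exactness of the analytic path."""

import numpy as np
import pytest
import sympy as sp
from scipy.linalg import expm

from conftest import reference_trajectory
from odeanalyzer import fixtures
from odeanalyzer import analytic_solver as asol
from odeanalyzer import ode_classification as oc
from odeanalyzer import shape_analysis as sa
from odeanalyzer._expr import TIME as t
from odeanalyzer.model_io import load_input
from odeanalyzer.stiffness import generate_spike_trains, SpikeTrainConfig

h = asol.STEP
tau, tau_s, C = sp.symbols("Tau tau_syn C")

NUMERIC_PARAMS = {tau: 10, tau_s: 2, C: 250, h: sp.Rational(1, 10)}


def alpha_system(**kwargs):
    shape = sa.derive_shape_ode(sp.E / tau_s * t * sp.exp(-t / tau_s), symbol="I")
    ode = oc.classify_ode("V", -sp.Symbol("V") / tau + sp.Symbol("I") / C, [shape])
    return shape, ode, asol.build_system_matrix(shape, ode, **kwargs)


def exp_system():
    shape = sa.derive_shape_ode(sp.exp(-t / tau_s), symbol="I")
    ode = oc.classify_ode("V", -sp.Symbol("V") / tau + sp.Symbol("I") / C, [shape])
    return shape, ode, asol.build_system_matrix(shape, ode)


class TestSystemMatrix:
    def test_order_one_matrix(self):
        _, _, sys = exp_system()
        expected = sp.Matrix([[-1 / tau_s, 0], [1 / C, -1 / tau]])
        assert sp.simplify(sys.A - expected) == sp.zeros(2, 2)
        assert sys.triangular

    def test_alpha_triangular_matrix_and_aux_root(self):
        # discriminant a1^2/4 + a0 vanishes for the alpha shape: x = 1/tau_s
        _, _, sys = alpha_system()
        assert sys.triangular
        assert sp.simplify(sys.x_aux - 1 / tau_s) == 0
        expected = sp.Matrix(
            [[-1 / tau_s, 0, 0], [1, -1 / tau_s, 0], [0, 1 / C, -1 / tau]]
        )
        assert sp.simplify(sys.A - expected) == sp.zeros(3, 3)
        assert sys.state_order == ["I__x", "I", "V"]
        # y = T (I', I, V)
        assert sp.simplify(sys.transform_T - sp.Matrix(
            [[1, 1 / tau_s, 0], [0, 1, 0], [0, 0, 1]]
        )) == sp.zeros(3, 3)

    def test_order_two_generic_companion_form(self):
        shape, ode, _ = alpha_system()
        sys = asol.build_system_matrix(shape, ode, force_generic=True)
        a0, a1 = shape.coefficients
        expected = sp.Matrix([[a1, a0, 0], [1, 0, 0], [0, 1 / C, -1 / tau]])
        assert sp.simplify(sys.A - expected) == sp.zeros(3, 3)
        assert sys.transform_T == sp.eye(3)

    def test_oscillatory_shape_falls_back_to_generic(self):
        # a1^2/4 + a0 < 0: the triangular auxiliary root would be complex
        shape = sa.Shape(
            symbol="I",
            order=2,
            coefficients=[sp.Integer(-4), sp.Integer(-1)],
            initial_values=[sp.Integer(0), sp.Integer(1)],
            source_form="ode_with_initial_values",
        )
        ode = oc.classify_ode("V", -sp.Symbol("V") / tau + sp.Symbol("I") / C, [shape])
        sys = asol.build_system_matrix(shape, ode)
        assert not sys.triangular


class TestPropagator:
    def test_zero_matrix_gives_identity(self):
        sys = asol.SystemMatrix(
            A=sp.zeros(2, 2), state_order=["a", "b"],
            transform_T=sp.eye(2), triangular=True,
        )
        assert asol.compute_propagator(sys) == sp.eye(2)

    @pytest.mark.parametrize("builder", [exp_system, alpha_system])
    def test_last_diagonal_entry_is_membrane_decay(self, builder):
        _, _, sys = builder()
        P = asol.compute_propagator(sys)
        n = P.rows - 1
        assert sp.simplify(P[n, n] - sp.exp(-h / tau)) == 0

    def test_semigroup_symbolically_for_triangular_orders(self):
        h1, h2 = sp.symbols("h1 h2", positive=True)
        for builder in (exp_system, alpha_system):
            _, _, sys = builder()
            P = asol.compute_propagator(sys)
            lhs = (P.subs(h, h1) * P.subs(h, h2)).applyfunc(sp.simplify)
            rhs = P.subs(h, h1 + h2)
            assert sp.simplify(lhs - rhs) == sp.zeros(P.rows, P.rows)

    @pytest.mark.parametrize("force_generic", [False, True])
    def test_numeric_agreement_with_matrix_exponential(self, force_generic):
        _, _, sys = alpha_system(force_generic=force_generic)
        P = asol.compute_propagator(sys)
        A_num = np.array(sys.A.subs(NUMERIC_PARAMS).evalf(30), dtype=float)
        P_num = np.array(P.subs(NUMERIC_PARAMS).evalf(30), dtype=float)
        assert np.max(np.abs(P_num - expm(A_num * 0.1))) < 1e-12

    def test_order_three_semigroup_numerically(self):
        shape = sa.derive_shape_ode(t**2 * sp.exp(-t / tau_s), symbol="I")
        ode = oc.classify_ode("V", -sp.Symbol("V") / tau + sp.Symbol("I") / C, [shape])
        sys = asol.build_system_matrix(shape, ode)
        P = asol.compute_propagator(sys)
        subs = {tau: 10, tau_s: 2, C: 250}
        P1 = np.array(P.subs(subs).subs(h, 0.1).evalf(30), dtype=float)
        P2 = np.array(P.subs(subs).subs(h, 0.25).evalf(30), dtype=float)
        P3 = np.array(P.subs(subs).subs(h, 0.35).evalf(30), dtype=float)
        assert np.max(np.abs(P1 @ P2 - P3)) < 1e-12


class TestUpdateStep:
    def test_order_one_instruction_structure(self):
        shape, ode, sys = exp_system()
        P = asol.compute_propagator(sys)
        scheme = asol.compose_update_step([P], [shape], ode, systems=[sys])
        assert len(scheme.update_instructions) == 2
        # y1 <- P11 y1 ; V <- P21 y1 + e^{-h/tau} V
        I, V = sp.Symbol("I"), sp.Symbol("V")
        assert sp.simplify(scheme.update_exprs["I"] - P[0, 0] * I) == 0
        v = scheme.update_exprs["V"]
        assert sp.simplify(v.diff(I) - P[1, 0]) == 0
        assert sp.simplify(v.diff(V) - sp.exp(-h / tau)) == 0

    def test_two_shapes_contribute_additively(self, two_shape_document):
        from odeanalyzer.model_io import analyse

        rec = analyse(load_input(two_shape_document), quiet=True)
        assert rec.scheme == "analytical"
        v_line = [s for s in rec.propagator["update_instructions"]
                  if s.startswith("V = ")][0]
        assert "I1" in v_line and "I2" in v_line
        names = rec.propagator["propagators"]
        assert any(k.startswith("P_I1_") for k in names)
        assert any(k.startswith("P_I2_") for k in names)

    def test_alpha_spike_increment_carries_initial_slope(self):
        shape, ode, sys = alpha_system()
        P = asol.compute_propagator(sys)
        scheme = asol.compose_update_step([P], [shape], ode, systems=[sys])
        inc = scheme.spike_increments["I"]
        # in the triangular basis the whole jump sits on y1 = I' + x I
        assert sp.simplify(inc[0] - sp.E / tau_s) == 0
        assert inc[1] == 0


class TestBias:
    def bias_scheme(self):
        model = load_input({
            "odes": [{"symbol": "V", "definition": "-V/Tau + I_e/C",
                      "initial_values": {"V": "0"}}],
            "shapes": [],
            "parameters": {"Tau": "10", "C": "250", "I_e": "100"},
        })
        shapes = []
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        return model, asol.build_scheme(ode, shapes, model)

    def test_constant_input_closed_form(self):
        # V(h) = I_E tau / C (1 - e^{-h/tau}) from V(0) = 0, h = 1
        model, scheme = self.bias_scheme()
        traj = asol.evolve_analytic(scheme, None, [], 1.0, 1,
                                    parameters=model.parameters)
        expected = 100 * 10 / 250 * (1 - np.exp(-1 / 10))
        assert traj[1][0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3806503, abs=5e-7)

    def test_piecewise_constant_with_equal_levels_reduces_to_constant(self):
        model, scheme = self.bias_scheme()
        n = 25
        constant = asol.evolve_analytic(scheme, None, [], 0.2, n,
                                        parameters=model.parameters)
        piecewise = asol.evolve_analytic(
            scheme, None, [], 0.2, n, parameters=model.parameters,
            bias_values=np.full(n, 100 / 250),
        )
        assert np.array_equal(constant, piecewise)

    def test_varying_piecewise_levels_match_oracle(self):
        model, scheme = self.bias_scheme()
        levels = np.array([0.4, 0.4, 0.0, 0.8, 0.8])
        traj = asol.evolve_analytic(scheme, None, [], 0.5, 5,
                                    parameters=model.parameters,
                                    bias_values=levels)
        # stepwise closed form V_{k+1} = V_k e^{-h/tau} + c_k tau (1 - e^{-h/tau})
        v, d = 0.0, np.exp(-0.5 / 10)
        for c in levels:
            v = v * d + c * 10 * (1 - d)
        assert traj[-1][0] == pytest.approx(v, rel=1e-12)


class TestEvolveExactness:
    def test_homogeneous_decay_matches_closed_form(self):
        model = fixtures.make_fixture("iaf_psc_alpha")
        from odeanalyzer.model_io import analyse  # scheme via full pipeline
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        scheme = asol.build_scheme(ode, shapes, model)
        traj = asol.evolve_analytic(scheme, {"V": 5.0}, [], 0.1, 40,
                                    parameters=model.parameters)
        v = traj[:, scheme.state_order.index("V")]
        assert np.max(np.abs(v - 5.0 * np.exp(-np.arange(41) * 0.1 / 10))) < 1e-12

    def test_spike_driven_membrane_matches_adaptive_oracle(self):
        model = fixtures.make_fixture("iaf_psc_alpha")
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        scheme = asol.build_scheme(ode, shapes, model)
        hv, n = 0.1, 100
        train = generate_spike_trains(
            SpikeTrainConfig(rate=0.5, duration=hv * n, trials=1, seed=7),
            resolution=hv,
        )[0]
        traj = asol.evolve_analytic(
            scheme, None, [(s, 1.0) for s in train], hv, n,
            parameters=model.parameters,
        )
        names, ref = reference_trajectory(model, train, hv, n)
        v = traj[:, scheme.state_order.index("V")]
        v_ref = ref[:, names.index("V")]
        scale = np.max(np.abs(v_ref))
        assert scale > 0
        assert np.max(np.abs(v - v_ref)) / scale < 1e-8

    def test_superposition_of_spike_trains(self):
        model = fixtures.make_fixture("iaf_psc_alpha")
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        scheme = asol.build_scheme(ode, shapes, model)
        a = [(0.5, 1.0), (2.0, 0.5)]
        b = [(1.0, 2.0), (2.0, 1.5), (4.0, 1.0)]
        kw = dict(parameters=model.parameters)
        both = asol.evolve_analytic(scheme, None, a + b, 0.5, 12, **kw)
        only_a = asol.evolve_analytic(scheme, None, a, 0.5, 12, **kw)
        only_b = asol.evolve_analytic(scheme, None, b, 0.5, 12, **kw)
        assert np.max(np.abs(both - only_a - only_b)) < 1e-12

    def test_off_grid_spike_is_rejected(self):
        model = fixtures.make_fixture("iaf_psc_alpha")
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        scheme = asol.build_scheme(ode, shapes, model)
        with pytest.raises(ValueError, match="grid"):
            asol.evolve_analytic(scheme, None, [(0.05, 1.0)], 0.1, 10,
                                 parameters=model.parameters)

    def test_triangular_and_generic_schemes_agree(self):
        model = fixtures.make_fixture("iaf_psc_alpha")
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        spikes = [(0.0, 1.0), (1.5, 2.0), (3.0, 0.25)]
        results = []
        for force in (False, True):
            sys = asol.build_system_matrix(shapes[0], ode, force_generic=force)
            P = asol.compute_propagator(sys)
            scheme = asol.compose_update_step([P], shapes, ode, systems=[sys])
            traj = asol.evolve_analytic(scheme, None, spikes, 0.5, 20,
                                        parameters=model.parameters)
            results.append(traj[:, scheme.state_order.index("V")])
        assert np.max(np.abs(results[0] - results[1])) < 1e-10

    def test_equal_membrane_and_synaptic_timescales(self):
        """tau_syn = Tau produces h*e^{-h/tau} propagator terms; the scheme
        must remain exact in this degenerate case."""
        model = fixtures.make_fixture("iaf_psc_alpha")
        model.parameters["tau_syn"] = sp.Integer(10)  # equal to Tau
        shapes = [sa.analyse_shape(s) for s in model.shapes]
        ode = oc.classify_ode("V", model.odes[0].definition, shapes)
        scheme = asol.build_scheme(ode, shapes, model)
        hv, n = 0.2, 50
        train = np.array([0.2, 3.0])
        traj = asol.evolve_analytic(scheme, None, [(s, 1.0) for s in train],
                                    hv, n, parameters=model.parameters)
        names, ref = reference_trajectory(model, train, hv, n)
        v = traj[:, scheme.state_order.index("V")]
        v_ref = ref[:, names.index("V")]
        assert np.max(np.abs(v - v_ref)) / np.max(np.abs(v_ref)) < 1e-8
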