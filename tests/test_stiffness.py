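"""Spike trains, adaptive step statistics and the recommendation tree."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odeanalyzer import fixtures
from odeanalyzer.model_io import load_input
from odeanalyzer.stiffness import (
    MACHINE_EPSILON,
    SpikeTrainConfig,
    StepStats,
    StiffnessError,
    build_numeric_system,
    classify_stiffness,
    generate_spike_trains,
    integrate_adaptive,
    stiffness_test,
)


def stats(scheme, m, s, failed=False):
    return StepStats(scheme=scheme, min_step=m, avg_step=s,
                     accepted_steps=100, failed=failed)


class TestSpikeTrains:
    def test_deterministic_given_seed(self):
        config = SpikeTrainConfig(rate=0.5, duration=20, trials=3, seed=42)
        a = generate_spike_trains(config, resolution=0.1)
        b = generate_spike_trains(config, resolution=0.1)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        # different seed -> different realization
        c = generate_spike_trains(
            SpikeTrainConfig(rate=0.5, duration=20, trials=3, seed=43), 0.1
        )
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_poisson_event_count(self):
        # nu * duration = 40 expected events; 1000 trials
        config = SpikeTrainConfig(rate=2.0, duration=20, trials=1000, seed=5)
        counts = [len(tr) for tr in generate_spike_trains(config)]
        standard_error = np.sqrt(40 / 1000)
        assert abs(np.mean(counts) - 40) < 3 * standard_error

    def test_zero_rate_gives_empty_trains(self):
        config = SpikeTrainConfig(rate=0.0, duration=20, trials=4, seed=1)
        assert all(len(tr) == 0 for tr in generate_spike_trains(config))

    def test_grid_alignment(self):
        config = SpikeTrainConfig(rate=1.0, duration=20, trials=2, seed=9)
        for train in generate_spike_trains(config, resolution=0.1):
            assert np.allclose(np.round(train / 0.1), train / 0.1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrainConfig(rate=-1.0)
        with pytest.raises(ValueError):
            SpikeTrainConfig(trials=0)


class TestIntegrateAdaptive:
    def decay_system(self):
        return build_numeric_system(load_input({
            "odes": [{"symbol": "V", "definition": "-V/Tau",
                      "initial_values": {"V": "1"}}],
            "shapes": [],
            "parameters": {"Tau": "10"},
        }))

    def test_smooth_problem_steps_track_the_grid(self):
        system = self.decay_system()
        result = integrate_adaptive(system, "explicit", np.array([]),
                                    h=0.5, tol=1e-3, duration=10.0)
        assert not result.failed
        assert result.min_step > 0.1
        assert result.avg_step == pytest.approx(0.5, rel=0.2)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            integrate_adaptive(self.decay_system(), "midpoint", np.array([]),
                               0.1, 1e-3, duration=1.0)

    def test_stiff_pair_explicit_steps_much_smaller_than_implicit(self):
        system = build_numeric_system(fixtures.make_fixture("stiff_pair"))
        spikes = np.array([4.0, 11.0])
        expl = integrate_adaptive(system, "explicit", spikes, 0.2, 1e-5, 20.0)
        impl = integrate_adaptive(system, "implicit", spikes, 0.2, 1e-5, 20.0)
        assert not expl.failed and not impl.failed
        assert impl.avg_step > 3 * expl.avg_step
        assert 0 < expl.min_step <= expl.avg_step
        assert 0 < impl.min_step <= impl.avg_step


class TestClassifyStiffness:
    eps = MACHINE_EPSILON

    def test_both_near_machine_precision_is_a_warning(self):
        rec = classify_stiffness(stats("explicit", self.eps, 1e-3),
                                 stats("implicit", 5 * self.eps, 1e-3))
        assert rec.scheme == "warning"

    def test_explicit_collapse_recommends_implicit(self):
        rec = classify_stiffness(stats("explicit", self.eps, 1e-5),
                                 stats("implicit", 1e-3, 1e-2))
        assert rec.scheme == "numeric-implicit"

    def test_implicit_collapse_recommends_explicit(self):
        rec = classify_stiffness(stats("explicit", 1e-3, 1e-2),
                                 stats("implicit", self.eps, 1e-5))
        assert rec.scheme == "numeric-explicit"

    def test_average_ratio_threshold_beta(self):
        expl = stats("explicit", 1e-3, 1e-2)
        assert classify_stiffness(expl, stats("implicit", 1e-3, 7e-2)).scheme \
            == "numeric-implicit"
        assert classify_stiffness(expl, stats("implicit", 1e-3, 5e-2)).scheme \
            == "numeric-explicit"
        # the rule is strict: s_impl must exceed beta * s_expl
        assert classify_stiffness(expl, stats("implicit", 1e-3, 6e-2)).scheme \
            == "numeric-explicit"

    def test_explicit_abort_counts_as_collapse(self):
        rec = classify_stiffness(stats("explicit", 1e-2, 1e-1, failed=True),
                                 stats("implicit", 1e-3, 1e-2))
        assert rec.scheme == "numeric-implicit"

    @settings(derandomize=True, max_examples=200)
    @given(
        m_e=st.floats(0, 1e-2, allow_nan=False),
        s_e=st.floats(1e-12, 1.0, allow_nan=False),
        m_i=st.floats(0, 1e-2, allow_nan=False),
        s_i=st.floats(1e-12, 1.0, allow_nan=False),
        f_e=st.booleans(),
        f_i=st.booleans(),
    )
    def test_decision_tree_is_total(self, m_e, s_e, m_i, s_i, f_e, f_i):
        rec = classify_stiffness(stats("explicit", m_e, s_e, f_e),
                                 stats("implicit", m_i, s_i, f_i))
        assert rec.scheme in ("warning", "numeric-implicit", "numeric-explicit")
        assert rec.stiffness_evidence["beta"] == 6.0


class TestStiffnessTest:
    def test_seed_reproducibility(self):
        model = fixtures.make_fixture("stiff_pair")
        config = SpikeTrainConfig(rate=0.1, duration=20, trials=3, seed=11)
        a = stiffness_test(model, h=0.2, tol=1e-3, config=config)
        b = stiffness_test(model, h=0.2, tol=1e-3, config=config)
        assert a.scheme == b.scheme
        assert a.stiffness_evidence == b.stiffness_evidence

    def test_unintegrable_system_raises(self):
        model = load_input({
            "odes": [{"symbol": "y", "definition": "y**2",
                      "initial_values": {"y": "1"}}],
            "shapes": [],
            "parameters": {},
        })
        # y' = y^2 blows up in finite time (t* = 1): both schemes abort
        config = SpikeTrainConfig(rate=0.0, duration=20, trials=1, seed=0)
        with pytest.raises(StiffnessError):
            stiffness_test(model, h=0.5, tol=1e-8, config=config)
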