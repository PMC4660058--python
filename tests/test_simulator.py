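"""Stochastic simulator: propensities, traces, observation, distributions."""

import math

import numpy as np
import pytest
from scipy import stats

from bfckinetics.model_core import BarbedEndState as S
from bfckinetics.model_core import bf_cdf, partition_fractions
from bfckinetics.replication import FMNL2, MDIA1_SETUP1, MDIA1_SETUP2
from bfckinetics.simulator import (
    FORMIN_ANCHORED,
    FilamentTrace,
    FlowProtocol,
    SolutionCondition,
    elongation_velocity,
    observe,
    observe_population,
    propensities,
    simulate_filament,
    simulate_population,
)

PA = SolutionCondition(actin=1.0, profilin=4.0, label="pa")
EMPTY = SolutionCondition(label="empty")


class TestPropensities:
    def test_bfc_decay_channels_under_pa(self):
        chans = dict(propensities(S.BFC, PA, MDIA1_SETUP2))
        assert chans[S.BF] == pytest.approx(2.02e-3)
        assert chans[S.BC] == pytest.approx(6.34e-3)

    def test_free_end_without_binders_has_no_channels(self):
        assert propensities(S.B, PA, MDIA1_SETUP1) == []

    def test_capping_of_formin_bound_end_is_pseudo_first_order(self):
        cond = SolutionCondition(actin=1.0, cp=0.1)
        chans = dict(propensities(S.BF, cond, MDIA1_SETUP1))
        assert chans[S.BFC] == pytest.approx(0.021)

    def test_ternary_complex_locked_without_actin(self):
        cond = SolutionCondition(formin=0.02)
        assert propensities(S.BFC, cond, MDIA1_SETUP1) == []
        ungated = dict(propensities(S.BFC, cond, MDIA1_SETUP1, bfc_decay_requires_actin=False))
        assert ungated[S.BC] == pytest.approx(4.2e-3)


class TestElongationVelocity:
    def test_capped_states_do_not_grow(self):
        assert elongation_velocity(S.BFC, PA, MDIA1_SETUP1) == 0.0
        assert elongation_velocity(S.BC, PA, MDIA1_SETUP1) == 0.0

    def test_mdia1_processive_velocity_at_standard_conditions(self):
        assert elongation_velocity(S.BF, PA, MDIA1_SETUP1) == pytest.approx(44.2)

    def test_fmnl2_velocity_is_twofold_free_end(self):
        v_free = elongation_velocity(S.B, PA, FMNL2)
        assert elongation_velocity(S.BF, PA, FMNL2) == pytest.approx(2 * v_free)

    def test_no_substrate_no_growth(self):
        assert elongation_velocity(S.B, EMPTY, MDIA1_SETUP1) == 0.0


class TestSimulateFilament:
    def test_quiescent_conditions_give_no_transitions(self):
        proto = FlowProtocol(((300.0, EMPTY),))
        trace = simulate_filament(proto, MDIA1_SETUP1, initial_state=S.B, rng_seed=1)
        assert trace.transitions == []
        assert trace.final_state is S.B
        assert trace.observed_until == 300.0

    def test_length_grows_only_in_elongating_states(self):
        cond = SolutionCondition(actin=1.0, cp=0.1)
        proto = FlowProtocol(((600.0, cond),))
        trace = simulate_filament(proto, MDIA1_SETUP1, initial_state=S.BF, rng_seed=3)
        assert np.all(np.diff(trace.lengths) >= -1e-12)
        # once capped, length stays flat
        arrest = next(t for t, _, to in trace.transitions if to is S.BFC)
        assert trace.length_at(arrest + 50.0) == pytest.approx(trace.length_at(arrest))

    def test_formin_anchored_detaches_on_formin_loss(self):
        proto = FlowProtocol(((5000.0, PA),), anchor_mode=FORMIN_ANCHORED)
        detached = 0
        for i in range(50):
            tr = simulate_filament(proto, MDIA1_SETUP2, initial_state=S.BFC, rng_seed=(9, i))
            if tr.detached_at is not None:
                detached += 1
                assert tr.final_state in (S.BC, S.B)
                assert tr.observed_until == tr.detached_at
                assert tr.transitions[-1][0] == tr.detached_at
        assert detached > 0

    def test_seed_anchored_never_detaches(self):
        proto = FlowProtocol(((5000.0, PA),))
        for i in range(50):
            tr = simulate_filament(proto, MDIA1_SETUP2, initial_state=S.BFC, rng_seed=(11, i))
            assert tr.detached_at is None

    def test_ternary_formation_order_tag(self):
        cond = SolutionCondition(actin=1.0, cp=0.5)
        proto = FlowProtocol(((2000.0, cond),))
        tr = simulate_filament(proto, MDIA1_SETUP1, initial_state=S.BF, rng_seed=5)
        assert tr.ternary_formation_order() == "via_BF_then_C"

    def test_zero_segments_rejected(self):
        with pytest.raises(ValueError):
            FlowProtocol((), anchor_mode="seed_anchored")


class TestSimulatePopulation:
    def test_reproducible_given_master_seed(self):
        proto = FlowProtocol(((600.0, PA),))
        a = simulate_population(20, proto, MDIA1_SETUP2, initial_state=S.BFC, master_seed=7)
        b = simulate_population(20, proto, MDIA1_SETUP2, initial_state=S.BFC, master_seed=7)
        for ta, tb in zip(a, b):
            assert ta.transitions == tb.transitions
            np.testing.assert_array_equal(ta.lengths, tb.lengths)

    def test_singleton_population(self):
        proto = FlowProtocol(((10.0, EMPTY),))
        assert len(simulate_population(1, proto, MDIA1_SETUP1)) == 1

    @pytest.mark.parametrize("bad_n", [0, -3, 2.5])
    def test_invalid_population_size(self, bad_n):
        proto = FlowProtocol(((10.0, EMPTY),))
        with pytest.raises(ValueError):
            simulate_population(bad_n, proto, MDIA1_SETUP1)


class TestExitTimeDistributions:
    def test_setup2_decay_mean_exit_time(self):
        proto = FlowProtocol(((5000.0, PA),))
        traces = simulate_population(
            20_000, proto, MDIA1_SETUP2, initial_state=S.BFC, master_seed=17
        )
        exits = np.array([tr.transitions[0][0] for tr in traces if tr.transitions])
        k = 2.02e-3 + 6.34e-3
        assert exits.mean() == pytest.approx(1.0 / k, rel=0.03)

    def test_setup2_detachment_fraction_matches_partition(self):
        proto = FlowProtocol(((5000.0, PA),), anchor_mode=FORMIN_ANCHORED)
        traces = simulate_population(
            20_000, proto, MDIA1_SETUP2, initial_state=S.BFC, master_seed=19
        )
        # first resolution of the ternary complex: detached without ever
        # reaching BF (later spontaneous BF -> B release is a separate event)
        frac = np.mean(
            [tr.detached_at is not None and not tr.ever_visited(S.BF) for tr in traces]
        )
        _, f_bc = partition_fractions(2.02e-3, 6.34e-3)
        assert frac == pytest.approx(f_bc, abs=3 * math.sqrt(f_bc * (1 - f_bc) / 20_000))

    def test_exit_times_are_exponential(self, fmnl2_decay_exit_times):
        k = 4.7e-3 + 9.4e-3
        sample = fmnl2_decay_exit_times[:10_000]
        result = stats.kstest(sample, "expon", args=(0.0, 1.0 / k))
        assert result.pvalue > 0.01

    def test_branching_probability_within_three_binomial_se(self, fmnl2_decay_population):
        _, traces = fmnl2_decay_population
        went_bf = np.array([tr.ever_visited(S.BF) for tr in traces])
        f_bf, _ = partition_fractions(4.7e-3, 9.4e-3)
        se = math.sqrt(f_bf * (1 - f_bf) / len(went_bf))
        assert abs(went_bf.mean() - f_bf) < 3 * se

    def test_empirical_bf_appearance_cdf_converges_to_model(self, fmnl2_decay_population):
        _, traces = fmnl2_decay_population
        bf_times = np.sort(
            [
                next(t for t, _, to in tr.transitions if to is S.BF)
                for tr in traces
                if tr.ever_visited(S.BF)
            ]
        )
        grid = np.linspace(0.0, 1500.0, 400)
        empirical = np.searchsorted(bf_times, grid, side="right") / len(traces)
        model = bf_cdf(grid, 4.7e-3, 9.4e-3)
        assert np.max(np.abs(empirical - model)) < 0.01


def _handmade_trace(pause_start=20.0, pause_len=5.0, end=60.0):
    """BF growth, a ternary pause of given length, then resumed BF growth."""
    v = 44.2
    t0, t1 = pause_start, pause_start + pause_len
    times = np.array([0.0, t0, t1, end])
    lengths = np.array([0.0, v * t0, v * t0, v * t0 + v * (end - t1)])
    return FilamentTrace(
        filament_id=0,
        initial_state=S.BF,
        transitions=[(t0, S.BF, S.BFC), (t1, S.BFC, S.BF)],
        times=times,
        lengths=lengths,
        observed_until=end,
    )


class TestObserve:
    PROTO = FlowProtocol(((60.0, PA),))

    def test_noiseless_fine_sampling_recovers_transition_times(self):
        trace = _handmade_trace(pause_start=20.0, pause_len=15.0)
        rows = observe(
            trace, self.PROTO, MDIA1_SETUP1,
            frame_interval=0.02, length_noise_sd=0.0, min_pause=0.5, velocity_window=0.02,
        )
        events = {r["event_type"]: r["time_s"] for r in rows if not r["censored"]}
        assert events["arrest"] == pytest.approx(20.0, abs=0.1)
        assert events["resume_fast"] == pytest.approx(35.0, abs=0.1)

    def test_pause_below_detection_limit_is_missed(self):
        trace = _handmade_trace(pause_start=20.0, pause_len=5.0)
        rows = observe(
            trace, self.PROTO, MDIA1_SETUP1,
            frame_interval=1 / 3, length_noise_sd=0.0, min_pause=10.0,
        )
        assert all(r["event_type"] != "arrest" for r in rows)

    def test_event_free_trace_yields_one_censored_row(self):
        proto = FlowProtocol(((120.0, EMPTY),))
        trace = simulate_filament(proto, MDIA1_SETUP1, initial_state=S.B, rng_seed=1)
        rows = observe(trace, proto, MDIA1_SETUP1, length_noise_sd=0.0)
        assert len(rows) == 1
        assert rows[0]["censored"] is True
        assert rows[0]["time_s"] == pytest.approx(120.0)

    def test_event_times_relative_to_segment_start(self):
        expo = SolutionCondition(formin=0.04, label="expo")
        proto = FlowProtocol(((30.0, expo), (200.0, PA)))
        trace = FilamentTrace(
            filament_id=0,
            initial_state=S.BC,
            transitions=[(10.0, S.BC, S.BFC), (80.0, S.BFC, S.BF)],
            times=np.array([0.0, 30.0, 80.0, 230.0]),
            lengths=np.array([0.0, 0.0, 0.0, 44.2 * 150.0]),
            observed_until=230.0,
        )
        rows = observe(trace, proto, MDIA1_SETUP1, length_noise_sd=0.0)
        resumes = [r for r in rows if r["event_type"] == "resume_fast"]
        assert len(resumes) == 1
        assert resumes[0]["condition_label"] == "pa"
        assert resumes[0]["time_s"] == pytest.approx(50.0, abs=2.0)

    def test_population_table_columns_and_determinism(self):
        proto = FlowProtocol(((400.0, PA),))
        traces = simulate_population(30, proto, MDIA1_SETUP2, initial_state=S.BFC, master_seed=4)
        t1 = observe_population(traces, proto, MDIA1_SETUP2, seed=5)
        t2 = observe_population(traces, proto, MDIA1_SETUP2, seed=5)
        assert list(t1.columns) == [
            "filament_id", "condition_label", "event_type", "time_s", "censored",
        ]
        assert t1.equals(t2)
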