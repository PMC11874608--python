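"""Tests for the staircase machinery and position-perturbed displays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coordlearn import (
    InvalidParameterError,
    ObserverModel,
    OscillatorParams,
    StaircaseConfig,
    StaircaseError,
    estimate_threshold,
    generate_perturbed_display,
    run_2afc_session,
    score_trial,
    staircase_init,
    staircase_update,
)
from coordlearn.psychophysics import SessionLog


class TestStaircaseRules:
    def test_initial_state(self):
        cfg = StaircaseConfig()
        state = staircase_init(cfg)
        assert state.current_difference == 30.0
        assert state.mode == "initial_descent"
        assert state.reversals == ()
        assert not state.finished

    def test_step_down_size(self):
        # 54.88 % of the 10° up-step; quoted as 5.48° (truncated)
        assert StaircaseConfig().step_down == pytest.approx(5.488)
        assert abs(StaircaseConfig().step_down - 5.48) < 0.01

    def test_initial_descent_steps_down_on_correct(self):
        cfg = StaircaseConfig()
        state = staircase_update(staircase_init(cfg), True, cfg)
        assert state.current_difference == pytest.approx(30.0 - cfg.step_down)
        assert state.mode == "initial_descent"

    def test_first_error_starts_updown_with_reversal(self):
        cfg = StaircaseConfig()
        state = staircase_update(staircase_init(cfg), False, cfg)
        assert state.mode == "updown"
        assert state.reversals == (30.0,)
        assert state.current_difference == pytest.approx(40.0)

    def test_two_consecutive_correct_needed_for_down(self):
        cfg = StaircaseConfig()
        state = staircase_update(staircase_init(cfg), False, cfg)  # -> updown @40
        one = staircase_update(state, True, cfg)
        assert one.current_difference == pytest.approx(40.0)  # no move yet
        two = staircase_update(one, True, cfg)
        assert two.current_difference == pytest.approx(40.0 - cfg.step_down)
        assert two.reversals == (30.0, 40.0)  # direction changed up -> down

    def test_difference_floored_at_one_degree(self):
        cfg = StaircaseConfig(initial_difference=2.0)
        state = staircase_update(staircase_init(cfg), True, cfg)
        assert state.current_difference == 1.0

    def test_update_after_finished_rejected(self):
        cfg = StaircaseConfig(n_reversal_stop=2)
        state = staircase_init(cfg)
        state = staircase_update(state, False, cfg)  # reversal 1
        state = staircase_update(state, True, cfg)
        state = staircase_update(state, True, cfg)   # down-step, reversal 2
        assert state.finished
        with pytest.raises(StaircaseError):
            staircase_update(state, True, cfg)


def replay_oracle(responses, cfg):
    """Brute-force reversal bookkeeping: track the level sequence, mark a
    reversal whenever the step direction changes (the initial descent's first
    error counts as the first reversal)."""
    level = cfg.initial_difference
    reversals = []
    last_dir = None
    in_descent = True
    cc = 0
    for correct in responses:
        if len(reversals) >= cfg.n_reversal_stop:
            break
        if in_descent:
            if correct:
                level = max(level - cfg.step_down, 1.0)
                last_dir = "down"
            else:
                reversals.append(level)
                level += cfg.step_up
                last_dir = "up"
                in_descent = False
        else:
            if correct:
                cc += 1
                if cc == 2:
                    if last_dir == "up":
                        reversals.append(level)
                    level = max(level - cfg.step_down, 1.0)
                    last_dir = "down"
                    cc = 0
            else:
                if last_dir == "down":
                    reversals.append(level)
                level += cfg.step_up
                last_dir = "up"
                cc = 0
    return reversals


class TestReversalBookkeeping:
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_replay_oracle(self, responses):
        cfg = StaircaseConfig(n_reversal_stop=4)
        state = staircase_init(cfg)
        for correct in responses:
            if state.finished:
                break
            state = staircase_update(state, correct, cfg)
        assert list(state.reversals) == replay_oracle(responses, cfg)
        assert state.finished == (len(state.reversals) >= cfg.n_reversal_stop)


class TestSession:
    def test_both_staircases_finish_with_eight_reversals(self):
        obs = ObserverModel(threshold_70=15.0)
        log = run_2afc_session(obs, seed=2)
        for state in log.states.values():
            assert state.finished
            assert len(state.reversals) == 8

    def test_seeded_sessions_identical(self):
        obs = ObserverModel(threshold_70=15.0)
        a = run_2afc_session(obs, seed=11)
        b = run_2afc_session(obs, seed=11)
        assert a.trials == b.trials

    def test_interleaving_uses_both_sides(self):
        obs = ObserverModel(threshold_70=15.0)
        log = run_2afc_session(obs, seed=3)
        sides = {t["side"] for t in log.trials}
        assert sides == {"below_90", "above_90"}


class TestThresholdEstimate:
    @staticmethod
    def _log_with(revs_a, revs_b):
        from coordlearn.psychophysics import StaircaseState
        mk = lambda revs: StaircaseState(current_difference=5.0, mode="updown",
                                         reversals=tuple(revs), finished=True)
        return SessionLog(trials=[], configs={},
                          states={"below_90": mk(revs_a), "above_90": mk(revs_b)})

    def test_hand_computed_mean_excluding_first(self):
        revs = [30, 20, 25, 15, 20, 10, 15, 5]
        log = self._log_with(revs, revs)
        assert estimate_threshold(log) == pytest.approx(110 / 7)

    def test_mean_of_per_side_means(self):
        log = self._log_with([10] * 8, [20] * 8)
        assert estimate_threshold(log) == pytest.approx(15.0)

    def test_too_few_reversals_rejected(self):
        log = self._log_with([10], [20] * 8)
        with pytest.raises(StaircaseError):
            estimate_threshold(log)

    def test_unfinished_session_rejected(self):
        obs = ObserverModel(threshold_70=15.0)
        log = run_2afc_session(obs, seed=2)
        from dataclasses import replace
        log.states["below_90"] = replace(log.states["below_90"], finished=False)
        with pytest.raises(StaircaseError):
            estimate_threshold(log)


class TestPerturbedDisplay:
    def test_bottom_amplitude_is_half_top(self, osc):
        spec, _ = generate_perturbed_display(osc, 90.0, seed=4)
        top = np.array(spec.half_cycle_amplitudes_top)
        bottom = np.array(spec.half_cycle_amplitudes_bottom)
        assert np.allclose(bottom, 0.5 * top)
        assert top.size == 40  # 2 half-cycles per second x 20 s

    def test_amplitudes_vary_and_stay_in_bounds(self, osc):
        spec, _ = generate_perturbed_display(osc, 90.0, seed=4)
        top = np.array(spec.half_cycle_amplitudes_top)
        assert np.var(top) > 0.0
        assert np.all(top >= 0.25 * osc.amplitude) and np.all(top <= osc.amplitude)

    def test_mean_relative_phase_preserved(self, osc):
        """The perturbation must not destroy the variable it preserves."""
        _, trial = generate_perturbed_display(osc, 90.0, seed=8)
        series_mean = _mean_relative_phase(trial)
        assert series_mean == pytest.approx(90.0, abs=3.0)

    def test_degenerate_draw_matches_unperturbed(self, osc):
        # amplitude range collapsed to a single value: an ordinary display
        spec, trial = generate_perturbed_display(
            osc, 90.0, max_amplitude=0.25 * osc.amplitude, seed=0)
        assert np.allclose(np.array(spec.half_cycle_amplitudes_top),
                           0.25 * osc.amplitude)
        t = osc.time_grid()
        expected = 0.25 * osc.amplitude * np.sin(osc.omega * t)
        assert np.allclose(trial.left_position, expected, atol=1e-9)

    def test_too_short_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_perturbed_display(OscillatorParams(duration=0.6), 90.0, seed=0)

    def test_bad_amplitude_rejected(self, osc):
        with pytest.raises(InvalidParameterError):
            generate_perturbed_display(osc, 90.0, max_amplitude=-1.0, seed=0)


def _mean_relative_phase(trial):
    from coordlearn import continuous_phase, preprocess_trajectory, relative_phase_series
    sr = trial.sample_rate
    lp = continuous_phase(preprocess_trajectory(trial.left_position, sr))
    rp = continuous_phase(preprocess_trajectory(trial.right_position, sr))
    return float(np.mean(relative_phase_series(lp, rp, trial.target_phase)
                         .relative_phase))
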