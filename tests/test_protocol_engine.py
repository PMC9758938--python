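"""Protocol compilation and closed-loop controller tests."""

import numpy as np
import pytest

import photobeam as pb
from photobeam.monitor_data import COLOR_CODE, ValidationError
from photobeam.protocol_engine import (
    LEFT,
    RIGHT,
    ClosedLoopResult,
    controller_step,
    run_closed_loop,
    zone_step,
)


def off_pulses(log, pulse_ms=1000):
    """(start_s, duration_ms) of every lights-off pulse in a compiled log."""
    events = sorted(log.events, key=lambda e: e.time_ms)
    pulses = []
    for i, ev in enumerate(events):
        if ev.color is pb.Color.OFF and ev.time_ms > 0:
            nxt = next(e for e in events[i + 1:] if e.tubes & ev.tubes)
            pulses.append((ev.time_ms // 1000, nxt.time_ms - ev.time_ms))
    return pulses


class TestCompileProtocol:
    def test_darkness_protocol_six_pulses_half_hour_apart(self):
        """Constant white for 30 min then 1-s darkness every 30 min, six
        trials over 3 h."""
        log = pb.compile_protocol(pb.darkness_protocol())
        assert log.events[0].time_ms == 0
        assert log.events[0].color is pb.Color.WHITE
        pulses = off_pulses(log)
        assert [t for t, _ in pulses] == [1800, 3600, 5400, 7200, 9000, 10800]
        assert all(dur == 1000 for _, dur in pulses)

    @pytest.mark.parametrize("iti_s,expected", [(300, 24), (60, 120)])
    def test_two_hour_session_pulse_counts(self, iti_s, expected):
        """2 h of stimulation yields 24 pulses at 5-min ITI, 120 at 1-min."""
        n = 7200 // iti_s
        log = pb.compile_protocol(pb.darkness_protocol(n_trials=n, iti_s=iti_s))
        assert len(off_pulses(log)) == expected

    def test_ld_12_12_over_48h_produces_four_toggles(self):
        log = pb.compile_protocol(pb.ld_protocol(48 * 3600, phase_h=0.0))
        seq = [(e.time_ms, e.color) for e in log.events]
        h = 3_600_000
        assert seq == [(0, pb.Color.WHITE), (12 * h, pb.Color.OFF),
                       (24 * h, pb.Color.WHITE), (36 * h, pb.Color.OFF)]

    def test_ld_phase_offset_shifts_boundaries(self):
        log = pb.compile_protocol(pb.ld_protocol(24 * 3600, phase_h=2.0))
        seq = [(e.time_ms / 3_600_000, e.color) for e in log.events]
        assert seq == [(0.0, pb.Color.WHITE), (10.0, pb.Color.OFF),
                       (22.0, pb.Color.WHITE)]

    def test_deterministic_and_idempotent(self):
        spec = pb.darkness_protocol(n_trials=4, iti_s=600)
        assert pb.compile_protocol(spec).events == \
            pb.compile_protocol(spec).events

    def test_illuminated_time_conservation(self):
        """Total lit time equals duration minus total off-pulse time."""
        spec = pb.darkness_protocol()
        log = pb.compile_protocol(spec)
        codes = log.color_codes(1, spec.duration_s)
        off_seconds = int(np.sum(codes == COLOR_CODE[pb.Color.OFF]))
        assert off_seconds == spec.stimuli.n_trials  # 1 s per pulse
        assert spec.duration_s - off_seconds == int(
            np.sum(codes != COLOR_CODE[pb.Color.OFF]))

    def test_pulse_train_past_duration_rejected(self):
        with pytest.raises(ValidationError):
            pb.ProtocolSpec(name="bad", duration_s=3600, habituation_s=1800,
                            stimuli=pb.PulseTrain(first_at_s=1800, iti_s=1800,
                                                  n_trials=2))

    def test_incompatible_blocks_rejected(self):
        with pytest.raises(ValidationError):
            pb.ProtocolSpec(name="bad", duration_s=7200, habituation_s=0,
                            ld_cycle=pb.LDCycle(),
                            stimuli=pb.PulseTrain(10, 10, 1))
        with pytest.raises(ValidationError):
            pb.ProtocolSpec(name="bad", duration_s=7200, habituation_s=0,
                            feedback=pb.FeedbackRule(),
                            ld_cycle=pb.LDCycle())

    def test_yaml_round_trip(self, tmp_path):
        for spec in (pb.darkness_protocol(),
                     pb.ld_protocol(7200, phase_h=3.0),
                     pb.place_preference_protocol(3600, swap_at_s=1800)):
            path = tmp_path / "p.yaml"
            pb.protocol_engine.save_protocol(spec, str(path))
            assert pb.protocol_engine.load_protocol(str(path)) == spec


class TestControllerStep:
    rule = pb.FeedbackRule(boundary_beam=9, left_color=pb.Color.BLUE,
                           right_color=pb.Color.GREEN, swap_at_s=18000)

    def test_left_of_boundary_gets_left_color(self):
        zones, codes, cmds = controller_step(self.rule, np.array([3]), None, 0)
        assert zones[0] == LEFT
        assert codes[0] == COLOR_CODE[pb.Color.BLUE]

    def test_boundary_keeps_previous_zone(self):
        prev = np.array([RIGHT], dtype=np.int8)
        zones, codes, _ = controller_step(self.rule, np.array([9]), prev, 0)
        assert zones[0] == RIGHT
        assert codes[0] == COLOR_CODE[pb.Color.GREEN]

    def test_boundary_without_history_defaults_left(self):
        zones, _, _ = controller_step(self.rule, np.array([9]), None, 0)
        assert zones[0] == LEFT

    def test_swap_interchanges_zone_colors(self):
        """After the swap time the right zone presents the former left
        color (blue)."""
        _, codes_pre, _ = controller_step(self.rule, np.array([12]), None,
                                          17_999)
        _, codes_post, _ = controller_step(self.rule, np.array([12]), None,
                                           18_000)
        assert codes_pre[0] == COLOR_CODE[pb.Color.GREEN]
        assert codes_post[0] == COLOR_CODE[pb.Color.BLUE]

    def test_commands_only_for_changed_tubes(self):
        prev_colors = np.array([COLOR_CODE[pb.Color.BLUE]], dtype=np.int8)
        _, _, cmds = controller_step(self.rule, np.array([3]), None, 0,
                                     prev_colors)
        assert cmds == []

    def test_same_colors_rejected(self):
        with pytest.raises(ValidationError):
            pb.FeedbackRule(left_color=pb.Color.BLUE,
                            right_color=pb.Color.BLUE)


class ScriptedStepper:
    """Fly stepper that replays a fixed position sequence."""

    def __init__(self, positions):
        self.positions = np.asarray(positions)
        self.n_flies = self.positions.shape[0]
        self._t = -1

    def current_positions(self):
        return self.positions[:, 0]

    def step(self, color_codes, t_s):
        self._t = t_s
        return self.positions[:, t_s]


class TestRunClosedLoop:
    def test_immobile_fly_single_command_constant_left_zone(self):
        spec = pb.place_preference_protocol(duration_s=100, habituation_s=0)
        stepper = ScriptedStepper(np.full((1, 100), 2))
        result = run_closed_loop(spec, stepper)
        assert len(result.stimulus_log) == 1
        ev = result.stimulus_log.events[0]
        assert ev.time_ms == 0 and ev.color is pb.Color.BLUE
        assert np.all(result.zones == LEFT)

    def test_single_crossing_two_commands(self):
        positions = np.concatenate([np.full(50, 2), np.full(50, 15)])[None, :]
        spec = pb.place_preference_protocol(duration_s=100, habituation_s=0)
        result = run_closed_loop(spec, ScriptedStepper(positions))
        assert len(result.stimulus_log) == 2
        colors = [e.color for e in result.stimulus_log.events]
        assert colors == [pb.Color.BLUE, pb.Color.GREEN]
        # one-tick latency: the green command comes the second AFTER the
        # crossing second
        assert result.stimulus_log.events[1].time_ms == 51_000

    def test_one_tick_latency_contract_random_walk(self, rng):
        """For every second t >= 1 the logged color equals the rule color of
        the zone occupied at t - 1 (brute-force recheck from the log)."""
        T = 300
        positions = np.clip(
            np.cumsum(rng.integers(-2, 3, size=(4, T)), axis=1) + 9, 1, 17)
        spec = pb.place_preference_protocol(duration_s=T, habituation_s=0,
                                            n_tubes=4)
        result = run_closed_loop(spec, ScriptedStepper(positions))
        rule = spec.feedback
        for i in range(4):
            codes = result.stimulus_log.color_codes(i + 1, T)
            for t in range(1, T):
                zone = result.zones[i, t - 1]
                left_c, right_c = rule.zone_colors(t)
                expect = left_c if zone == LEFT else right_c
                assert codes[t] == COLOR_CODE[expect], (i, t)

    def test_requires_feedback(self):
        with pytest.raises(ValidationError):
            run_closed_loop(pb.darkness_protocol(), ScriptedStepper(
                np.full((1, 10), 2)))
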