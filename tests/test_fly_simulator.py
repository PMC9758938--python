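"""Generative model tests: kinematics, startle dynamics, cohorts,
invariants."""

import math

import numpy as np
import pytest

import photobeam as pb
from photobeam.fly_simulator import CohortSimulator, _displace
from photobeam.monitor_data import COLOR_CODE, UsageError, ValidationError

WHITE = COLOR_CODE[pb.Color.WHITE]
OFF = COLOR_CODE[pb.Color.OFF]
GEOM = pb.DEFAULT_GEOMETRY


class TestDisplacement:
    def test_beam3_to_beam7_counts_four_crossings(self):
        """Travelling from the beam-3 coordinate onto the beam-7 coordinate
        interrupts beams 4, 5, 6 and 7."""
        x0 = np.array([GEOM.beam_x(3)])
        dx = np.array([GEOM.beam_x(7) - GEOM.beam_x(3)])
        _, cross, pos = _displace(x0, dx, np.array([3]), GEOM)
        assert cross[0] == 4
        assert pos[0] == 7

    def test_no_move_no_crossings(self):
        x0 = np.array([33.0])
        _, cross, pos = _displace(x0, np.array([0.0]), np.array([7]), GEOM)
        assert cross[0] == 0 and pos[0] == 7

    def test_reflection_counts_both_path_legs(self):
        """A path that bounces off the near wall crosses the beams below the
        start twice (down and back up)."""
        x0 = np.array([GEOM.beam_x(2) + 1.0])  # just above beam 2
        dx = np.array([-(x0[0] + GEOM.beam_x(3) + 0.5)])  # reflect up past 3
        x1, cross, pos = _displace(x0, dx, np.array([2]), GEOM)
        # down: crosses beams 2, 1; up: crosses 1, 2, 3
        assert cross[0] == 5
        assert pos[0] == 3
        assert 0 <= x1[0] <= GEOM.tube_length

    def test_displacement_invariant_over_random_steps(self, rng):
        x = rng.uniform(0, GEOM.tube_length, 2000)
        pos = np.asarray(GEOM.nearest_beam(x))
        for _ in range(50):
            dx = rng.normal(0, 8.0, 2000)
            x_new, cross, pos_new = _displace(x, dx, pos, GEOM)
            assert np.all(cross >= np.abs(pos_new - pos))
            x, pos = x_new, pos_new


class TestStepAndStartle:
    def test_immobile_params_never_move(self):
        cohort = [pb.FlyParams(p_move=0.0, startle_gain=0.0)]
        res = pb.simulate_session(pb.darkness_protocol(n_trials=2, iti_s=120,
                                                       habituation_s=60),
                                  cohort, seed=1)
        tr = res.traces[0]
        assert np.all(tr.counts == 0)
        assert np.all(tr.position == tr.position[0])

    def test_movement_fraction_matches_independent_oracle(self, rng):
        """Across 10^5 fly-seconds at p_move = 0.3 the fraction of seconds
        with crossings matches an independently coded scalar simulation of
        the same kinematics (binomial movement, Gaussian step, uniform
        beams)."""
        n, T = 1000, 100
        cohort = [pb.FlyParams(p_move=0.3, startle_gain=0.0)] * n
        sim = CohortSimulator(cohort, GEOM, np.random.default_rng(7))
        hits_engine = 0
        for t in range(T):
            sim.step(WHITE, t)
            hits_engine += int(np.sum(sim.last_crossings > 0))
        frac_engine = hits_engine / (n * T)

        # independent oracle: same model, separate scalar implementation
        d = GEOM.spacing
        nb = GEOM.n_beams
        L = GEOM.tube_length
        oracle_rng = np.random.default_rng(8)
        hits = 0
        total = 0
        x = oracle_rng.uniform(0.05 * L, 0.95 * L)
        for _ in range(50_000):
            total += 1
            if oracle_rng.random() < 0.3:
                step = oracle_rng.normal(0, 1.2 * d)
                raw = x + step
                x1 = -raw if raw < 0 else (2 * L - raw if raw > L else raw)
                lo, hi = (x, x1) if x1 > x else (x1, x)
                crossed = sum(1 for k in range(1, nb + 1)
                              if lo < k * d <= hi or lo <= k * d < hi)
                if raw < 0 or raw > L:  # reflected legs double-cross
                    crossed = (sum(1 for k in range(1, nb + 1) if k * d < x)
                               + sum(1 for k in range(1, nb + 1) if k * d < x1)
                               ) if raw < 0 else \
                              (sum(1 for k in range(1, nb + 1) if k * d > x)
                               + sum(1 for k in range(1, nb + 1) if k * d > x1))
                if crossed > 0:
                    hits += 1
                x = x1
        frac_oracle = hits / total
        # both estimates of P(crossings > 0) agree within Monte-Carlo error
        se = math.sqrt(frac_oracle * (1 - frac_oracle) / total
                       + frac_engine * (1 - frac_engine) / (n * T))
        assert abs(frac_engine - frac_oracle) < 4 * se

    def test_first_stimulus_full_gain_and_kappa_one_no_habituation(self):
        p = pb.FlyParams(startle_gain=0.4, habit_decay=1.0)
        s0 = pb.FlyState(x=45.0, position=9)
        s1 = pb.apply_lights_off(s0, p)
        assert s1.effective_beta == pytest.approx(0.4)
        # kappa = 1: the tenth stimulus still triggers the full gain
        s = s1
        for _ in range(9):
            s = pb.apply_lights_off(s, p)
        assert s.effective_beta == pytest.approx(0.4)

    def test_habituation_recursion_matches_closed_form(self):
        """Effective gain before stimulus m follows the load recursion
        N_m = (N_{m-1} + 1) * r^T with r = exp(-1/tau_rec)."""
        p = pb.FlyParams(startle_gain=0.5, habit_decay=0.7,
                         habit_recovery=600.0)
        iti = 60
        relax = math.exp(-1.0 / 600.0)
        state = pb.FlyState(x=45.0, position=9)
        load = 0.0
        rng = np.random.default_rng(0)
        for m in range(12):
            state = pb.apply_lights_off(state, p)
            assert state.effective_beta == pytest.approx(0.5 * 0.7 ** load)
            for _ in range(iti):
                state, _, _ = pb.step_fly(state, p, pb.Color.WHITE, rng)
            load = (load + 1.0) * relax ** iti

    def test_short_iti_desensitizes_more_than_long_iti(self):
        """kappa = 0.7, tau_rec = 600 s: mean effective gain over 24 stimuli
        at 1-min ITI is below the mean over 4 stimuli at 5-min ITI."""
        def mean_gain(iti_s, n_stim, kappa=0.7, tau_rec=600.0, beta=1.0):
            relax = math.exp(-iti_s / tau_rec)
            load, gains = 0.0, []
            for _ in range(n_stim):
                gains.append(beta * kappa ** load)
                load = (load + 1.0) * relax
            return np.mean(gains)

        assert mean_gain(60, 24) < mean_gain(300, 4)

    def test_ld_cycle_modulates_activity_by_phase_factors(self):
        """Mean counts in light vs dark approach the light/dark factor
        ratio."""
        spec = pb.ld_protocol(duration_s=48 * 3600, phase_h=0.0, n_tubes=20)
        cohort = [pb.FlyParams(p_move=0.2, startle_gain=0.0,
                               light_factor=1.0, dark_factor=0.5)] * 20
        pop = pb.simulate_population(spec, cohort, seed=77)
        light = pb.zt_hours(np.arange(spec.duration_s), 0.0) < 12
        ratio = pop.counts[:, light].mean() / pop.counts[:, ~light].mean()
        assert ratio == pytest.approx(2.0, rel=0.06)


class TestSimulateSession:
    def test_same_seed_bit_identical(self):
        spec = pb.darkness_protocol(n_trials=2, iti_s=300, habituation_s=300)
        cohort = pb.make_cohort(pb.preset("csorc"), 8, pb.Heterogeneity(),
                                seed=3)
        a = pb.simulate_session(spec, cohort, seed=5)
        b = pb.simulate_session(spec, cohort, seed=5)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.counts, tb.counts)
            assert np.array_equal(ta.position, tb.position)
        assert a.stimulus_log.events == b.stimulus_log.events

    def test_cohort_larger_than_monitor_rejected(self):
        spec = pb.darkness_protocol(n_trials=1, iti_s=60, habituation_s=30)
        with pytest.raises(UsageError):
            pb.simulate_session(spec, [pb.FlyParams()] * 17, seed=0)

    def test_traces_satisfy_displacement_invariant(self):
        """Every simulator-produced trace obeys counts >= |dposition| under
        assorted protocols and parameter sets."""
        protocols = [
            pb.darkness_protocol(n_trials=3, iti_s=120, habituation_s=60),
            pb.ld_protocol(duration_s=7200, phase_h=6.0),
            pb.place_preference_protocol(duration_s=1200, swap_at_s=600),
        ]
        params = [pb.preset("csorc"), pb.preset("w1118"),
                  pb.preset("innate_averse"), pb.preset("blue_learner"),
                  pb.FlyParams(p_move=0.9, step_scale=4.0, startle_gain=0.8)]
        for k, spec in enumerate(protocols):
            res = pb.simulate_session(spec, params * 2, seed=100 + k)
            for tr in res.traces:
                assert len(tr.displacement_violations()) == 0

    def test_stimulus_log_matches_compiled_protocol(self):
        spec = pb.darkness_protocol(n_trials=2, iti_s=300, habituation_s=300)
        res = pb.simulate_session(spec, [pb.FlyParams()] * 2, seed=9)
        assert res.stimulus_log.events == pb.compile_protocol(spec).events


class TestMakeCohort:
    def test_heterogeneity_off_gives_identical_copies(self):
        template = pb.preset("w1118")
        cohort = pb.make_cohort(template, 5, None, seed=1)
        assert cohort == [template] * 5

    def test_mixture_fractions_recovered_at_n_1000(self):
        """Sign mixture (0.59 none, 0.08 negative, 0.33 positive) is
        recovered within a 3-sigma binomial interval."""
        template = pb.FlyParams(startle_gain=0.4,
                                startle_sign_mix=(0.59, 0.08))
        cohort = pb.make_cohort(template, 1000, pb.Heterogeneity(), seed=11)
        gains = np.array([p.startle_gain for p in cohort])
        for frac, want in [(np.mean(gains == 0), 0.59),
                           (np.mean(gains < 0), 0.08),
                           (np.mean(gains > 0), 0.33)]:
            se = math.sqrt(want * (1 - want) / 1000)
            assert abs(frac - want) < 3 * se

    def test_seeded_cohort_reproducible(self):
        t = pb.preset("csorc")
        assert pb.make_cohort(t, 20, pb.Heterogeneity(), seed=4) == \
            pb.make_cohort(t, 20, pb.Heterogeneity(), seed=4)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValidationError):
            pb.Heterogeneity(sign_mix=(0.8, 0.5))
        with pytest.raises(ValidationError):
            pb.FlyParams(startle_sign_mix=(-0.1, 0.2))
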