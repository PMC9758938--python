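"""Agent-based generative model of single-fly locomotion in a monitored tube.

Each fly is a 1-D random walker with reflecting walls.  Every second it
moves with probability ``clamp(p_move * phase_factor + effective_beta, 0, 1)``
and, when moving, is displaced by a zero-mean Gaussian step (sd
``step_scale`` beam widths) plus deterministic drift terms:

* attraction toward the nearest food-plugged tube end (``food_bias``),
* extra drift toward the ethanol end during the dark phase
  (``ethanol_dark_boost``),
* innate drift away from a blue-illuminated zone (``blue_aversion``), and
* a learned, position-bound bias away from regions previously experienced
  under blue light (``learn_rate``), which is what makes a zone swap degrade
  the learned preference to chance.

A 1-s lights-off event sets ``effective_beta`` to
``startle_gain * habit_decay ** habituation_load``; the load increments per
stimulus and relaxes toward zero with time constant ``habit_recovery``, so
closely spaced stimuli desensitize the response more than widely spaced
ones.  The increment itself decays with time constant ``startle_tau``
(seconds), producing elevated activity for a few tens of seconds after each
stimulus.

Beam crossings are counted geometrically: every beam coordinate on the
(possibly wall-reflected) path travelled within the second counts one
crossing, and the reported beam position is the beam last crossed — exactly
what a multi-beam monitor sees.  This construction guarantees the trace
invariant ``counts[k] >= |position[k] - position[k-1]]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .monitor_data import (
    COLOR_CODE,
    ActivityTrace,
    BeamGeometry,
    Color,
    DEFAULT_GEOMETRY,
    StimulusLog,
    UsageError,
    ValidationError,
)
from . import protocol_engine
from .protocol_engine import ProtocolSpec, run_closed_loop

__all__ = [
    "FlyParams",
    "FlyState",
    "Heterogeneity",
    "make_cohort",
    "step_fly",
    "apply_lights_off",
    "simulate_session",
    "simulate_population",
    "SessionResult",
    "PopulationResult",
    "CohortSimulator",
    "LINE_PRESETS",
    "preset",
]

_OFF = COLOR_CODE[Color.OFF]
_BLUE = COLOR_CODE[Color.BLUE]
_WHITE = COLOR_CODE[Color.WHITE]

_DEFAULT_T0 = datetime(2022, 1, 1, 8, 0, 0)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlyParams:
    """Generative parameters of one simulated fly.

    Units: probabilities per second; displacements in beam widths (the mean
    beam-to-beam distance); time constants in seconds.  ``startle_gain`` may
    be negative for a freezing (negative) responder and zero for a
    non-responder; ``startle_sign_mix = (p_none, p_negative)`` gives the
    mixture used by :func:`make_cohort` when drawing heterogeneous cohorts.
    """

    p_move: float = 0.25
    step_scale: float = 1.2
    startle_gain: float = 0.35
    startle_tau: float = 12.0
    startle_sign_mix: tuple = (0.0, 0.0)
    habit_decay: float = 1.0
    habit_recovery: float = 600.0
    light_factor: float = 1.0
    dark_factor: float = 0.5
    food_bias: float = 0.0
    ethanol_dark_boost: float = 0.0
    blue_aversion: float = 0.0
    learn_rate: float = 0.0
    learn_cap: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_move <= 1.0:
            raise ValidationError("p_move must lie in [0, 1]")
        if self.startle_tau <= 0 or self.habit_recovery <= 0:
            raise ValidationError("startle_tau and habit_recovery must be > 0")
        if not 0.0 <= self.habit_decay <= 1.0:
            raise ValidationError("habit_decay (kappa) must lie in [0, 1]")
        p0, pneg = self.startle_sign_mix
        if min(p0, pneg) < 0 or p0 + pneg > 1.0 + 1e-12:
            raise ValidationError("startle_sign_mix weights must be a "
                                  "sub-probability vector")
        if self.step_scale < 0 or self.light_factor < 0 or self.dark_factor < 0:
            raise ValidationError("scales and factors must be non-negative")


#: Cohort presets loosely emulating the three fly lines of the startle
#: assays: a weakly active, mostly unresponsive red-eyed wild type; a more
#: active, highly responsive white-eyed line that also desensitizes at long
#: inter-trial intervals; and a fragile-X model whose increase/decrease
#: responses balance out to a near-zero mean delta.
LINE_PRESETS = {
    "csorc": FlyParams(p_move=0.06, step_scale=1.2, startle_gain=0.45,
                       startle_tau=12.0, startle_sign_mix=(0.59, 0.08),
                       habit_decay=0.75, habit_recovery=600.0),
    "w1118": FlyParams(p_move=0.12, step_scale=1.2, startle_gain=0.60,
                       startle_tau=12.0, startle_sign_mix=(0.31, 0.12),
                       habit_decay=0.60, habit_recovery=1200.0),
    "fragile_x": FlyParams(p_move=0.12, step_scale=1.2, startle_gain=0.50,
                           startle_tau=12.0, startle_sign_mix=(0.20, 0.40),
                           habit_decay=0.75, habit_recovery=600.0),
    "ethanol_assay": FlyParams(p_move=0.10, step_scale=1.2, startle_gain=0.0,
                               food_bias=0.06, ethanol_dark_boost=0.04,
                               dark_factor=0.5),
    "innate_averse": FlyParams(p_move=0.25, step_scale=1.2, startle_gain=0.0,
                               blue_aversion=0.4),
    "blue_learner": FlyParams(p_move=0.25, step_scale=1.2, startle_gain=0.0,
                              blue_aversion=0.0, learn_rate=2e-4,
                              learn_cap=0.3),
}


def preset(name: str) -> FlyParams:
    """Return a copy of a named line preset."""
    try:
        return LINE_PRESETS[name]
    except KeyError:
        raise UsageError(f"unknown preset {name!r}; available: "
                         f"{sorted(LINE_PRESETS)}") from None


@dataclass(frozen=True)
class Heterogeneity:
    """Between-fly variability applied by :func:`make_cohort`.

    ``sign_mix`` overrides the template's responder mixture
    ``(p_non_responder, p_negative)``; remaining mass is positive
    responders.  ``p_move_cv`` and ``gain_cv`` add mean-preserving lognormal
    jitter to baseline activity and startle gain.
    """

    sign_mix: Optional[tuple] = None
    p_move_cv: float = 0.4
    gain_cv: float = 0.0
    negative_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sign_mix is not None:
            p0, pneg = self.sign_mix
            if min(p0, pneg) < 0 or p0 + pneg > 1.0 + 1e-12:
                raise ValidationError("invalid responder mixture weights")
        if self.p_move_cv < 0 or self.gain_cv < 0:
            raise ValidationError("coefficients of variation must be >= 0")


def _lognormal_jitter(rng: np.random.Generator, mean: float, cv: float,
                      n: int) -> np.ndarray:
    if cv <= 0 or mean == 0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


def make_cohort(template: FlyParams, n: int,
                heterogeneity: Optional[Heterogeneity] = None,
                seed: int = 0) -> list:
    """Draw ``n`` per-fly parameter sets from a template.

    With ``heterogeneity=None`` the cohort is ``n`` identical copies.
    Otherwise each fly's responder class (non/negative/positive) is drawn
    from the sign mixture and its baseline activity and gain are jittered.
    Deterministic under ``seed``.
    """
    if n < 1:
        raise UsageError("cohort size must be >= 1")
    if heterogeneity is None:
        return [template] * n
    rng = np.random.default_rng(seed)
    mix = (heterogeneity.sign_mix if heterogeneity.sign_mix is not None
           else template.startle_sign_mix)
    p0, pneg = mix
    u = rng.random(n)
    # class 0 = non-responder, 1 = negative, 2 = positive
    cls = np.where(u < p0, 0, np.where(u < p0 + pneg, 1, 2))
    p_moves = np.clip(_lognormal_jitter(rng, template.p_move,
                                        heterogeneity.p_move_cv, n), 0.0, 1.0)
    gains = _lognormal_jitter(rng, abs(template.startle_gain),
                              heterogeneity.gain_cv, n)
    cohort = []
    for i in range(n):
        if cls[i] == 0:
            g = 0.0
        elif cls[i] == 1:
            g = -gains[i] * heterogeneity.negative_scale
        else:
            g = gains[i]
        cohort.append(replace(template, p_move=float(p_moves[i]),
                              startle_gain=float(g), startle_sign_mix=mix))
    return cohort


# ---------------------------------------------------------------------------
# Geometric displacement: reflecting walls, crossing count, last beam
# ---------------------------------------------------------------------------


def _displace(x: np.ndarray, dx: np.ndarray, position: np.ndarray,
              geometry: BeamGeometry):
    """Apply displacements with reflecting walls.

    Returns ``(x_new, crossings, position_new)`` where ``crossings`` counts
    every beam coordinate on the travelled (possibly reflected) path and
    ``position_new`` is the beam last crossed (unchanged if none).
    """
    bp = np.asarray(geometry.beam_positions)
    L = geometry.tube_length
    nb = geometry.n_beams
    dx = np.clip(dx, -0.95 * L, 0.95 * L)
    raw = x + dx
    refl_low = raw < 0
    refl_high = raw > L
    x1 = np.where(refl_low, -raw, np.where(refl_high, 2 * L - raw, raw))
    x1 = np.clip(x1, 0.0, L)

    f0 = np.searchsorted(bp, x, side="right")
    f1 = np.searchsorted(bp, x1, side="right")
    cross = np.where(refl_low, f0 + f1,
                     np.where(refl_high, (nb - f0) + (nb - f1),
                              np.abs(f1 - f0)))

    # Beam last crossed, by travel direction of the final path leg.
    right = dx > 0
    plain = np.where(right, f1, f1 + 1)
    low = np.where(f1 > 0, f1, 1)                 # final leg moves right
    high = np.where(f1 < nb, f1 + 1, nb)          # final leg moves left
    last = np.where(refl_low, low, np.where(refl_high, high, plain))
    last = np.clip(last, 1, nb)
    position_new = np.where(cross > 0, last, position)
    return x1, cross.astype(np.int64), position_new.astype(np.int64)


# ---------------------------------------------------------------------------
# Vectorized cohort engine
# ---------------------------------------------------------------------------


class CohortSimulator:
    """Steps a whole cohort of flies one second at a time.

    Implements the stepper interface consumed by
    :func:`photobeam.protocol_engine.run_closed_loop`; fly ``i`` occupies
    tube ``i + 1``.  All randomness comes from the supplied generator.
    """

    def __init__(self, cohort: Sequence[FlyParams], geometry: BeamGeometry,
                 rng: np.random.Generator,
                 blue_boundary_x: Optional[float] = None,
                 x0: Optional[np.ndarray] = None):
        self.geometry = geometry
        self.rng = rng
        self.n_flies = n = len(cohort)
        d = geometry.spacing
        get = lambda attr: np.array([getattr(p, attr) for p in cohort],
                                    dtype=float)
        self.p_move = get("p_move")
        self.step_sd = get("step_scale") * d
        self.gain = get("startle_gain")
        self.tau_decay = np.exp(-1.0 / get("startle_tau"))
        self.kappa = get("habit_decay")
        self.rec_decay = np.exp(-1.0 / get("habit_recovery"))
        self.light_f = get("light_factor")
        self.dark_f = get("dark_factor")
        self.food_mm = get("food_bias") * d
        self.eth_mm = get("ethanol_dark_boost") * d
        self.blue_mm = get("blue_aversion") * d
        self.learn_rate = get("learn_rate")
        self.learn_cap = get("learn_cap")
        self._has_food = np.any(self.food_mm != 0)
        self._has_eth = np.any(self.eth_mm != 0)
        self._has_blue = np.any(self.blue_mm != 0)
        self._has_learn = np.any(self.learn_rate != 0)
        self.blue_boundary_x = blue_boundary_x

        if x0 is None:
            L = geometry.tube_length
            x0 = rng.uniform(0.05 * L, 0.95 * L, n)
        self.x = np.asarray(x0, dtype=float)
        self.position = np.asarray(geometry.nearest_beam(self.x), dtype=np.int64)
        self.eb = np.zeros(n)
        self.habit_load = np.zeros(n)
        self.av_left = np.zeros(n)
        self.av_right = np.zeros(n)
        self.prev_codes = np.full(n, _WHITE, dtype=np.int8)
        self.last_crossings = np.zeros(n, dtype=np.int64)

    def current_positions(self) -> np.ndarray:
        return self.position

    def step(self, color_codes, t_s: int) -> np.ndarray:
        """Advance one second under per-fly illumination ``color_codes``
        (scalar or length-n array of color codes)."""
        n = self.n_flies
        codes = np.broadcast_to(np.asarray(color_codes, dtype=np.int8), (n,))
        onset = (codes == _OFF) & (self.prev_codes != _OFF)
        if onset.any():
            triggered = self.gain * np.power(self.kappa, self.habit_load)
            self.eb = np.where(onset, triggered, self.eb)
            self.habit_load = self.habit_load + onset
        dark = codes == _OFF
        phase = np.where(dark, self.dark_f, self.light_f)
        p = np.clip(self.p_move * phase + self.eb, 0.0, 1.0)
        move = self.rng.random(n) < p

        drift = np.zeros(n)
        L = self.geometry.tube_length
        if self._has_food:
            drift += self.food_mm * np.where(self.x < 0.5 * L, -1.0, 1.0)
        if self._has_eth:
            drift += self.eth_mm * dark
        if self._has_blue or self._has_learn:
            bx = self.blue_boundary_x
            if bx is not None:
                blue_on = codes == _BLUE
                if self._has_blue:
                    drift += (self.blue_mm * np.sign(bx - self.x)) * blue_on
                if self._has_learn:
                    on_left = self.x < bx
                    inc = self.learn_rate * blue_on
                    self.av_left = np.minimum(self.av_left + inc * on_left,
                                              self.learn_cap)
                    self.av_right = np.minimum(self.av_right + inc * ~on_left,
                                               self.learn_cap)
                    drift += (self.av_left - self.av_right) * self.geometry.spacing

        dx = (self.rng.standard_normal(n) * self.step_sd + drift) * move
        self.x, self.last_crossings, self.position = _displace(
            self.x, dx, self.position, self.geometry)
        self.eb *= self.tau_decay
        self.habit_load *= self.rec_decay
        self.prev_codes = codes
        return self.position


# ---------------------------------------------------------------------------
# Single-fly functional API
# ---------------------------------------------------------------------------


@dataclass
class FlyState:
    """Mutable state of one simulated fly."""

    x: float
    position: int
    effective_beta: float = 0.0
    habit_load: float = 0.0
    aversion_left: float = 0.0
    aversion_right: float = 0.0
    stimulus_count: int = 0


def apply_lights_off(state: FlyState, params: FlyParams) -> FlyState:
    """Register a lights-off event: the startle increment is set to
    ``startle_gain * habit_decay ** habituation_load`` and the load rises by
    one (it relaxes back toward zero between stimuli during stepping)."""
    eb = params.startle_gain * params.habit_decay ** state.habit_load
    return replace(state, effective_beta=eb,
                   habit_load=state.habit_load + 1.0,
                   stimulus_count=state.stimulus_count + 1)


def step_fly(state: FlyState, params: FlyParams, light: Color,
             rng: np.random.Generator,
             geometry: BeamGeometry = DEFAULT_GEOMETRY,
             blue_boundary_x: Optional[float] = None):
    """Advance a single fly one second; returns
    ``(state', crossings, beam_position)``.

    Lights-off onsets must be registered separately via
    :func:`apply_lights_off` before the step of the stimulus second.
    """
    d = geometry.spacing
    dark = light is Color.OFF
    phase = params.dark_factor if dark else params.light_factor
    p = min(max(params.p_move * phase + state.effective_beta, 0.0), 1.0)
    move = rng.random() < p
    drift = 0.0
    av_left, av_right = state.aversion_left, state.aversion_right
    if params.food_bias:
        drift += params.food_bias * d * (-1.0 if state.x < geometry.tube_length / 2
                                         else 1.0)
    if params.ethanol_dark_boost and dark:
        drift += params.ethanol_dark_boost * d
    if blue_boundary_x is not None and light is Color.BLUE:
        if params.blue_aversion:
            drift += params.blue_aversion * d * math.copysign(
                1.0, blue_boundary_x - state.x)
        if params.learn_rate:
            if state.x < blue_boundary_x:
                av_left = min(av_left + params.learn_rate, params.learn_cap)
            else:
                av_right = min(av_right + params.learn_rate, params.learn_cap)
    if params.learn_rate:
        drift += (av_left - av_right) * d
    dx = (rng.standard_normal() * params.step_scale * d + drift) if move else 0.0
    x1, cross, pos = _displace(np.array([state.x]), np.array([dx]),
                               np.array([state.position]), geometry)
    new_state = replace(
        state, x=float(x1[0]), position=int(pos[0]),
        effective_beta=state.effective_beta * math.exp(-1.0 / params.startle_tau),
        habit_load=state.habit_load * math.exp(-1.0 / params.habit_recovery),
        aversion_left=av_left, aversion_right=av_right)
    return new_state, int(cross[0]), int(pos[0])


# ---------------------------------------------------------------------------
# Session-level drivers
# ---------------------------------------------------------------------------


@dataclass
class PopulationResult:
    """Raw matrices from a (possibly multi-monitor) cohort run."""

    counts: np.ndarray        # (n_flies, duration_s) int
    positions: np.ndarray     # (n_flies, duration_s) int
    stimulus_log: StimulusLog
    zones: Optional[np.ndarray]  # (n_flies, duration_s) or None
    t0: datetime
    zt0: float


@dataclass
class SessionResult:
    traces: list
    stimulus_log: StimulusLog
    zones: Optional[np.ndarray]


def simulate_population(spec: ProtocolSpec, cohort: Sequence[FlyParams],
                        seed: int, geometry: BeamGeometry = DEFAULT_GEOMETRY,
                        t0: datetime = _DEFAULT_T0,
                        zt0: Optional[float] = None) -> PopulationResult:
    """Simulate an arbitrary-size cohort (a multi-monitor batch).

    Fly ``i`` occupies tube ``i + 1``; the tube-count limit of a single
    physical monitor is not enforced here (see :func:`simulate_session`).
    Fully reproducible under ``seed``.
    """
    n = len(cohort)
    if n < 1:
        raise UsageError("cohort must contain at least one fly")
    if zt0 is None:
        zt0 = spec.ld_cycle.phase_h if spec.ld_cycle is not None else 0.0
    if spec.n_tubes < n:
        spec = replace(spec, n_tubes=n)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    duration = spec.duration_s

    boundary_x = None
    if spec.feedback is not None:
        spec.feedback.validate_geometry(geometry.n_beams)
        boundary_x = geometry.beam_x(spec.feedback.boundary_beam)
    sim = CohortSimulator(cohort, geometry, rng, blue_boundary_x=boundary_x)

    counts = np.empty((n, duration), dtype=np.int16)
    positions = np.empty((n, duration), dtype=np.int8)

    if spec.feedback is not None:
        recorder = _RecordingStepper(sim, counts, positions)
        result = run_closed_loop(spec, recorder)
        return PopulationResult(counts=counts, positions=positions,
                                stimulus_log=result.stimulus_log,
                                zones=result.zones, t0=t0, zt0=zt0)

    log = protocol_engine.compile_protocol(spec)
    tube_ids = range(1, n + 1)
    if log.uniform_across(tube_ids):
        col = log.color_codes(1, duration, initial=Color.WHITE)
        for t in range(duration):
            positions[:, t] = sim.step(col[t], t)
            counts[:, t] = sim.last_crossings
    else:
        mat = np.stack([log.color_codes(i, duration, initial=Color.WHITE)
                        for i in tube_ids])
        for t in range(duration):
            positions[:, t] = sim.step(mat[:, t], t)
            counts[:, t] = sim.last_crossings
    return PopulationResult(counts=counts, positions=positions,
                            stimulus_log=log, zones=None, t0=t0, zt0=zt0)


class _RecordingStepper:
    """Adapter that records counts/positions while the closed loop drives
    the cohort simulator."""

    def __init__(self, sim: CohortSimulator, counts: np.ndarray,
                 positions: np.ndarray):
        self.sim = sim
        self.n_flies = sim.n_flies
        self.counts = counts
        self.positions = positions

    def current_positions(self) -> np.ndarray:
        return self.sim.current_positions()

    def step(self, color_codes, t_s: int) -> np.ndarray:
        pos = self.sim.step(color_codes, t_s)
        self.counts[:, t_s] = self.sim.last_crossings
        self.positions[:, t_s] = pos
        return pos


def simulate_session(spec: ProtocolSpec, cohort: Sequence[FlyParams],
                     seed: int, geometry: BeamGeometry = DEFAULT_GEOMETRY,
                     t0: datetime = _DEFAULT_T0,
                     zt0: Optional[float] = None) -> SessionResult:
    """Simulate one monitor's session and package per-fly activity traces.

    The cohort may not exceed the monitor's tube count.  Same seed, same
    output, bit for bit.
    """
    if len(cohort) > geometry.n_tubes:
        raise UsageError(
            f"cohort of {len(cohort)} exceeds the monitor's "
            f"{geometry.n_tubes} tubes; split across monitors or use "
            f"simulate_population")
    pop = simulate_population(spec, cohort, seed, geometry=geometry, t0=t0,
                              zt0=zt0)
    traces = [
        ActivityTrace(fly_id=f"tube{i + 1:02d}", t0=pop.t0, zt0=pop.zt0,
                      counts=pop.counts[i], position=pop.positions[i])
        for i in range(len(cohort))
    ]
    return SessionResult(traces=traces, stimulus_log=pop.stimulus_log,
                         zones=pop.zones)
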