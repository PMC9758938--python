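"""Protocol compiler and per-second closed-loop illumination controller.

A protocol describes how the LEDs of a beam-monitored tube rack behave over
a session: an open-loop timeline (constant light, sudden-darkness pulse
trains, light:dark cycles) and/or a closed-loop rule that maps the fly's
current tube zone to an illumination color each second.

Open-loop protocols compile deterministically to a millisecond-resolution
:class:`~photobeam.monitor_data.StimulusLog`.  Closed-loop protocols are run
tick by tick against a fly stepper (usually the simulator): the position
read at the end of second ``t - 1`` decides the color applied during second
``t`` — a one-tick read→decide→write latency, mirroring a real rig.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Protocol, Sequence

import numpy as np
import yaml

from .monitor_data import (
    CODE_COLOR,
    COLOR_CODE,
    Color,
    StimulusEvent,
    StimulusLog,
    ValidationError,
)

__all__ = [
    "Segment",
    "PulseTrain",
    "LDCycle",
    "FeedbackRule",
    "ProtocolSpec",
    "compile_protocol",
    "zone_step",
    "controller_step",
    "run_closed_loop",
    "ClosedLoopResult",
    "load_protocol",
    "save_protocol",
    "darkness_protocol",
    "ld_protocol",
    "place_preference_protocol",
]

LEFT, RIGHT = 0, 1


@dataclass(frozen=True)
class Segment:
    """One open-loop timeline entry: ``color`` at ``intensity`` on the given
    tubes (None = all) during ``[start_ms, end_ms)``."""

    start_ms: int
    end_ms: int
    color: Color
    intensity: float = 1.0
    tubes: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValidationError("segment end_ms must exceed start_ms")


@dataclass(frozen=True)
class PulseTrain:
    """Repeated brief stimulus: ``n_trials`` pulses of ``color`` lasting
    ``pulse_ms``, the k-th starting at ``first_at_s + k * iti_s``."""

    first_at_s: int
    iti_s: int
    n_trials: int
    pulse_ms: int = 1000
    color: Color = Color.OFF

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.iti_s < 1:
            raise ValidationError("pulse train needs n_trials >= 1, iti_s >= 1")
        if self.pulse_ms < 1 or self.pulse_ms > self.iti_s * 1000:
            raise ValidationError("pulse_ms must lie in [1, iti_s * 1000]")

    def pulse_times_s(self) -> np.ndarray:
        return self.first_at_s + self.iti_s * np.arange(self.n_trials)


@dataclass(frozen=True)
class LDCycle:
    """Light:dark illumination schedule (white light vs darkness).

    ``phase_h`` is the Zeitgeber hour at session start; the lights are on
    whenever ``(elapsed_h + phase_h) mod period_h < light_h``.
    """

    period_h: float = 24.0
    light_h: float = 12.0
    phase_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.light_h < self.period_h:
            raise ValidationError("light_h must lie in (0, period_h)")

    def is_light(self, t_s) -> np.ndarray:
        h = np.asarray(t_s, dtype=float) / 3600.0
        return (h + self.phase_h) % self.period_h < self.light_h


@dataclass(frozen=True)
class FeedbackRule:
    """Closed-loop zone→color rule.

    The tube is split at ``boundary_beam``; beams below it are the left
    zone, beams above it the right zone, and a fly sitting exactly on the
    boundary keeps its previous zone (hysteresis, so the LEDs do not
    chatter).  At ``swap_at_s`` the two zone colors are interchanged.
    """

    boundary_beam: int = 9
    left_color: Color = Color.BLUE
    right_color: Color = Color.GREEN
    swap_at_s: Optional[int] = None
    tick_s: int = 1

    def __post_init__(self) -> None:
        if self.left_color == self.right_color:
            raise ValidationError("left_color and right_color must differ")
        if self.tick_s < 1:
            raise ValidationError("tick_s must be >= 1")

    def validate_geometry(self, n_beams: int) -> None:
        if not 1 < self.boundary_beam < n_beams:
            raise ValidationError(
                f"boundary_beam must lie strictly inside (1, {n_beams})")

    def zone_colors(self, t_s: float) -> tuple:
        """(left, right) colors in effect at session second ``t_s``."""
        if self.swap_at_s is not None and t_s >= self.swap_at_s:
            return self.right_color, self.left_color
        return self.left_color, self.right_color


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of a light protocol.

    Exactly one behavioural block — an open-loop timeline with optional
    pulse train, a light:dark cycle, or a closed-loop feedback rule — may be
    combined with the initial ``habituation_s`` of constant white light.
    """

    name: str
    duration_s: int
    habituation_s: int = 1800
    timeline: tuple = ()
    stimuli: Optional[PulseTrain] = None
    ld_cycle: Optional[LDCycle] = None
    feedback: Optional[FeedbackRule] = None
    n_tubes: int = 16

    def __post_init__(self) -> None:
        if self.duration_s < 1:
            raise ValidationError("duration_s must be >= 1")
        if not 0 <= self.habituation_s < self.duration_s:
            raise ValidationError("habituation_s must lie in [0, duration_s)")
        if self.ld_cycle is not None and self.stimuli is not None:
            raise ValidationError("ld_cycle and stimuli are mutually exclusive")
        if self.feedback is not None and (self.stimuli is not None
                                          or self.ld_cycle is not None):
            raise ValidationError(
                "feedback cannot be combined with stimuli or ld_cycle")
        if self.stimuli is not None:
            last_end_ms = (int(self.stimuli.pulse_times_s()[-1]) * 1000
                           + self.stimuli.pulse_ms)
            if last_end_ms > self.duration_s * 1000:
                raise ValidationError("pulse train extends past protocol duration")
        for seg in self.timeline:
            if seg.end_ms > self.duration_s * 1000:
                raise ValidationError("timeline segment extends past duration")

    @property
    def all_tubes(self) -> frozenset:
        return frozenset(range(1, self.n_tubes + 1))


# ---------------------------------------------------------------------------
# Convenience constructors for the study's protocols
# ---------------------------------------------------------------------------


def darkness_protocol(n_trials: int = 6, iti_s: int = 1800,
                      habituation_s: int = 1800, pulse_ms: int = 1000,
                      n_tubes: int = 16) -> ProtocolSpec:
    """Constant white light with 1-s sudden-darkness pulses.

    The default reproduces the 3-h startle session: 30 min habituation, then
    six lights-off pulses at 30-min intervals.
    """
    duration = habituation_s + iti_s * n_trials
    return ProtocolSpec(
        name=f"darkness-{n_trials}x{iti_s}s",
        duration_s=duration,
        habituation_s=habituation_s,
        stimuli=PulseTrain(first_at_s=habituation_s, iti_s=iti_s,
                           n_trials=n_trials, pulse_ms=pulse_ms),
        n_tubes=n_tubes,
    )


def ld_protocol(duration_s: int, phase_h: float = 0.0, light_h: float = 12.0,
                period_h: float = 24.0, n_tubes: int = 16) -> ProtocolSpec:
    """12:12-style light:dark cycle (no habituation block)."""
    return ProtocolSpec(
        name=f"ld-{light_h:g}:{period_h - light_h:g}",
        duration_s=duration_s,
        habituation_s=0,
        ld_cycle=LDCycle(period_h=period_h, light_h=light_h, phase_h=phase_h),
        n_tubes=n_tubes,
    )


def place_preference_protocol(duration_s: int, swap_at_s: Optional[int] = None,
                              habituation_s: int = 0, boundary_beam: int = 9,
                              n_tubes: int = 16) -> ProtocolSpec:
    """Closed-loop blue/green zone protocol, optionally with a zone swap."""
    return ProtocolSpec(
        name="place-preference",
        duration_s=duration_s,
        habituation_s=habituation_s,
        feedback=FeedbackRule(boundary_beam=boundary_beam, swap_at_s=swap_at_s),
        n_tubes=n_tubes,
    )


# ---------------------------------------------------------------------------
# Open-loop compilation
# ---------------------------------------------------------------------------


def compile_protocol(spec: ProtocolSpec) -> StimulusLog:
    """Compile an open-loop protocol into a deterministic stimulus log.

    For pulse protocols: white light from t = 0, each pulse an OFF event of
    exactly ``pulse_ms`` followed by restoration of white.  For light:dark
    cycles: white/off toggles at the phase boundaries.  Closed-loop specs
    compile to their open-loop prefix only (habituation white light); the
    feedback portion of the log is produced by :func:`run_closed_loop`.
    """
    tubes = spec.all_tubes
    events: list = []

    if spec.ld_cycle is not None:
        ld = spec.ld_cycle
        boundaries_h: list = [0.0]
        h = -(ld.phase_h % ld.period_h)  # session hour of the cycle origin
        while h < spec.duration_s / 3600.0:
            for edge in (ld.light_h, ld.period_h):
                t_h = h + edge
                if 0.0 < t_h < spec.duration_s / 3600.0:
                    boundaries_h.append(t_h)
            h += ld.period_h
        for t_h in sorted(set(boundaries_h)):
            t_ms = int(round(t_h * 3600_000))
            light = bool(ld.is_light(t_h * 3600.0))
            events.append(StimulusEvent(
                t_ms, tubes, Color.WHITE if light else Color.OFF,
                1.0 if light else 0.0))
    elif spec.feedback is not None:
        if spec.habituation_s > 0:
            events.append(StimulusEvent(0, tubes, Color.WHITE, 1.0))
    else:
        events.append(StimulusEvent(0, tubes, Color.WHITE, 1.0))
        for seg in spec.timeline:
            seg_tubes = seg.tubes if seg.tubes is not None else tubes
            events.append(StimulusEvent(seg.start_ms, seg_tubes, seg.color,
                                        seg.intensity))
            events.append(StimulusEvent(seg.end_ms, seg_tubes, Color.WHITE, 1.0))
        if spec.stimuli is not None:
            for t_s in spec.stimuli.pulse_times_s():
                t_ms = int(t_s) * 1000
                events.append(StimulusEvent(t_ms, tubes, spec.stimuli.color,
                                            0.0 if spec.stimuli.color is Color.OFF
                                            else 1.0))
                events.append(StimulusEvent(t_ms + spec.stimuli.pulse_ms, tubes,
                                            Color.WHITE, 1.0))

    events.sort(key=lambda e: e.time_ms)
    # Drop per-tube no-op entries so the log stays deduplicated.
    deduped: list = []
    last: dict = {}
    for ev in events:
        changed = frozenset(t for t in ev.tubes
                            if last.get(t) != (ev.color, ev.intensity))
        if not changed:
            continue
        for t in changed:
            last[t] = (ev.color, ev.intensity)
        deduped.append(StimulusEvent(ev.time_ms, changed, ev.color, ev.intensity))
    return StimulusLog(deduped)


# ---------------------------------------------------------------------------
# Closed-loop controller
# ---------------------------------------------------------------------------


def zone_step(positions: np.ndarray, prev_zones: np.ndarray,
              boundary_beam: int) -> np.ndarray:
    """Vectorized zone update with boundary hysteresis.

    left if position < boundary, right if > boundary, previous zone when the
    fly sits exactly on the boundary beam.
    """
    positions = np.asarray(positions)
    zones = np.where(positions < boundary_beam, LEFT,
                     np.where(positions > boundary_beam, RIGHT, prev_zones))
    return zones.astype(np.int8)


def controller_step(rule: FeedbackRule, positions: np.ndarray,
                    prev_zones: Optional[np.ndarray], t_s: float,
                    prev_colors: Optional[np.ndarray] = None):
    """One controller tick: positions → zones → per-tube LED commands.

    Returns ``(zones, color_codes, commands)`` where ``commands`` lists
    ``(tube_index0, color)`` only for tubes whose color changed (so the
    resulting log stays deduplicated).  A missing previous zone for a fly
    sitting on the boundary defaults to the left zone.
    """
    positions = np.asarray(positions)
    if prev_zones is None:
        prev_zones = np.full(positions.shape, LEFT, dtype=np.int8)
    zones = zone_step(positions, prev_zones, rule.boundary_beam)
    left_color, right_color = rule.zone_colors(t_s)
    codes = np.where(zones == LEFT, COLOR_CODE[left_color],
                     COLOR_CODE[right_color]).astype(np.int8)
    if prev_colors is None:
        changed = np.ones(len(codes), dtype=bool)
    else:
        changed = codes != prev_colors
    commands = [(i, CODE_COLOR[int(codes[i])]) for i in np.nonzero(changed)[0]]
    return zones, codes, commands


class FlyStepper(Protocol):
    """Interface the closed loop drives (implemented by the simulator)."""

    n_flies: int

    def current_positions(self) -> np.ndarray:
        """Beam positions at the end of the previous second."""
        ...

    def step(self, color_codes: np.ndarray, t_s: int) -> np.ndarray:
        """Advance one second under the given per-fly illumination; return
        end-of-second beam positions."""
        ...


@dataclass
class ClosedLoopResult:
    stimulus_log: StimulusLog
    zones: np.ndarray  # (n_flies, duration_s) int8, LEFT/RIGHT per second


def run_closed_loop(spec: ProtocolSpec, flies: FlyStepper,
                    seed: Optional[int] = None) -> ClosedLoopResult:
    """Run the per-second feedback loop of a closed-loop protocol.

    Each second ``t`` the controller reads the positions sampled at the end
    of second ``t - 1`` (the initial placement for ``t = 0``) and applies
    the corresponding zone color during second ``t`` — so the logged color
    at any second ``t >= 1`` equals the rule color of the zone occupied at
    ``t - 1``.  During the habituation block the tubes are white.  ``seed``
    is unused here (the stepper owns all randomness) and accepted for
    interface symmetry.
    """
    if spec.feedback is None:
        raise ValidationError("run_closed_loop requires spec.feedback")
    rule = spec.feedback
    n = flies.n_flies
    duration = spec.duration_s
    zones = np.empty((n, duration), dtype=np.int8)
    events: list = []

    pos = np.asarray(flies.current_positions())
    prev_zones = zone_step(pos, np.full(n, LEFT, dtype=np.int8),
                           rule.boundary_beam)
    prev_colors = np.full(n, -1, dtype=np.int8)

    white = np.full(n, COLOR_CODE[Color.WHITE], dtype=np.int8)
    for t in range(duration):
        if t < spec.habituation_s:
            codes = white
            commands = [(i, Color.WHITE)
                        for i in np.nonzero(codes != prev_colors)[0]]
        else:
            _, codes, commands = controller_step(rule, pos, prev_zones, t,
                                                 prev_colors)
        for i, color in commands:
            events.append(StimulusEvent(t * 1000, frozenset([int(i) + 1]),
                                        color,
                                        0.0 if color is Color.OFF else 1.0))
        prev_colors = codes
        pos = flies.step(codes, t)
        prev_zones = zone_step(pos, prev_zones, rule.boundary_beam)
        zones[:, t] = prev_zones

    # Merge simultaneous same-color events into compact tube sets.
    merged: dict = {}
    for ev in events:
        key = (ev.time_ms, ev.color, ev.intensity)
        merged.setdefault(key, set()).update(ev.tubes)
    log = StimulusLog([
        StimulusEvent(t_ms, frozenset(tubes), color, intensity)
        for (t_ms, color, intensity), tubes in sorted(
            merged.items(), key=lambda kv: kv[0][0])
    ])
    return ClosedLoopResult(stimulus_log=log, zones=zones)


# ---------------------------------------------------------------------------
# Config file (YAML) serialization
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: ProtocolSpec) -> dict:
    out: dict = {
        "name": spec.name,
        "duration_s": spec.duration_s,
        "habituation_s": spec.habituation_s,
        "n_tubes": spec.n_tubes,
    }
    if spec.timeline:
        out["timeline"] = [
            {"start_ms": s.start_ms, "end_ms": s.end_ms, "color": s.color.value,
             "intensity": s.intensity,
             "tubes": sorted(s.tubes) if s.tubes is not None else None}
            for s in spec.timeline
        ]
    if spec.stimuli is not None:
        st = spec.stimuli
        out["stimuli"] = {"first_at_s": st.first_at_s, "iti_s": st.iti_s,
                          "n_trials": st.n_trials, "pulse_ms": st.pulse_ms,
                          "color": st.color.value}
    if spec.ld_cycle is not None:
        ld = spec.ld_cycle
        out["ld_cycle"] = {"period_h": ld.period_h, "light_h": ld.light_h,
                           "phase_h": ld.phase_h}
    if spec.feedback is not None:
        fb = spec.feedback
        out["feedback"] = {"boundary_beam": fb.boundary_beam,
                           "left_color": fb.left_color.value,
                           "right_color": fb.right_color.value,
                           "swap_at_s": fb.swap_at_s, "tick_s": fb.tick_s}
    return out


def _spec_from_dict(d: dict) -> ProtocolSpec:
    timeline = tuple(
        Segment(start_ms=s["start_ms"], end_ms=s["end_ms"],
                color=Color(s["color"]), intensity=s.get("intensity", 1.0),
                tubes=frozenset(s["tubes"]) if s.get("tubes") else None)
        for s in d.get("timeline", [])
    )
    stimuli = None
    if "stimuli" in d:
        st = dict(d["stimuli"])
        st["color"] = Color(st.get("color", "off"))
        stimuli = PulseTrain(**st)
    ld = LDCycle(**d["ld_cycle"]) if "ld_cycle" in d else None
    feedback = None
    if "feedback" in d:
        fb = dict(d["feedback"])
        fb["left_color"] = Color(fb.get("left_color", "blue"))
        fb["right_color"] = Color(fb.get("right_color", "green"))
        feedback = FeedbackRule(**fb)
    return ProtocolSpec(
        name=d["name"], duration_s=d["duration_s"],
        habituation_s=d.get("habituation_s", 1800), timeline=timeline,
        stimuli=stimuli, ld_cycle=ld, feedback=feedback,
        n_tubes=d.get("n_tubes", 16),
    )


def save_protocol(spec: ProtocolSpec, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def load_protocol(path: str) -> ProtocolSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return _spec_from_dict(d)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: invalid protocol config ({exc})") from exc
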