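"""Closed-loop gap-cross session logic.

The behavioural rig alternates between two states: *exploration* (doors open,
the mouse attempts one crossing at the current gap distance while motion
sensors log its position) and *adjustment* (doors closed, the platforms move
to the next distance).  The next distance is drawn uniformly from the 0.5 cm
grid spanning 1.0 cm below to 1.5 cm above the session's maximum successfully
crossed distance, clamped to [3.0, 7.0] cm; every session starts at 3.0 cm
and runs to 20 successful trials or 20 simulated minutes.

Distances are held on an integer half-centimetre grid internally — exact set
membership is load-bearing for the adaptive rule, so no floating-point grid
arithmetic is allowed near it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agent import BehavioralAgent, SensorEvent, TrialOutcome

STEP_CM = 0.5


def _to_units(cm: float, what: str = "distance") -> int:
    u = cm / STEP_CM
    r = round(u)
    if abs(u - r) > 1e-9:
        raise ValueError(f"{what} {cm} cm is not a multiple of {STEP_CM} cm")
    return int(r)


@dataclass(frozen=True)
class GapCrossConfig:
    """Assay geometry, adaptive-rule offsets and session accounting."""

    d_min: float = 3.0  # cm
    d_max: float = 7.0  # cm
    step: float = STEP_CM  # cm
    lower_offset: float = 1.0  # cm below the running max
    upper_offset: float = 1.5  # cm above the running max
    first_trial_distance: float = 3.0  # cm, every session starts here
    success_quota: int = 20  # successful trials ending a session
    session_time_limit: float = 1200.0  # s
    sessions_total: int = 12
    sessions_per_day: int = 2
    nose_max: float = 4.5  # cm, upper edge of the nose-distance class
    whisker_min: float = 5.0  # cm, lower edge of the whisker-distance class

    def __post_init__(self) -> None:
        if abs(self.step - STEP_CM) > 1e-12:
            raise ValueError("grid step is fixed at 0.5 cm")
        lo, hi = _to_units(self.d_min, "d_min"), _to_units(self.d_max, "d_max")
        if hi < lo:
            raise ValueError("d_max must be >= d_min")
        first = _to_units(self.first_trial_distance, "first_trial_distance")
        if not lo <= first <= hi:
            raise ValueError("first_trial_distance must lie on the grid within [d_min, d_max]")
        _to_units(self.lower_offset, "lower_offset")
        _to_units(self.upper_offset, "upper_offset")
        if self.success_quota < 1:
            raise ValueError("success_quota must be >= 1")
        if self.session_time_limit <= 0:
            raise ValueError("session_time_limit must be positive")
        if self.sessions_total < 1:
            raise ValueError("sessions_total must be >= 1")

    def grid(self) -> list[float]:
        lo, hi = _to_units(self.d_min), _to_units(self.d_max)
        return [u * STEP_CM for u in range(lo, hi + 1)]


@dataclass
class Trial:
    distance: float  # cm
    outcome: str  # "success" | "failure"
    events: tuple[SensorEvent, ...]
    reward_delivered: bool


@dataclass
class Session:
    trials: list[Trial]
    termination: str  # "quota" | "timeout"
    max_distance_crossed: Optional[float]  # cm, None if no success
    session_index: int = 1

    @property
    def n_successes(self) -> int:
        return sum(t.outcome == "success" for t in self.trials)


@dataclass
class ExperimentRecord:
    mouse_id: str
    genotype: str
    sessions: list[Session]


def candidate_distances(
    max_crossed: Optional[float], config: GapCrossConfig
) -> list[float]:
    """Grid of distances the adaptive rule may draw from.

    The window runs from ``max_crossed - lower_offset`` (clamped at d_min) to
    ``max_crossed + upper_offset`` (clamped at d_max) in 0.5 cm steps.  Before
    the first success of a session the maximum crossed distance is undefined
    and the window is anchored at the session's fixed starting distance.
    """
    if max_crossed is None:
        m = _to_units(config.first_trial_distance)
    else:
        m = _to_units(max_crossed, "max_crossed")
        if not _to_units(config.d_min) <= m <= _to_units(config.d_max):
            raise ValueError(f"max_crossed {max_crossed} cm is outside [{config.d_min}, {config.d_max}]")
    lo = max(_to_units(config.d_min), m - _to_units(config.lower_offset))
    hi = min(_to_units(config.d_max), m + _to_units(config.upper_offset))
    return [u * STEP_CM for u in range(lo, hi + 1)]


def next_gap_distance(
    max_crossed: Optional[float], config: GapCrossConfig, rng: np.random.Generator
) -> float:
    """Uniform draw over :func:`candidate_distances`."""
    candidates = candidate_distances(max_crossed, config)
    return candidates[rng.integers(len(candidates))]


def classify_trial(events: Sequence[SensorEvent]) -> Optional[str]:
    """Classify a sensor-event trace as success, failure, or incomplete.

    Success means the target-rear sensor (4) was reached; failure means the
    mouse reached the home edge (2), possibly touched the target edge (3),
    and returned home (1) without reaching 4.  Anything else is an incomplete
    trace and yields ``None`` (no trial is emitted for it).
    """
    if not events:
        raise ValueError("empty event sequence")
    last_t = -np.inf
    for ev in events:
        if ev.sensor_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown sensor id {ev.sensor_id}")
        if ev.timestamp < last_t:
            raise ValueError("event timestamps are not non-decreasing")
        last_t = ev.timestamp
    if events[0].sensor_id not in (1, 2):
        raise ValueError(f"trial must begin at the home platform (sensor 1 or 2), got {events[0].sensor_id}")
    ids = [ev.sensor_id for ev in events]
    if 4 in ids:
        return "success"
    if 2 in ids and ids[-1] == 1:
        return "failure"
    return None


def run_session(
    agent: BehavioralAgent,
    config: GapCrossConfig,
    rng: np.random.Generator,
    session_index: int = 1,
) -> Session:
    """Run one closed-loop session against a simulated agent.

    Exploration and adjustment alternate: each trial runs at the current
    distance, then the doors close and the next distance is drawn from the
    adaptive window around the running maximum successful distance (which
    resets every session).  The session ends at ``success_quota`` successes
    or once the simulated clock exceeds ``session_time_limit``; the timeout
    is checked between trials, so a trial in progress at the limit completes.
    """
    quota = config.success_quota
    limit = config.session_time_limit
    trials: list[Trial] = []
    clock = 0.0
    successes = 0
    max_crossed: Optional[float] = None
    distance = config.first_trial_distance
    termination = "timeout"
    while True:
        out = agent.respond(distance, session_index, rng)
        outcome = classify_trial(out.events)
        if outcome is None or (outcome == "success") != out.success:
            raise ValueError(
                f"agent emitted a malformed event sequence for a "
                f"{'successful' if out.success else 'failed'} trial: "
                f"{[ev.sensor_id for ev in out.events]}"
            )
        trials.append(
            Trial(distance=distance, outcome=outcome, events=out.events,
                  reward_delivered=out.success)
        )
        clock += out.duration + out.inter_trial_time
        if out.success:
            successes += 1
            if max_crossed is None or distance > max_crossed:
                max_crossed = distance
        if successes >= quota:
            termination = "quota"
            break
        if clock > limit:
            termination = "timeout"
            break
        distance = next_gap_distance(max_crossed, config, rng)
    return Session(trials=trials, termination=termination,
                   max_distance_crossed=max_crossed, session_index=session_index)


def run_experiment(
    agent: BehavioralAgent,
    config: GapCrossConfig,
    rng: np.random.Generator,
    mouse_id: str = "m00",
) -> ExperimentRecord:
    """Run the full training series (default 12 consecutive sessions).

    The agent's learning enters through the session index; the adaptive
    rule's running maximum resets at each session boundary.
    """
    sessions = [
        run_session(agent, config, rng, session_index=i)
        for i in range(1, config.sessions_total + 1)
    ]
    return ExperimentRecord(mouse_id=mouse_id, genotype=agent.config.genotype,
                            sessions=sessions)
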