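"""Generative model of a mouse performing the gap-cross task.

The agent stands behind the same sensor-event interface a live animal
produces: each trial at a gap distance ``d`` (cm) yields either a successful
crossing (home rear -> home edge -> target edge -> target rear, sensors
1-2-3-4) or a failed approach that retreats to the home platform.  Success is
Bernoulli with

    p = (1 - lapse) * logistic(intercept - slope * d + L * (session - 1))

where ``L`` is a per-session learning rate in logit units that depends on the
distance class: "nose" distances (<= 4.5 cm, target reachable with the
snout) versus "whisker" distances (>= 5 cm, whisker-only information).
Genotype-specific deficits are expressed by zeroing the whisker-class rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

#: distances at or below this are "nose" distances; above, "whisker"
NOSE_MAX_CM = 4.5


class SensorEvent(NamedTuple):
    sensor_id: int  # 1 home rear, 2 home edge, 3 target edge, 4 target rear
    timestamp: float  # s, relative to trial start


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of the simulated mouse.

    ``intercept``/``slope`` set the psychometric curve over distance (logit
    units, per-cm); the two learning rates add logit units per completed
    session; ``lapse_rate`` caps asymptotic performance; timing fields (s)
    drive the simulated session clock.
    """

    genotype: str = "WT"
    intercept: float = 4.0
    slope: float = 1.0  # per cm
    nose_learning_rate: float = 0.2  # logit units per session
    whisker_learning_rate: float = 0.2
    lapse_rate: float = 0.02
    inter_trial_mean: float = 20.0  # s, door-closed adjustment phase
    inter_trial_jitter: float = 5.0  # s
    crossing_time: float = 8.0  # s
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError(f"lapse_rate must be in [0, 0.5), got {self.lapse_rate}")
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0, got {self.slope}")
        for name in ("intercept", "nose_learning_rate", "whisker_learning_rate"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.inter_trial_mean < 0 or self.inter_trial_jitter < 0 or self.crossing_time <= 0:
            raise ValueError("timing parameters must be non-negative (crossing_time positive)")


@dataclass(frozen=True)
class TrialOutcome:
    """One simulated trial: outcome, its sensor trace, and its timing."""

    success: bool
    events: tuple[SensorEvent, ...]
    duration: float  # s from first to last sensor event
    inter_trial_time: float  # s of adjustment phase following the trial


def _check_distance(distance: float) -> None:
    if not (3.0 <= distance <= 7.0) or abs(distance * 2 - round(distance * 2)) > 1e-9:
        raise ValueError(
            f"distance {distance} cm is off the 0.5 cm grid within [3.0, 7.0]"
        )


def success_probability(config: AgentConfig, distance: float, session_index: int) -> float:
    """Closed-form success probability for a distance and session."""
    _check_distance(distance)
    if session_index < 1:
        raise ValueError(f"session_index must be >= 1, got {session_index}")
    rate = (
        config.nose_learning_rate
        if distance <= NOSE_MAX_CM
        else config.whisker_learning_rate
    )
    logit = config.intercept - config.slope * distance + rate * (session_index - 1)
    return (1.0 - config.lapse_rate) / (1.0 + math.exp(-logit))


class BehavioralAgent:
    """Stateless simulated mouse: all randomness comes from the caller's rng."""

    def __init__(self, config: AgentConfig):
        self.config = config

    def respond(
        self, distance: float, session_index: int, rng: np.random.Generator
    ) -> TrialOutcome:
        return simulate_agent_response(self, distance, session_index, rng)


def simulate_agent_response(
    agent: BehavioralAgent,
    distance: float,
    session_index: int,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Simulate one trial at ``distance`` during session ``session_index``.

    Successful crossings traverse sensors 1-2-3-4; failures either turn back
    at the home edge (1-2-1) or reach out to the target edge before
    retreating (1-2-3-2-1), with equal probability — both retreat shapes
    occur in real sessions.
    """
    cfg = agent.config
    p = success_probability(cfg, distance, session_index)
    success = rng.random() < p
    duration = cfg.crossing_time * (0.75 + 0.5 * rng.random())
    iti = max(0.0, cfg.inter_trial_mean + cfg.inter_trial_jitter * rng.standard_normal())
    if success:
        events = (
            SensorEvent(1, 0.0),
            SensorEvent(2, 0.35 * duration),
            SensorEvent(3, 0.70 * duration),
            SensorEvent(4, duration),
        )
    elif rng.random() < 0.5:
        events = (
            SensorEvent(1, 0.0),
            SensorEvent(2, 0.50 * duration),
            SensorEvent(1, duration),
        )
    else:
        events = (
            SensorEvent(1, 0.0),
            SensorEvent(2, 0.30 * duration),
            SensorEvent(3, 0.55 * duration),
            SensorEvent(2, 0.80 * duration),
            SensorEvent(1, duration),
        )
    return TrialOutcome(success=success, events=events, duration=duration, inter_trial_time=iti)
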